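"""Zero-lag cross-correlation between normalized EEG series and behavior.

For each 5 s bin the behavior is binarized (present if any scored second in
the bin carries the label; a majority rule is available) and Pearson's r is
computed against the binned EEG series at lag 0. Mild limbic behaviors
(staring, chewing/head-waving) track hippocampal electrographic activity more
tightly than convulsive behaviors, and r is invariant to affine rescaling of
the EEG series, so gain differences between animals do not matter.

Bins outside a behavior's scoring horizon are excluded pairwise. Zero
variance in either vector yields an explicitly flagged undefined result
(``valid=False``, r=nan) rather than a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .behavior import BehaviorTrace, resolve_category
from .preprocess import NormalizedSeries

__all__ = ["XcorrResult", "xcorr_zero_lag"]


@dataclass(frozen=True)
class XcorrResult:
    behavior_label: str
    signal_kind: str  # "amplitude" | "beta_low_gamma_power"
    r: float
    n_bins: int
    valid: bool = True

    @property
    def fisher_z(self) -> float:
        return float(np.arctanh(self.r))


def xcorr_zero_lag(
    series: NormalizedSeries,
    trace: BehaviorTrace,
    behavior_label: str | Iterable[str],
    bin_width_s: float = 5.0,
    rule: str = "any",
) -> XcorrResult:
    """Pearson correlation between a binned EEG series and a 0/1 behavior
    indicator, lag 0."""
    codes = resolve_category(behavior_label)
    label = behavior_label if isinstance(behavior_label, str) else "+".join(sorted(codes))
    if rule not in ("any", "majority"):
        raise ValueError("rule must be 'any' or 'majority'")
    if abs(bin_width_s - series.bin_width_s) > 1e-9:
        raise ValueError("series bin width must match the requested bin width")

    sec_per_bin = int(round(bin_width_s))
    member = np.isin(trace.codes, list(codes))
    scored = np.arange(trace.n_seconds) < trace.scored_until(codes)
    n_bins = min(series.n_bins, trace.n_seconds // sec_per_bin)
    if n_bins < 3:
        raise ValueError("need at least 3 overlapping bins")
    member = member[: n_bins * sec_per_bin].reshape(n_bins, sec_per_bin)
    scored = scored[: n_bins * sec_per_bin].reshape(n_bins, sec_per_bin)
    n_scored = scored.sum(axis=1)
    keep = n_scored > 0
    hits = (member & scored).sum(axis=1)
    if rule == "any":
        indicator = hits > 0
    else:
        indicator = hits * 2 > n_scored
    x = series.values[:n_bins][keep]
    y = indicator[keep].astype(float)
    kind = "amplitude" if series.kind == "rms_amplitude" else "beta_low_gamma_power"
    if y.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return XcorrResult(label, kind, float("nan"), int(y.size), valid=False)
    r = float(np.corrcoef(x, y)[0, 1])
    return XcorrResult(label, kind, r, int(y.size), valid=True)
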