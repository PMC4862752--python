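"""Racine-stage behavior traces and derived metrics.

Behavior is scored once per second on a modified Racine scale:

======  =============  ==========================
code    label          Racine stage
======  =============  ==========================
none    no seizure behavior
0       staring        0
1_2     C-HW           1-2 (chewing / head-waving, scored jointly)
3       FLC            3 (forelimb clonus)
4       rear           4 (rearing)
5f      fall           5 (falling)
5tc     T-C            5 (tonic-clonic)
======  =============  ==========================

Falling and tonic-clonic both map to Racine 5 but keep distinct codes.
Severity ordering: none < 0 < 1_2 < 3 < 4 < 5f <= 5tc.

Some designs score a stage only over part of the session (e.g. staring for
the first 30 min only, or only Racine 3-5 after the first 2 h of a 6 h
session). Per-code scoring horizons record this; seconds past a horizon are
*missing*, not zero, and are excluded from percent-time denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CODES",
    "RANK",
    "LABELS",
    "CATEGORIES",
    "BehaviorTrace",
    "resolve_category",
    "category_time",
    "staring_latency",
    "proportion_reaching_stage",
    "max_stage_per_min",
]

CODES: tuple[str, ...] = ("none", "0", "1_2", "3", "4", "5f", "5tc")
RANK: dict[str, int] = {"none": 0, "0": 1, "1_2": 2, "3": 3, "4": 4, "5f": 5, "5tc": 6}

#: Field names for individual behaviors.
LABELS: dict[str, frozenset[str]] = {
    "staring": frozenset({"0"}),
    "C-HW": frozenset({"1_2"}),
    "FLC": frozenset({"3"}),
    "rear": frozenset({"4"}),
    "fall": frozenset({"5f"}),
    "T-C": frozenset({"5tc"}),
}

#: Named stage unions used for percent-time analyses.
CATEGORIES: dict[str, frozenset[str]] = {
    "R0_5": frozenset({"0", "1_2", "3", "4", "5f", "5tc"}),
    "R1_5": frozenset({"1_2", "3", "4", "5f", "5tc"}),
    "R1_2": frozenset({"1_2"}),
    "R3_5": frozenset({"3", "4", "5f", "5tc"}),
}


def resolve_category(category: str | Iterable[str]) -> frozenset[str]:
    """Accept a named union (R1_5 ...), a behavior label (FLC ...), a single
    code, or an explicit set of codes."""
    if isinstance(category, str):
        if category in CATEGORIES:
            return CATEGORIES[category]
        if category in LABELS:
            return LABELS[category]
        category = {category}
    codes = frozenset(category)
    unknown = codes - set(CODES)
    if unknown:
        raise ValueError(f"unknown behavior codes: {sorted(unknown)}")
    return codes


@dataclass
class BehaviorTrace:
    """Per-second stage codes plus optional per-code scoring horizons.

    ``horizons[code]`` is the number of seconds from trace start over which
    that code was scored; codes absent from the mapping are scored for the
    whole trace.
    """

    codes: np.ndarray
    horizons: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="U4")
        bad = set(np.unique(self.codes)) - set(CODES)
        if bad:
            raise ValueError(f"unknown behavior codes in trace: {sorted(bad)}")
        for c, h in self.horizons.items():
            if c not in CODES:
                raise ValueError(f"horizon for unknown code {c!r}")
            if h > self.n_seconds:
                raise ValueError(f"horizon for {c!r} exceeds trace length")

    @property
    def n_seconds(self) -> int:
        return self.codes.size

    def ranks(self) -> np.ndarray:
        out = np.zeros(self.n_seconds, dtype=int)
        for c, r in RANK.items():
            out[self.codes == c] = r
        return out

    def scored_until(self, codes: frozenset[str]) -> float:
        """Horizon up to which membership in ``codes`` is fully determined."""
        return min(self.horizons.get(c, float(self.n_seconds)) for c in codes)


def category_time(
    trace: BehaviorTrace,
    category: str | Iterable[str],
    bin_width_s: float = 300.0,
) -> np.ndarray:
    """Percent of scored seconds per bin spent in ``category``.

    Bins with no scored second are NaN (missing), not zero.
    """
    codes = resolve_category(category)
    member = np.isin(trace.codes, list(codes))
    horizon = trace.scored_until(codes)
    scored = np.arange(trace.n_seconds) < horizon
    n_bins = int(np.ceil(trace.n_seconds / bin_width_s - 1e-9))
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        lo, hi = int(b * bin_width_s), min(int((b + 1) * bin_width_s), trace.n_seconds)
        n_scored = int(scored[lo:hi].sum())
        if n_scored:
            out[b] = 100.0 * member[lo:hi][scored[lo:hi]].sum() / n_scored
    return out


def staring_latency(trace: BehaviorTrace) -> float | None:
    """Onset time (s) of the first staring run strictly longer than 20 s,
    or None if no qualifying run exists."""
    is_star = trace.codes == "0"
    padded = np.concatenate(([False], is_star, [False])).astype(int)
    idx = np.flatnonzero(np.diff(padded))
    for s, e in zip(idx[0::2], idx[1::2]):
        if e - s > 20:
            return float(s)
    return None


def proportion_reaching_stage(
    traces: Sequence[BehaviorTrace], stage: str
) -> float:
    """Fraction of animals with at least one second at ``stage`` or any more
    severe stage. Non-increasing in stage severity."""
    if not traces:
        raise ValueError("empty cohort")
    if stage not in RANK or stage == "none":
        raise ValueError(f"stage must be one of {CODES[1:]}")
    # 5f and 5tc are the same Racine stage: reaching "5f" means reaching 5.
    min_rank = RANK["5f"] if stage in ("5f", "5tc") else RANK[stage]
    return float(np.mean([bool((t.ranks() >= min_rank).any()) for t in traces]))


def max_stage_per_min(trace: BehaviorTrace) -> np.ndarray:
    """Highest stage code reached in each 1 min bin (heat-map reduction).

    Ordering none < 0 < 1_2 < 3 < 4 < 5; within Racine 5, tonic-clonic
    outranks falling.
    """
    ranks = trace.ranks()
    n_bins = int(np.ceil(trace.n_seconds / 60.0 - 1e-9))
    inv = {v: k for k, v in RANK.items()}
    out = np.empty(n_bins, dtype="U4")
    for b in range(n_bins):
        seg = ranks[b * 60 : (b + 1) * 60]
        out[b] = inv[int(seg.max())] if seg.size else "none"
    return out
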