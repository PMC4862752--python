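"""Status-epilepticus (SE) state machines and cohort summaries.

Two operational definitions, both producing half-open episodes in seconds:

*Behavioral SE* — opens when Racine 3-5 behaviors (FLC, rearing,
falling/tonic-clonic) occur uninterrupted for at least 30 s; stays open while
gaps between Racine 3-5 seconds do not exceed 2 min; closes at the end of the
last Racine 3-5 second before a longer gap. "Uninterrupted" is strict: a
single second of any other code breaks an onset run. The silent up-to-2-min
tail after the last convulsive second is *not* counted as SE time.

*Electrographic SE* — a hysteresis machine on normalized EEG amplitude:
opens at the start of a >=30 s run of amplitude >=10x baseline; closes at the
start of the first >=30 s run below 3x baseline; values in [3x, 10x) sustain
an open episode. These parameters capture severe merging seizures without
classifying earlier isolated seizures as SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .behavior import RANK, BehaviorTrace
from .preprocess import NormalizedSeries

__all__ = [
    "SEConfig",
    "SEEpisode",
    "detect_behavioral_se",
    "detect_electrographic_se",
    "se_summary",
]


@dataclass(frozen=True)
class SEConfig:
    behavioral_onset_run_s: float = 30.0
    behavioral_max_gap_s: float = 120.0
    electrographic_onset_x: float = 10.0
    electrographic_onset_run_s: float = 30.0
    electrographic_offset_x: float = 3.0
    electrographic_offset_run_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.electrographic_onset_x > self.electrographic_offset_x > 1:
            raise ValueError("need onset_x > offset_x > 1")
        for f in (
            self.behavioral_onset_run_s,
            self.electrographic_onset_run_s,
            self.electrographic_offset_run_s,
        ):
            if f <= 0:
                raise ValueError("run lengths must be positive")


@dataclass(frozen=True)
class SEEpisode:
    kind: str  # "behavioral" | "electrographic"
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("episode offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _runs_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def detect_behavioral_se(trace: BehaviorTrace, cfg: SEConfig | None = None) -> list[SEEpisode]:
    """Behavioral SE episodes from a per-second Racine trace."""
    cfg = cfg or SEConfig()
    conv = trace.ranks() >= RANK["3"]
    runs = _runs_bool(conv)
    onset_run = int(cfg.behavioral_onset_run_s)
    max_gap = cfg.behavioral_max_gap_s
    episodes: list[SEEpisode] = []
    open_ep: list[float] | None = None
    for s, e in runs:
        if open_ep is not None and s - open_ep[1] <= max_gap:
            open_ep[1] = e  # any convulsive activity within the gap sustains SE
            continue
        if open_ep is not None:
            episodes.append(SEEpisode("behavioral", open_ep[0], open_ep[1]))
            open_ep = None
        if e - s >= onset_run:
            open_ep = [float(s), float(e)]
    if open_ep is not None:
        episodes.append(SEEpisode("behavioral", open_ep[0], open_ep[1]))
    return episodes


def detect_electrographic_se(
    series: NormalizedSeries, cfg: SEConfig | None = None
) -> list[SEEpisode]:
    """Electrographic SE episodes from a normalized amplitude series."""
    cfg = cfg or SEConfig()
    if series.kind != "rms_amplitude":
        raise ValueError("electrographic SE requires a normalized amplitude series")
    bw = series.bin_width_s
    n_on = int(round(cfg.electrographic_onset_run_s / bw))
    n_off = int(round(cfg.electrographic_offset_run_s / bw))
    v = series.values
    episodes: list[SEEpisode] = []
    onset_bin: int | None = None
    hi_count = 0
    lo_count = 0
    hi_start = 0
    lo_start = 0
    open_since: int | None = None
    for i, x in enumerate(v):
        if open_since is None:
            if x >= cfg.electrographic_onset_x:
                if hi_count == 0:
                    hi_start = i
                hi_count += 1
                if hi_count >= n_on:
                    open_since = hi_start
                    lo_count = 0
            else:
                hi_count = 0
        else:
            if x < cfg.electrographic_offset_x:
                if lo_count == 0:
                    lo_start = i
                lo_count += 1
                if lo_count >= n_off:
                    episodes.append(
                        SEEpisode("electrographic", open_since * bw, lo_start * bw)
                    )
                    open_since = None
                    hi_count = 0
                    lo_count = 0
            else:
                lo_count = 0
    if open_since is not None:
        episodes.append(SEEpisode("electrographic", open_since * bw, v.size * bw))
    return episodes


def se_summary(
    cohort: Mapping[str, Sequence[SEEpisode]],
    bin_width_s: float = 300.0,
    horizon_s: float | None = None,
    t_ref_s: float = 0.0,
) -> dict:
    """Cohort SE summary.

    Returns ``incidence_per_bin`` (fraction of subjects in SE during each
    bin), per-subject ``latency_s`` (first onset minus ``t_ref_s``, typically
    the KA injection; None if the subject never reached SE) and per-subject
    ``total_time_s``.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if horizon_s is None:
        horizon_s = max(
            (ep.offset_s for eps in cohort.values() for ep in eps), default=bin_width_s
        )
    n_bins = int(np.ceil(horizon_s / bin_width_s - 1e-9))
    incidence = np.zeros(n_bins)
    latency: dict[str, float | None] = {}
    total: dict[str, float] = {}
    for subj, eps in cohort.items():
        eps = sorted(eps, key=lambda e: e.onset_s)
        latency[subj] = eps[0].onset_s - t_ref_s if eps else None
        total[subj] = float(sum(e.duration_s for e in eps))
        in_bin = np.zeros(n_bins, dtype=bool)
        for ep in eps:
            b0 = int(ep.onset_s // bin_width_s)
            b1 = int(np.ceil(ep.offset_s / bin_width_s - 1e-12))
            in_bin[max(b0, 0) : min(b1, n_bins)] = True
        incidence += in_bin
    incidence /= len(cohort)
    return {"incidence_per_bin": incidence, "latency_s": latency, "total_time_s": total}
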