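"""Threshold/duration electrographic seizure detection.

A seizure is a maximal run of consecutive bins whose normalized value meets
or exceeds ``threshold_x`` times baseline, lasting at least ``min_duration_s``:
5x baseline amplitude for 30 s, or 5x baseline beta-low gamma power for 20 s.
3x and 10x thresholds are used for robustness sweeps. Because detection
operates on baseline-normalized series it is invariant to raw-signal gain.

Durations are bin-quantized (30 s = 6 five-second bins); ties exactly at the
threshold count as supra-threshold. Runs separated by no more than
``merge_gap_s`` are merged *before* the duration test (default 0 = no
merging). Bins before ``analysis_start_s`` (typically the KA injection) are
never counted as seizure, so baseline bins cannot self-detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .preprocess import NormalizedSeries

__all__ = [
    "DetectConfig",
    "SeizureEvent",
    "FirstSeizureSummary",
    "detect_seizures",
    "time_in_seizure",
    "first_seizure_metrics",
    "threshold_sweep",
]

_MIN_DURATION = {"amplitude": 30.0, "band_power": 20.0}
_SERIES_KIND = {"amplitude": "rms_amplitude", "band_power": "band_power"}


@dataclass(frozen=True)
class DetectConfig:
    mode: str = "amplitude"  # or "band_power"
    threshold_x: float = 5.0
    min_duration_s: float | None = None  # default: 30 s amplitude, 20 s power
    merge_gap_s: float = 0.0
    analysis_start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MIN_DURATION:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.threshold_x > 1:
            raise ValueError("threshold_x must exceed 1 (units: multiples of baseline)")

    @property
    def effective_min_duration_s(self) -> float:
        return self.min_duration_s if self.min_duration_s is not None else _MIN_DURATION[self.mode]


@dataclass(frozen=True)
class SeizureEvent:
    onset_s: float
    offset_s: float
    mode: str
    threshold_x: float
    peak_value: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class FirstSeizureSummary:
    """Characteristics of the first detected seizure.

    ``status`` is ``"no_seizure"`` (with all metrics None) when no event was
    detected — an explicit outcome, distinct from zero, because such animals
    were re-tested rather than scored 0.
    """

    status: str  # "seizure" | "no_seizure"
    latency_s: float | None = None
    duration_s: float | None = None
    mean_norm_amplitude: float | None = None
    mean_norm_beta_low_gamma_power: float | None = None
    time_to_iv_s: float | None = None


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def detect_seizures(series: NormalizedSeries, cfg: DetectConfig | None = None) -> list[SeizureEvent]:
    """Run the threshold/duration criterion on a normalized series."""
    cfg = cfg or DetectConfig()
    if not isinstance(series, NormalizedSeries):
        raise TypeError("detection requires a baseline-normalized series")
    if series.kind != _SERIES_KIND[cfg.mode]:
        raise ValueError(
            f"mode {cfg.mode!r} requires series kind {_SERIES_KIND[cfg.mode]!r}, "
            f"got {series.kind!r}"
        )
    bw = series.bin_width_s
    min_bins = int(round(cfg.effective_min_duration_s / bw))
    if abs(min_bins * bw - cfg.effective_min_duration_s) > 1e-9:
        raise ValueError("min_duration_s must be a multiple of the bin width")
    supra = series.values >= cfg.threshold_x
    start_bin = int(np.ceil(cfg.analysis_start_s / bw - 1e-9))
    supra[:start_bin] = False
    runs = _runs(supra)
    if cfg.merge_gap_s > 0 and runs:
        gap_bins = int(cfg.merge_gap_s / bw)
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= gap_bins:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(r) for r in merged]
    events = []
    for s, e in runs:
        if e - s >= min_bins:
            events.append(
                SeizureEvent(
                    onset_s=s * bw,
                    offset_s=e * bw,
                    mode=cfg.mode,
                    threshold_x=cfg.threshold_x,
                    peak_value=float(series.values[s:e].max()),
                )
            )
    return events


def _check_sorted_disjoint(intervals: Sequence[tuple[float, float]]) -> None:
    prev = -np.inf
    for on, off in intervals:
        if off <= on:
            raise ValueError(f"empty or inverted interval [{on}, {off})")
        if on < prev:
            raise ValueError("intervals overlap or are unsorted")
        prev = off


def time_in_seizure(
    events: Sequence[SeizureEvent] | Sequence[tuple[float, float]],
    bin_width_s: float,
    duration_s: float,
) -> np.ndarray:
    """Percent of each bin covered by events; values in [0, 100].

    ``bin_width_s`` is typically 300 (5 min) or 600 (10 min).
    """
    ivals = [
        (ev.onset_s, ev.offset_s) if isinstance(ev, SeizureEvent) else (ev[0], ev[1])
        for ev in events
    ]
    ivals.sort()
    _check_sorted_disjoint(ivals)
    n_bins = int(np.ceil(duration_s / bin_width_s - 1e-9))
    out = np.zeros(n_bins)
    for on, off in ivals:
        if on >= duration_s:
            continue
        off = min(off, duration_s)
        b0 = int(on // bin_width_s)
        b1 = int(np.ceil(off / bin_width_s - 1e-12))
        for b in range(b0, b1):
            lo, hi = b * bin_width_s, (b + 1) * bin_width_s
            out[b] += max(0.0, min(off, hi) - max(on, lo))
    return out / bin_width_s * 100.0


def first_seizure_metrics(
    events: Sequence[SeizureEvent],
    amp_series: NormalizedSeries | None,
    power_series: NormalizedSeries | None,
    markers: Mapping[str, float],
) -> FirstSeizureSummary:
    """Latency, duration, mean normalized amplitude and beta-low gamma power
    of the first event; latency is measured from the KA injection."""
    if not events:
        return FirstSeizureSummary(status="no_seizure")
    if "ka_injection_s" not in markers:
        raise ValueError("ka_injection_s marker required for first-seizure latency")
    first = min(events, key=lambda e: e.onset_s)
    ka = markers["ka_injection_s"]

    def _mean_over(series: NormalizedSeries | None) -> float | None:
        if series is None:
            return None
        b0 = int(first.onset_s // series.bin_width_s)
        b1 = int(np.ceil(first.offset_s / series.bin_width_s - 1e-12))
        return float(series.values[b0:b1].mean())

    iv = markers.get("iv_injection_s")
    return FirstSeizureSummary(
        status="seizure",
        latency_s=first.onset_s - ka,
        duration_s=first.duration_s,
        mean_norm_amplitude=_mean_over(amp_series),
        mean_norm_beta_low_gamma_power=_mean_over(power_series),
        time_to_iv_s=(iv - ka) if iv is not None else None,
    )


class SweepResult(NamedTuple):
    events: list[SeizureEvent]
    time_in_seizure: np.ndarray


def threshold_sweep(
    series: NormalizedSeries,
    cfg: DetectConfig | None = None,
    thresholds: Sequence[float] = (3.0, 5.0, 10.0),
    tis_bin_s: float = 300.0,
    duration_s: float | None = None,
) -> dict[float, SweepResult]:
    """One detection pass per threshold.

    Per-bin time in seizure is non-increasing in the threshold, mirroring the
    robustness of drug effects to the threshold choice.
    """
    from dataclasses import replace

    cfg = cfg or DetectConfig()
    duration_s = duration_s if duration_s is not None else series.duration_s
    out: dict[float, SweepResult] = {}
    for th in thresholds:
        evs = detect_seizures(series, replace(cfg, threshold_x=th))
        out[th] = SweepResult(evs, time_in_seizure(evs, tis_bin_s, duration_s))
    return out
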