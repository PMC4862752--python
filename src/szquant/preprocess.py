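"""EEG preprocessing: filtering, baseline-window selection, binned RMS amplitude,
and baseline normalization.

All quantification downstream of this module operates on *normalized* series:
per-bin values expressed as multiples of the mean over a pre-injection baseline
window. This makes every threshold (3x, 5x, 10x baseline) gain-independent, so
differences in electrode impedance or amplifier gain between animals drop out.

Conventions
-----------
* Time is in seconds from recording start; intervals are half-open ``[on, off)``.
* Bins are non-overlapping, left-aligned at t=0; a final partial bin is dropped.
* The hardware chain applied a 500 Hz analog low-pass before 400 Hz
  digitization; that corner is above the digital Nyquist (200 Hz), so no
  software low-pass is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "FilterConfig",
    "BaselineWindow",
    "BinnedSeries",
    "NormalizedSeries",
    "apply_filters",
    "select_baseline",
    "rms_amplitude",
    "normalize_to_baseline",
]


@dataclass
class EEGRecording:
    """Single-channel hippocampal EEG trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples (arbitrary units; only ratios to baseline matter).
    fs : float
        Sampling rate in Hz (400 Hz in the standard acquisition).
    markers : dict
        Event times in seconds from recording start. Recognized keys:
        ``ka_injection_s`` (kainic-acid injection) and ``iv_injection_s``
        (i.v. vehicle/drug injection).
    """

    samples: np.ndarray
    fs: float
    markers: dict[str, float] = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        for key, t in self.markers.items():
            if not (0.0 <= t <= self.duration_s):
                raise ValueError(
                    f"marker {key}={t} outside recording [0, {self.duration_s}]"
                )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase filter chain: Butterworth high-pass + IIR notch.

    ``lowpass_hz`` is ``None`` by default (see module docstring).
    """

    highpass_hz: float = 1.0
    notch_hz: float | None = 60.0
    notch_q: float = 30.0
    lowpass_hz: float | None = None
    order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        for name, f in (
            ("highpass_hz", self.highpass_hz),
            ("notch_hz", self.notch_hz),
            ("lowpass_hz", self.lowpass_hz),
        ):
            if f is not None and not (0 < f < nyq):
                raise ValueError(
                    f"{name}={f} Hz must lie strictly between 0 and the "
                    f"Nyquist frequency {nyq} Hz at fs={fs} Hz"
                )


@dataclass(frozen=True)
class BaselineWindow:
    """Reference window for normalization: 120 s starting 800 s into the
    recording, optionally shifted by +/-60 s to dodge motion artifact."""

    start_s: float = 800.0
    length_s: float = 120.0
    shift_s: float = 0.0

    @property
    def effective_start_s(self) -> float:
        return self.start_s + self.shift_s

    @property
    def effective_end_s(self) -> float:
        return self.effective_start_s + self.length_s


@dataclass
class BinnedSeries:
    """Per-bin scalar series (RMS amplitude or band power)."""

    values: np.ndarray
    bin_width_s: float = 5.0
    kind: str = "rms_amplitude"  # or "band_power"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_width_s


@dataclass
class NormalizedSeries(BinnedSeries):
    """A :class:`BinnedSeries` expressed as multiples of its baseline mean."""

    baseline_mean: float = 1.0


def apply_filters(rec: EEGRecording, cfg: FilterConfig | None = None) -> EEGRecording:
    """Apply the zero-phase filter chain (forward-backward, no phase shift).

    High-pass removes DC and slow drift; the notch suppresses 60 Hz mains.
    Attenuation at the notch frequency exceeds 40 dB while passband loss at
    e.g. 20 Hz stays below 1 dB.
    """
    cfg = cfg or FilterConfig()
    cfg.validate(rec.fs)
    x = rec.samples
    sos = sps.butter(cfg.order, cfg.highpass_hz, btype="highpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    if cfg.notch_hz is not None:
        b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)
        x = sps.filtfilt(b, a, x)
    if cfg.lowpass_hz is not None:
        sos = sps.butter(cfg.order, cfg.lowpass_hz, btype="lowpass", fs=rec.fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    return EEGRecording(samples=x, fs=rec.fs, markers=dict(rec.markers), t0=rec.t0)


def select_baseline(
    rec: EEGRecording,
    win: BaselineWindow | None = None,
    artifact_mask: np.ndarray | None = None,
) -> BaselineWindow:
    """Pick the baseline window, shifting by 60 s if artifact was flagged.

    Candidates are tried in the order shift = 0, -60, +60 s; the first whose
    span is inside the recording, precedes the KA injection (when marked) and
    contains no flagged second is returned.

    Parameters
    ----------
    artifact_mask : ndarray of bool, optional
        One flag per second of recording (True = motion artifact). Artifact
        identification itself is an input here; in the original workflow it
        was done by visual inspection.
    """
    win = win or BaselineWindow()
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
    ka = rec.markers.get("ka_injection_s")
    tried = []
    for shift in (0.0, -60.0, 60.0):
        cand = replace(win, shift_s=shift)
        lo, hi = cand.effective_start_s, cand.effective_end_s
        if lo < 0 or hi > rec.duration_s:
            tried.append((shift, "outside recording"))
            continue
        if ka is not None and hi > ka:
            tried.append((shift, "overlaps KA injection"))
            continue
        if artifact_mask is not None:
            sec = np.arange(int(np.floor(lo)), int(np.ceil(hi)))
            sec = sec[sec < artifact_mask.size]
            if artifact_mask[sec].any():
                tried.append((shift, "artifact"))
                continue
        return cand
    raise ValueError(
        "no artifact-free baseline window among candidate shifts 0, -60, +60 s: "
        + "; ".join(f"{s:+g}s {why}" for s, why in tried)
    )


def rms_amplitude(rec: EEGRecording, bin_width_s: float = 5.0) -> BinnedSeries:
    """Root-mean-square amplitude per non-overlapping bin.

    ``value_b = sqrt(mean(x^2))`` over each ``bin_width_s`` bin; the trailing
    partial bin is dropped.
    """
    n_per = int(round(bin_width_s * rec.fs))
    if n_per < 1 or rec.samples.size < n_per:
        raise ValueError("recording shorter than one bin")
    n_bins = rec.samples.size // n_per
    x = rec.samples[: n_bins * n_per].reshape(n_bins, n_per)
    return BinnedSeries(np.sqrt(np.mean(x * x, axis=1)), bin_width_s, "rms_amplitude")


def baseline_bin_slice(bin_width_s: float, win: BaselineWindow) -> slice:
    """Indices of bins lying entirely inside the baseline window."""
    i0 = int(np.ceil(win.effective_start_s / bin_width_s - 1e-9))
    i1 = int(np.floor(win.effective_end_s / bin_width_s + 1e-9))
    if i1 <= i0:
        raise ValueError("baseline window shorter than one bin")
    return slice(i0, i1)


def normalize_to_baseline(
    series: BinnedSeries, win: BaselineWindow | None = None
) -> NormalizedSeries:
    """Divide every bin by the mean over baseline-window bins.

    Idempotent: normalizing an already-normalized series returns it unchanged
    (its baseline mean is 1 by construction). Scale-invariant: multiplying the
    raw trace by any positive gain leaves the result unchanged.
    """
    win = win or BaselineWindow()
    sl = baseline_bin_slice(series.bin_width_s, win)
    if sl.stop > series.n_bins:
        raise ValueError("baseline window extends beyond the series")
    m = float(np.mean(series.values[sl]))
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"degenerate baseline mean {m}; cannot normalize")
    return NormalizedSeries(
        values=series.values / m,
        bin_width_s=series.bin_width_s,
        kind=series.kind,
        baseline_mean=m,
    )
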