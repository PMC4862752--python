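"""Per-bin power spectral density, 1 Hz aggregation, band power, and
per-frequency baseline normalization.

The PSD is computed by FFT over each non-overlapping 5 s bin with a
rectangular window (no taper) and one-sided density scaling, so that
``sum(power) * df`` equals the bin's mean squared value (Parseval). At 400 Hz
a 5 s bin holds 2000 samples, giving a native resolution of 0.2 Hz; no
zero-padding is applied.

The 50-100 Hz range is excluded from analysis because a 60 Hz notch filter
sits inside it. Standard bands:

* delta-theta: 1-10 Hz
* beta-low gamma: 10-50 Hz (the primary electrographic seizure marker)
* ripple: 100-200 Hz
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BaselineWindow, BinnedSeries, EEGRecording, baseline_bin_slice

__all__ = [
    "Spectrogram",
    "BandDef",
    "BANDS",
    "EXCLUDED_HZ",
    "compute_psd",
    "aggregate_1hz",
    "band_power",
    "normalize_spectrogram",
]

#: Frequency range contaminated by the 60 Hz notch; never analyzed.
EXCLUDED_HZ = (50.0, 100.0)


@dataclass(frozen=True)
class BandDef:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low {self.low_hz} >= high {self.high_hz}")
        lo, hi = EXCLUDED_HZ
        if max(self.low_hz, lo) < min(self.high_hz, hi):
            raise ValueError(
                f"band {self.name} ({self.low_hz}-{self.high_hz} Hz) intersects "
                f"the excluded {lo}-{hi} Hz range"
            )


BANDS: dict[str, BandDef] = {
    "delta_theta": BandDef("delta_theta", 1.0, 10.0),
    "beta_low_gamma": BandDef("beta_low_gamma", 10.0, 50.0),
    "ripple": BandDef("ripple", 100.0, 200.0),
}


@dataclass
class Spectrogram:
    """Per-bin one-sided PSD. ``power[i, b]`` is the density at ``freqs[i]``
    in time bin ``b``; ``df`` is the frequency spacing so ``power * df``
    integrates to power."""

    freqs: np.ndarray
    power: np.ndarray  # shape (n_freqs, n_bins)
    bin_width_s: float
    df: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape[0] != self.freqs.size:
            raise ValueError("power rows must match freqs")

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


def compute_psd(rec: EEGRecording, bin_width_s: float = 5.0) -> Spectrogram:
    """One PSD per non-overlapping bin (rectangular window, one-sided)."""
    n_per = int(round(bin_width_s * rec.fs))
    if n_per < 2:
        raise ValueError("bin must hold at least 2 samples")
    n_bins = rec.samples.size // n_per
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    x = rec.samples[: n_bins * n_per].reshape(n_bins, n_per)
    X = np.fft.rfft(x, axis=1)
    # One-sided density: |X|^2 / (fs * N), doubled except DC and Nyquist.
    psd = (np.abs(X) ** 2) / (rec.fs * n_per)
    psd[:, 1:] *= 2.0
    if n_per % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n_per, d=1.0 / rec.fs)
    return Spectrogram(freqs=freqs, power=psd.T, bin_width_s=bin_width_s, df=rec.fs / n_per)


def aggregate_1hz(spec: Spectrogram) -> Spectrogram:
    """Sum spectral power into contiguous 1 Hz bins ``[k, k+1)``.

    Total power is conserved. The result stores integrated power per 1 Hz
    bin, which with ``df = 1`` is numerically identical to a density.
    """
    if spec.df > 1.0:
        raise ValueError(f"native resolution {spec.df} Hz coarser than 1 Hz")
    edges_lo = np.floor(spec.freqs).astype(int)
    kmax = edges_lo.max()
    out = np.zeros((kmax + 1, spec.n_bins))
    np.add.at(out, edges_lo, spec.power * spec.df)
    return Spectrogram(
        freqs=np.arange(kmax + 1, dtype=float),
        power=out,
        bin_width_s=spec.bin_width_s,
        df=1.0,
    )


def band_power(spec: Spectrogram, band: BandDef | str) -> BinnedSeries:
    """Integrated power over ``[low, high)`` per time bin.

    Bands crossing the excluded 50-100 Hz range are rejected (the
    :class:`BandDef` constructor enforces this).
    """
    if isinstance(band, str):
        band = BANDS[band]
    mask = (spec.freqs >= band.low_hz) & (spec.freqs < band.high_hz)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency samples")
    vals = (spec.power[mask] * spec.df).sum(axis=0)
    return BinnedSeries(values=vals, bin_width_s=spec.bin_width_s, kind="band_power")


def normalize_spectrogram(
    spec: Spectrogram, win: BaselineWindow | None = None
) -> Spectrogram:
    """Divide each frequency row by its own baseline-window mean.

    Per-frequency normalization is what the heat-map spectrograms use; the
    scalar per-band normalization used for threshold series is obtained by
    passing :func:`band_power` output through
    :func:`szquant.preprocess.normalize_to_baseline` instead.
    """
    win = win or BaselineWindow()
    sl = baseline_bin_slice(spec.bin_width_s, win)
    if sl.stop > spec.n_bins:
        raise ValueError("baseline window extends beyond the spectrogram")
    base = spec.power[:, sl].mean(axis=1)
    bad = ~(base > 0)
    if bad.any():
        raise ValueError(
            f"zero baseline power at {int(bad.sum())} frequencies "
            f"(first at {spec.freqs[bad][0]:g} Hz); cannot normalize"
        )
    return Spectrogram(
        freqs=spec.freqs.copy(),
        power=spec.power / base[:, None],
        bin_width_s=spec.bin_width_s,
        df=spec.df,
    )
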