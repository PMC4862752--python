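"""Per-bin power spectra, beta-low gamma band power, and power-based
seizure detection.

The beta-low gamma band (10-50 Hz) is the primary electrographic seizure
marker; power exceeding 5x baseline for 20 s counts as a seizure. The
50-100 Hz range is never analyzed (60 Hz notch).
"""

import numpy as np

import szquant as sz

params = sz.SynthEEGParams(
    duration_s=2400.0, ka_injection_s=1200.0, escalation_onset_s=1800.0, seed=3
)
rec, truth = sz.generate_eeg(params)
filtered = sz.apply_filters(rec)
window = sz.select_baseline(filtered)

spec = sz.compute_psd(filtered)  # one PSD per 5 s bin, 0.2 Hz native grid
blg = sz.normalize_to_baseline(sz.band_power(spec, "beta_low_gamma"), window)
events = sz.detect_seizures(
    blg, sz.DetectConfig(mode="band_power", threshold_x=5.0, analysis_start_s=1200.0)
)
print(f"power-based detection: {len(events)} events (5x baseline power for >=20 s)")

norm = sz.normalize_spectrogram(sz.aggregate_1hz(spec), window)
for name in ("delta_theta", "beta_low_gamma", "ripple"):
    band = sz.BANDS[name]
    rows = (norm.freqs >= band.low_hz) & (norm.freqs < band.high_hz)
    post = norm.power[rows][:, 240:]  # bins after KA injection
    print(f"{name:15s} mean power {post.mean():5.1f}x baseline after KA")
# Values are fold-changes over each frequency's own baseline mean: the
# injected 10-50 Hz oscillation drives the beta-low gamma rise, while broad-
# band amplitude scaling lifts the other ranges more modestly.
baseline_bins = norm.power[:, 160:184]
print(f"baseline self-check: mean {baseline_bins.mean():.3f}x (should be ~1)")
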