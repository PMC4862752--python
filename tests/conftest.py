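import numpy as np
import pytest

import szquant as sz


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down protocol: 20 min baseline, KA at 1200 s, escalation at
    1800 s, 40 min total. Keeps full structural fidelity (baseline window at
    800-920 s, discrete then merging seizures) at ~1/4 the default length."""
    return sz.SynthEEGParams(
        duration_s=2400.0, ka_injection_s=1200.0, escalation_onset_s=1800.0, seed=7
    )


@pytest.fixture(scope="session")
def small_subject(small_params):
    """Generated recording + truth + normalized amplitude/power series."""
    rec, truth = sz.generate_eeg(small_params)
    filt = sz.apply_filters(rec)
    win = sz.select_baseline(filt)
    amp = sz.normalize_to_baseline(sz.rms_amplitude(filt), win)
    spec = sz.compute_psd(filt)
    blg = sz.normalize_to_baseline(sz.band_power(spec, "beta_low_gamma"), win)
    return {
        "params": small_params,
        "rec": rec,
        "truth": truth,
        "filt": filt,
        "win": win,
        "amp": amp,
        "spec": spec,
        "blg": blg,
    }


def make_normalized(values, bin_width_s=5.0, kind="rms_amplitude"):
    return sz.NormalizedSeries(
        values=np.asarray(values, dtype=float), bin_width_s=bin_width_s, kind=kind
    )
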