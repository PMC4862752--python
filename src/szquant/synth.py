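"""Synthetic EEG, behavior and microdialysis generators with ground truth.

These generators emulate the statistical structure of hippocampal recordings
in the kainic-acid (KA) status-epilepticus model so that every downstream
stage — normalization, threshold detection, SE state machines, EEG-behavior
cross-correlation, dialysis time courses — can be tested against known
ground truth without animal data.

The emulated recording: 20 min of quiet baseline, KA injection, discrete
electrographic seizures with elevated RMS amplitude and added 10-50 Hz
(beta-low gamma) oscillation that appear as a renewal process, then a
*merging* phase in which inter-seizure gaps shrink and seizures lengthen
until activity is nearly continuous. A ``drug_effect`` parameter in [0, 1]
attenuates the merging-phase escalation (1 = escalation fully suppressed),
standing in for aromatase-inhibitor treatment. Merging-phase seizures carry
a higher amplitude gain (1.5x the discrete-seizure gain), reflecting the
escalation of amplitude into severe merging activity that the 10x-baseline
electrographic-SE criterion is designed to capture.

Baseline EEG is 1/f^alpha Gaussian colored noise (alpha = 1 by default);
motion artifacts are brief high-amplitude broadband transients. All
randomness flows from one seeded generator per call; identical parameters
and seed give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .behavior import BehaviorTrace
from .dialysis import DialysisSample
from .preprocess import EEGRecording

__all__ = [
    "SynthEEGParams",
    "GroundTruth",
    "generate_eeg",
    "generate_behavior",
    "generate_dialysis",
]


@dataclass(frozen=True)
class SynthEEGParams:
    """Study-condition parameters for the EEG generator.

    Defaults follow the standard 2 h post-injection protocol: recording
    starts at t=0, KA at 1200 s (after 20 min of baseline), escalation into
    merging seizures from 4800 s (the second hour of testing), total 8400 s
    at 400 Hz.
    """

    duration_s: float = 8400.0
    fs: float = 400.0
    baseline_noise_exponent: float = 1.0
    seizure_rate: float = 10.0  # discrete events per hour after KA
    seizure_amp_gain: float = 8.0  # RMS multiple of baseline inside events
    seizure_band_low: float = 10.0
    seizure_band_high: float = 50.0
    ka_injection_s: float = 1200.0
    escalation_onset_s: float = 4800.0
    drug_effect: float = 0.0
    artifact_rate: float = 1.0  # transients per hour
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "fs", "seizure_rate", "artifact_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.fs > 2 * self.seizure_band_high:
            raise ValueError("fs must exceed twice the seizure band upper edge")
        if not 0.0 <= self.drug_effect <= 1.0:
            raise ValueError("drug_effect must lie in [0, 1]")
        if not self.duration_s > self.escalation_onset_s >= 0:
            raise ValueError("need duration_s > escalation_onset_s >= 0")
        if not 0 <= self.ka_injection_s < self.duration_s:
            raise ValueError("ka_injection_s must lie inside the recording")


@dataclass
class GroundTruth:
    """Injected-event labels accompanying a synthetic recording."""

    duration_s: float
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    se_intervals: list[tuple[float, float]] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    merging_intervals: list[tuple[float, float]] = field(default_factory=list)
    behavior_trace: BehaviorTrace | None = None

    def __post_init__(self) -> None:
        for name in ("seizure_intervals", "se_intervals", "artifact_intervals"):
            prev = -np.inf
            for on, off in getattr(self, name):
                if not (0 <= on < off <= self.duration_s + 1e-9):
                    raise ValueError(f"{name}: interval [{on}, {off}) outside recording")
                if on < prev:
                    raise ValueError(f"{name}: intervals overlap or unsorted")
                prev = off


def _colored_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    if alpha == 0:
        return white / white.std()
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    X *= f ** (-alpha / 2.0)
    x = np.fft.irfft(X, n=n)
    return x / x.std()


def _draw_intervals(
    rng: np.random.Generator, p: SynthEEGParams
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(discrete intervals, merging-phase intervals)."""
    discrete: list[tuple[float, float]] = []
    merging: list[tuple[float, float]] = []
    if p.seizure_rate <= 0:
        return discrete, merging
    mean_gap = 3600.0 / p.seizure_rate
    esc = max(p.escalation_onset_s, p.ka_injection_s)
    # Discrete phase: renewal process of Exp(mean_gap) gaps, 40-120 s events.
    t = p.ka_injection_s + rng.exponential(mean_gap)
    while t < min(esc, p.duration_s):
        dur = rng.uniform(40.0, 120.0)
        end = min(t + dur, esc, p.duration_s)
        if end - t >= 30.0:
            discrete.append((t, end))
        t = end + rng.exponential(mean_gap)
    # Merging phase: geometric gap shrinkage / duration growth, both
    # attenuated by the drug effect.
    if esc < p.duration_s:
        shrink = 0.7 ** (1.0 - p.drug_effect)
        growth = 1.3 ** (1.0 - p.drug_effect)
        dur_k, gap_k = 60.0, 60.0
        t = esc + rng.uniform(0.0, 30.0)
        while t < p.duration_s:
            dur = min(dur_k, 300.0) * rng.uniform(0.9, 1.1)
            end = min(t + dur, p.duration_s)
            if end - t >= 30.0:
                merging.append((t, end))
            t = end + max(gap_k * rng.uniform(0.9, 1.1), 5.0)
            dur_k *= growth
            gap_k *= shrink
    return discrete, merging


def _se_truth(merging: list[tuple[float, float]], max_gap: float = 120.0) -> list[tuple[float, float]]:
    """Ground-truth SE: merging-phase event clusters (gaps <= max_gap) at
    least 5 min long in which seizures cover at least 60% of the span."""
    clusters: list[list] = []  # [start, end, covered_seconds]
    for on, off in merging:
        if clusters and on - clusters[-1][1] <= max_gap:
            clusters[-1][1] = off
            clusters[-1][2] += off - on
        else:
            clusters.append([on, off, off - on])
    return [
        (a, b) for a, b, cov in clusters if b - a >= 300.0 and cov / (b - a) >= 0.6
    ]


def generate_eeg(params: SynthEEGParams) -> tuple[EEGRecording, GroundTruth]:
    """Generate a synthetic recording plus its ground truth."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs))
    x = _colored_noise(rng, n, p.baseline_noise_exponent)

    discrete, merging = _draw_intervals(rng, p)
    sos = sps.butter(
        4, [p.seizure_band_low, p.seizure_band_high], btype="bandpass", fs=p.fs, output="sos"
    )
    ramp_s = 2.0

    # Amplitude gains are defined on the >1 Hz analysis band: quantification
    # high-passes at 1 Hz, which discards part of the 1/f baseline power, so
    # the added oscillation is scaled by the baseline's high-pass retention
    # factor to make the *normalized* in-seizure amplitude land on the
    # configured multiple.
    hp = sps.butter(4, 1.0, btype="highpass", fs=p.fs, output="sos")
    i_ref = int(min(p.ka_injection_s, p.duration_s) * p.fs)
    ref = x[: max(i_ref, int(min(60.0 * p.fs, n)))]
    retention = float(np.clip(sps.sosfiltfilt(hp, ref).std(), 1e-6, None))

    def _inject(on: float, off: float, gain: float) -> None:
        i0, i1 = int(on * p.fs), int(off * p.fs)
        seg = i1 - i0
        if seg <= 0:
            return
        osc = sps.sosfilt(sos, rng.standard_normal(seg))
        osc /= max(osc.std(), 1e-12)
        env = np.ones(seg)
        nr = min(int(ramp_s * p.fs), seg // 2)
        if nr > 0:
            r = 0.5 * (1 - np.cos(np.linspace(0, np.pi, nr)))
            env[:nr] = r
            env[-nr:] = r[::-1]
        g = gain / np.sqrt(2.0)
        x[i0:i1] = x[i0:i1] * (1.0 + (g - 1.0) * env) + g * retention * env * osc

    for on, off in discrete:
        _inject(on, off, p.seizure_amp_gain)
    for on, off in merging:
        _inject(on, off, p.seizure_amp_gain * 1.5)

    artifacts: list[tuple[float, float]] = []
    if p.artifact_rate > 0:
        n_art = rng.poisson(p.artifact_rate * p.duration_s / 3600.0)
        for t0 in np.sort(rng.uniform(0.0, p.duration_s, size=n_art)):
            dur = rng.uniform(0.3, 1.0)
            i0, i1 = int(t0 * p.fs), min(int((t0 + dur) * p.fs), n)
            if i1 > i0:
                x[i0:i1] += 20.0 * rng.standard_normal(i1 - i0)
                if artifacts and t0 < artifacts[-1][1]:
                    artifacts[-1] = (artifacts[-1][0], max(artifacts[-1][1], t0 + dur))
                else:
                    artifacts.append((t0, min(t0 + dur, p.duration_s)))

    rec = EEGRecording(
        samples=x, fs=p.fs, markers={"ka_injection_s": p.ka_injection_s}
    )
    truth = GroundTruth(
        duration_s=p.duration_s,
        seizure_intervals=discrete + merging,
        se_intervals=_se_truth(merging),
        artifact_intervals=artifacts,
        merging_intervals=merging,
    )
    return rec, truth


def _in_intervals(t: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for on, off in intervals:
        mask |= (t >= on) & (t < off)
    return mask


def generate_behavior(
    truth: GroundTruth,
    mild_match_prob: float = 0.9,
    convulsive_match_prob: float = 0.3,
    seed: int = 0,
) -> BehaviorTrace:
    """Per-second Racine codes coupled to the electrographic ground truth.

    Mild limbic behaviors (staring, C-HW) occur inside electrographic seizure
    intervals with probability ``mild_match_prob`` per second; convulsive
    behaviors (Racine 3-5) are more loosely coupled, occurring inside
    intervals with the lower ``convulsive_match_prob`` and at a small base
    rate outside. During ground-truth SE intervals the trace alternates
    sustained convulsive blocks with short mild interludes, so the behavioral
    SE criterion (30 s uninterrupted Racine 3-5, gaps <= 2 min) is met.
    """
    if not 0 <= convulsive_match_prob <= 1 or not 0 <= mild_match_prob <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if not mild_match_prob > convulsive_match_prob:
        raise ValueError("mild coupling must exceed convulsive coupling")
    rng = np.random.default_rng(seed)
    n = int(round(truth.duration_s))
    t = np.arange(n, dtype=float)
    codes = np.full(n, "none", dtype="U4")

    in_se = _in_intervals(t, truth.se_intervals)
    in_sz = _in_intervals(t, truth.seizure_intervals) & ~in_se

    conv_codes = np.array(["3", "4", "5f", "5tc"])
    conv_p = [0.5, 0.3, 0.1, 0.1]
    mild_codes = np.array(["0", "1_2"])
    mild_p = [0.4, 0.6]

    # Outside any event: sparse spontaneous behaviors.
    out_mask = ~(in_se | in_sz)
    u = rng.random(n)
    v = rng.random(n)
    pick_mild = rng.choice(mild_codes, size=n, p=mild_p)
    pick_conv = rng.choice(conv_codes, size=n, p=conv_p)
    codes[out_mask & (u < 0.01)] = pick_mild[out_mask & (u < 0.01)]
    codes[out_mask & (u >= 0.01) & (v < 0.003)] = pick_conv[out_mask & (u >= 0.01) & (v < 0.003)]

    # Inside discrete seizures: tight mild coupling, loose convulsive coupling.
    mild_hit = in_sz & (u < mild_match_prob)
    codes[mild_hit] = pick_mild[mild_hit]
    conv_hit = in_sz & ~mild_hit & (v < convulsive_match_prob)
    codes[conv_hit] = pick_conv[conv_hit]

    # Inside SE, two layers reproduce the key coupling asymmetry:
    # convulsive behavior is a bout process that ignores the instantaneous
    # EEG (bouts spill over electrographic lulls and past the SE offset,
    # emulating extra-limbic convulsive activity loosely synced to the
    # hippocampus), while mild behavior in the remaining seconds tracks the
    # momentary merging-seizure events tightly.
    for on, off in truth.se_intervals:
        s = int(on)
        end = min(int(off), n)
        length = end - s
        if length <= 0:
            continue
        conv_mask = np.zeros(length, dtype=bool)
        onset_run = int(rng.integers(35, 61))
        conv_mask[:onset_run] = True
        pos = onset_run
        while pos < length:
            pos += int(rng.integers(20, 81))  # lull between convulsive bouts
            bout = int(rng.integers(2, 9))  # brief motor act (FLC/rear/fall)
            conv_mask[pos : pos + bout] = True
            pos += bout
        seg = np.full(length, "none", dtype="U4")
        seg[conv_mask] = rng.choice(conv_codes, size=int(conv_mask.sum()), p=conv_p)
        t_seg = np.arange(s, end, dtype=float)
        in_ev = _in_intervals(t_seg, truth.merging_intervals)
        mild_sel = ~conv_mask & in_ev & (rng.random(length) < mild_match_prob)
        seg[mild_sel] = rng.choice(mild_codes, size=int(mild_sel.sum()), p=mild_p)
        codes[s:end] = seg
        # convulsive overhang into the post-SE lull
        o_end = min(end + int(rng.integers(60, 181)), n)
        if o_end > end:
            tail = rng.random(o_end - end) < 0.5
            codes[end:o_end][tail] = rng.choice(conv_codes, size=int(tail.sum()), p=conv_p)
    return BehaviorTrace(codes=codes)


# Post-KA percent-of-baseline profiles per 30 min sample, by severity class.
# Mild seizures: small delayed rise; moderate: ~3x within the first 30 min;
# severe: already-high baseline and a flat (~1x) response.
_DIALYSIS_PROFILES = {
    "mild": ((1.0, 1.2, 1.6, 1.9), 1.0),
    "moderate": ((3.0, 3.2, 3.0, 2.8), 1.0),
    "severe": ((1.0, 1.05, 0.95, 1.0), 1.65),
}


def generate_dialysis(
    severity: str,
    baseline_pg_ml: float = 5.0,
    seed: int = 0,
    noise_cv: float = 0.10,
    n_baseline: int = 4,
) -> list[DialysisSample]:
    """30-min dialysate samples around KA with a severity-dependent E2 rise.

    ``baseline_pg_ml`` is the nominal basal dialysate concentration; the
    severe class scales it by 1.65 (severe animals start from elevated basal
    E2). ``noise_cv`` is multiplicative measurement noise; with ``noise_cv=0``
    post/baseline ratios equal the configured profile exactly.
    """
    if severity not in _DIALYSIS_PROFILES:
        raise ValueError(f"unknown severity {severity!r}; expected mild|moderate|severe")
    if baseline_pg_ml <= 0:
        raise ValueError("baseline concentration must be positive")
    profile, base_mult = _DIALYSIS_PROFILES[severity]
    rng = np.random.default_rng(seed)
    base = baseline_pg_ml * base_mult
    samples = []
    t = -30.0 * n_baseline
    for _ in range(n_baseline):
        conc = base * max(1.0 + rng.normal(0.0, noise_cv) if noise_cv else 1.0, 0.0)
        samples.append(DialysisSample(t, t + 30.0, conc, phase="baseline"))
        t += 30.0
    for mult in profile:
        conc = base * mult * max(1.0 + rng.normal(0.0, noise_cv) if noise_cv else 1.0, 0.0)
        samples.append(DialysisSample(t, t + 30.0, conc, phase="post_KA"))
        t += 30.0
    return samples
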