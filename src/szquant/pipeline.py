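"""End-to-end orchestration on a synthetic cohort.

``run_pipeline`` generates a two-group cohort (vehicle-like, drug-like), runs
the full electrographic + behavioral analysis per subject, and writes tidy
long-format tables, interval files, cohort statistics, optional plots, and a
machine-readable manifest to an output directory. Every number in the report
is reproducible from the manifest (config + seed + package version) alone.

All time coordinates are seconds from recording start with half-open
intervals ``[onset, offset)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import CATEGORIES, category_time, staring_latency
from .detect import DetectConfig, detect_seizures, first_seizure_metrics, time_in_seizure
from .dialysis import classify_severity
from .io import write_intervals
from .preprocess import (
    BaselineWindow,
    FilterConfig,
    apply_filters,
    normalize_to_baseline,
    rms_amplitude,
    select_baseline,
)
from .se import SEConfig, detect_behavioral_se, detect_electrographic_se, se_summary
from .spectral import BANDS, aggregate_1hz, band_power, compute_psd, normalize_spectrogram
from .stats import mixed_anova
from .synth import SynthEEGParams, generate_behavior, generate_eeg
from .xcorr import xcorr_zero_lag

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a synthetic-cohort run."""

    n_vehicle: int = 10
    n_drug: int = 10
    drug_effect: float = 0.8
    seed: int = 0
    eeg: SynthEEGParams = field(default_factory=SynthEEGParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    baseline: BaselineWindow = field(default_factory=BaselineWindow)
    detect_threshold_x: float = 5.0
    tis_bin_s: float = 300.0
    se: SEConfig = field(default_factory=SEConfig)
    mild_match_prob: float = 0.9
    convulsive_match_prob: float = 0.3
    make_plots: bool = True
    out_dir: str = "szquant_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in (("eeg", SynthEEGParams), ("filters", FilterConfig),
                         ("baseline", BaselineWindow), ("se", SEConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        def _enc(v):
            return dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v

        return {k: _enc(v) for k, v in dataclasses.asdict(self).items()}


def _analyze_subject(name: str, group: str, cfg: PipelineConfig, seed: int) -> dict:
    """Full per-subject analysis; returns intermediate products and metrics."""
    params = dataclasses.replace(
        cfg.eeg, seed=seed, drug_effect=cfg.drug_effect if group == "drug" else 0.0
    )
    rec, truth = generate_eeg(params)
    trace = generate_behavior(
        truth, cfg.mild_match_prob, cfg.convulsive_match_prob, seed=seed + 1
    )
    ka = rec.markers["ka_injection_s"]
    filt = apply_filters(rec, cfg.filters)

    mask = np.zeros(int(np.ceil(rec.duration_s)), dtype=bool)
    for on, off in truth.artifact_intervals:
        mask[int(on) : int(np.ceil(off))] = True
    win = select_baseline(filt, cfg.baseline, artifact_mask=mask)

    amp = normalize_to_baseline(rms_amplitude(filt), win)
    spec = compute_psd(filt)
    blg = normalize_to_baseline(band_power(spec, BANDS["beta_low_gamma"]), win)
    nspec = normalize_spectrogram(aggregate_1hz(spec), win)

    amp_cfg = DetectConfig(mode="amplitude", threshold_x=cfg.detect_threshold_x, analysis_start_s=ka)
    pow_cfg = DetectConfig(mode="band_power", threshold_x=cfg.detect_threshold_x, analysis_start_s=ka)
    amp_events = detect_seizures(amp, amp_cfg)
    pow_events = detect_seizures(blg, pow_cfg)

    return {
        "name": name,
        "group": group,
        "rec": rec,
        "truth": truth,
        "trace": trace,
        "win": win,
        "amp": amp,
        "blg": blg,
        "nspec": nspec,
        "amp_events": amp_events,
        "pow_events": pow_events,
        "first": first_seizure_metrics(amp_events, amp, blg, rec.markers),
        "beh_se": detect_behavioral_se(trace, cfg.se),
        "eeg_se": detect_electrographic_se(amp, cfg.se),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis on a synthetic cohort; write the report bundle.

    Returns the report as a dict of DataFrames / arrays, and writes CSV
    tables, interval files, a manifest and (optionally) plots to
    ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = [("veh%02d" % i, "vehicle", cfg.seed + 1000 * i) for i in range(cfg.n_vehicle)]
    subjects += [("drug%02d" % i, "drug", cfg.seed + 1000 * (cfg.n_vehicle + i)) for i in range(cfg.n_drug)]

    results = []
    for name, group, seed in subjects:
        try:
            results.append(_analyze_subject(name, group, cfg, seed))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed for subject {name}: {exc}") from exc

    dur = cfg.eeg.duration_s
    ka = cfg.eeg.ka_injection_s

    tis_rows, subj_rows, beh_rows, xc_rows = [], [], [], []
    for r in results:
        tis = time_in_seizure(r["amp_events"], cfg.tis_bin_s, dur)
        for b, v in enumerate(tis):
            tis_rows.append(
                dict(subject=r["name"], group=r["group"], metric="time_in_seizure_amp",
                     bin_start_s=b * cfg.tis_bin_s, value=v, unit="percent")
            )
        for cat in ("R1_5", "R1_2", "R3_5"):
            ct = category_time(r["trace"], cat, cfg.tis_bin_s)
            for b, v in enumerate(ct):
                beh_rows.append(
                    dict(subject=r["name"], group=r["group"], category=cat,
                         bin_start_s=b * cfg.tis_bin_s, value=v, unit="percent")
                )
        for sig, series in (("amplitude", r["amp"]), ("beta_low_gamma_power", r["blg"])):
            for label in ("staring", "C-HW", "FLC", "rear", "fall"):
                res = xcorr_zero_lag(series, r["trace"], label)
                xc_rows.append(
                    dict(subject=r["name"], group=r["group"], behavior=label,
                         signal=sig, r=res.r, n_bins=res.n_bins, valid=res.valid)
                )
        fs = r["first"]
        # second half of the post-KA window (the 2nd hour in the 2 h design)
        half = (dur - ka) / 2.0
        hour2 = tis[int((ka + half) // cfg.tis_bin_s) : int(dur // cfg.tis_bin_s)]
        subj_rows.append(
            dict(subject=r["name"], group=r["group"],
                 baseline_shift_s=r["win"].shift_s,
                 first_seizure_status=fs.status,
                 first_seizure_latency_s=fs.latency_s,
                 first_seizure_duration_s=fs.duration_s,
                 n_amp_events=len(r["amp_events"]),
                 n_power_events=len(r["pow_events"]),
                 severity=(classify_severity(r["trace"])
                           if r["trace"].n_seconds >= 7200 else None),
                 staring_latency_s=staring_latency(r["trace"]),
                 behavioral_se_total_s=sum(e.duration_s for e in r["beh_se"]),
                 electrographic_se_total_s=sum(e.duration_s for e in r["eeg_se"]),
                 late_epoch_time_in_seizure_pct=float(np.mean(hour2)) if hour2.size else None)
        )
        write_intervals(r["amp_events"], out / f"{r['name']}_amp_events.tsv")
        write_intervals(r["beh_se"] + r["eeg_se"], out / f"{r['name']}_se_episodes.tsv")

    tis_df = pd.DataFrame(tis_rows)
    beh_df = pd.DataFrame(beh_rows)
    xc_df = pd.DataFrame(xc_rows)
    subj_df = pd.DataFrame(subj_rows)

    beh_cohort = {r["name"]: r["beh_se"] for r in results}
    inc = se_summary(beh_cohort, cfg.tis_bin_s, horizon_s=dur, t_ref_s=ka)
    inc_df = pd.DataFrame(
        {"bin_start_s": np.arange(inc["incidence_per_bin"].size) * cfg.tis_bin_s,
         "behavioral_se_incidence": inc["incidence_per_bin"]}
    )

    # Drug x epoch mixed ANOVA on percent time in seizure (amplitude, 5x);
    # epochs are the two halves of the post-KA window (hours 1 and 2 in the
    # standard design), the contrast carrying the escalation effect.
    stats_out = {}
    half = (dur - ka) / 2.0
    anova_rows = []
    for r in results:
        for lo, label in ((ka, "early"), (ka + half, "late")):
            cov = time_in_seizure(
                [(max(e.onset_s, lo) - lo, min(e.offset_s, lo + half) - lo)
                 for e in r["amp_events"]
                 if e.onset_s < lo + half and e.offset_s > lo],
                half, half,
            )
            anova_rows.append(dict(subject=r["name"], group=r["group"], time=label,
                                   response=float(cov[0])))
    adf = pd.DataFrame(anova_rows)
    if min(cfg.n_vehicle, cfg.n_drug) >= 3:
        stats_out["time_in_seizure_mixed_anova"] = mixed_anova(adf)

    manifest = {"version": __version__, "config": cfg.to_manifest()}
    for df, fname in ((tis_df, "time_in_seizure.csv"), (beh_df, "behavior_time.csv"),
                      (xc_df, "xcorr.csv"), (subj_df, "subjects.csv"),
                      (inc_df, "se_incidence.csv")):
        df.to_csv(out / fname, index=False, float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, sort_keys=True)

    if cfg.make_plots:
        _make_plots(out, results, tis_df, inc_df, cfg)

    return {"subjects": subj_df, "time_in_seizure": tis_df, "behavior_time": beh_df,
            "xcorr": xc_df, "se_incidence": inc_df, "stats": stats_out,
            "manifest": manifest}


def _make_plots(out: Path, results, tis_df: pd.DataFrame, inc_df: pd.DataFrame,
                cfg: PipelineConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .behavior import RANK, max_stage_per_min

    # Normalized spectrogram heat map for the first subject.
    r = results[0]
    fig, ax = plt.subplots(figsize=(8, 3))
    ns = r["nspec"]
    keep = ns.freqs <= 200
    im = ax.imshow(
        np.log10(np.maximum(ns.power[keep], 1e-3)), aspect="auto", origin="lower",
        extent=[0, ns.n_bins * ns.bin_width_s, ns.freqs[keep][0], ns.freqs[keep][-1] + 1],
        cmap="magma",
    )
    fig.colorbar(im, ax=ax, label="log10 power / baseline")
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)", title=r["name"])
    fig.savefig(out / "spectrogram.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for grp, c in (("vehicle", "tab:blue"), ("drug", "tab:orange")):
        sub = tis_df[tis_df.group == grp]
        g = sub.groupby("bin_start_s")["value"]
        m, s = g.mean(), g.sem().fillna(0)
        ax.errorbar(m.index / 60, m, yerr=s, color=c, label=grp, capsize=2)
    ax.set(xlabel="time (min)", ylabel="% time in seizure (5x amplitude)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "time_in_seizure.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.step(inc_df["bin_start_s"] / 60, inc_df["behavioral_se_incidence"] * 100, where="post")
    ax.set(xlabel="time (min)", ylabel="% rats in behavioral SE", ylim=(0, 100))
    fig.tight_layout()
    fig.savefig(out / "se_incidence.png", dpi=110)
    plt.close(fig)

    heat = np.array([[RANK[c] for c in max_stage_per_min(r["trace"])] for r in results])
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(heat, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set(xlabel="minute", ylabel="subject", title="max Racine stage per minute")
    fig.tight_layout()
    fig.savefig(out / "behavior_heatmap.png", dpi=110)
    plt.close(fig)
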