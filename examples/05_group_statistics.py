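"""Cohort statistics on pipeline outputs: mixed ANOVA, post-hoc t tests,
chi-square on stage attainment, Cohen's d and Newman-Keuls.

Runs the end-to-end pipeline on a small synthetic cohort (3 vehicle-like,
3 drug-like subjects, scaled 40 min protocol) and analyzes the report.
"""

import numpy as np

import szquant as sz
from szquant.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    n_vehicle=3, n_drug=3, drug_effect=0.8, seed=11,
    eeg=sz.SynthEEGParams(duration_s=2400.0, ka_injection_s=1200.0,
                          escalation_onset_s=1800.0),
    make_plots=False, out_dir="scratch/example_run",
)
report = run_pipeline(cfg)

anova = report["stats"]["time_in_seizure_mixed_anova"]
inter = anova["interaction"]
print(f"drug x epoch interaction: F({inter['df1']:.0f},{inter['df2']:.0f}) = "
      f"{inter['F']:.2f}, p = {inter['p']:.4f}")
# A significant interaction means the escalation from the early to the late
# epoch differs between groups — the drug-effect signature.

subj = report["subjects"]
veh = subj[subj.group == "vehicle"]["late_epoch_time_in_seizure_pct"].to_numpy()
drg = subj[subj.group == "drug"]["late_epoch_time_in_seizure_pct"].to_numpy()
print(f"late-epoch time in seizure: vehicle {veh.mean():.1f}%, drug {drg.mean():.1f}%")
tt = sz.posthoc_ttests([(veh, drg)])[0]
print(f"post-hoc t test: t = {tt['t']:.2f}, Bonferroni p = {tt['p_adj']:.3f}")
print(f"Cohen's d = {sz.cohens_d(veh, drg):.2f}")

xc = report["xcorr"]
amp_xc = xc[(xc.signal == "amplitude") & xc.valid]
groups, labels = [], []
for label, g in amp_xc.groupby("behavior"):
    if len(g) >= 2:
        groups.append(g["r"].to_numpy())
        labels.append(label)
print("mean EEG-behavior r by behavior:",
      {l: round(float(np.mean(g)), 2) for l, g in zip(labels, groups)})
if len(groups) >= 3:
    n_reject = sum(r["reject"] for r in sz.newman_keuls(groups, labels=labels))
    print(f"Newman-Keuls: {n_reject} behavior pairs significantly different")
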