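"""Behavioral and electrographic status-epilepticus detection.

Behavioral SE: Racine 3-5 behaviors uninterrupted for 30 s, sustained while
gaps stay under 2 min. Electrographic SE: amplitude >=10x baseline for 30 s,
ending after 30 s below 3x (hysteresis).
"""

import szquant as sz

params = sz.SynthEEGParams(
    duration_s=2400.0, ka_injection_s=1200.0, escalation_onset_s=1800.0, seed=7
)
rec, truth = sz.generate_eeg(params)
trace = sz.generate_behavior(truth, seed=8)

beh = sz.detect_behavioral_se(trace)
print("behavioral SE episodes:")
for e in beh:
    print(f"  [{e.onset_s:7.1f}, {e.offset_s:7.1f}) s ({e.duration_s:.0f} s)")

filtered = sz.apply_filters(rec)
amp = sz.normalize_to_baseline(sz.rms_amplitude(filtered), sz.select_baseline(filtered))
eeg = sz.detect_electrographic_se(amp)
print("electrographic SE episodes:")
for e in eeg:
    print(f"  [{e.onset_s:7.1f}, {e.offset_s:7.1f}) s ({e.duration_s:.0f} s)")

print(f"ground-truth SE spans: {[(round(a), round(b)) for a, b in truth.se_intervals]}")

summary = sz.se_summary({"rat1": beh}, bin_width_s=300.0,
                        horizon_s=params.duration_s, t_ref_s=1200.0)
lat = summary["latency_s"]["rat1"]
print(f"latency from KA to behavioral SE: {lat:.0f} s; "
      f"total SE time {summary['total_time_s']['rat1']:.0f} s")
# Both machines should bracket the generator's merging phase; the behavioral
# episode can outlast the electrographic one because convulsive bouts spill
# into electrographic lulls.
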