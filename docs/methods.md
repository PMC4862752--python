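# Methods

This note documents the quantitative model behind `szquant`: what each stage
assumes, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Baseline normalization

All electrographic quantities are expressed as multiples of the mean over a
reference window: 120 s beginning 800 s after recording start, a period of
quiet rest before KA injection. When motion artifact is flagged inside the
window (artifact identification is an *input* — originally visual
inspection — not something this package attempts), candidate shifts are
tried in the order 0, −60, +60 s and the first clean window that also
precedes the KA marker is used; if all three are contaminated the call fails
loudly rather than silently picking a dirty baseline.

Normalization uses the **mean** (not median) of baseline bins; this is the
reading under which "5× baseline amplitude" is a single scalar multiple.
Two properties follow and are property-tested: idempotence
(normalizing twice changes nothing) and gain invariance (rescaling the raw
trace by any positive constant leaves every normalized value, and hence
every detection, unchanged).

## Filtering

Zero-phase (forward–backward) Butterworth order-4 high-pass at 1 Hz plus an
IIR notch at 60 Hz with Q = 30. The filter family and Q are package choices;
only the corner frequencies are part of the protocol. No software low-pass
is applied by default: the acquisition chain's 500 Hz analog low-pass lies
above the 200 Hz Nyquist frequency of the 400 Hz digitized record, so it
cannot and need not be reproduced digitally. Because the notch makes
50–100 Hz untrustworthy, that range is excluded from every analysis; bands
crossing it are rejected at construction.

## Spectra and band power

PSDs are computed per non-overlapping 5 s bin by FFT with a rectangular
window (none is part of the protocol; rectangular keeps Parseval exact:
∑ PSD·Δf equals the bin's mean square to machine precision) and one-sided
density scaling. At 400 Hz a bin holds 2000 samples → 0.2 Hz native
resolution, no zero-padding. For display/heat-maps the grid is aggregated
into 1 Hz bins [k, k+1), conserving total power.

Normalization ambiguity: heat-map spectrograms are normalized
**per frequency** (each row by its own baseline mean), while the
threshold-detection series uses a **scalar** per-band baseline (band power
summed first, then normalized) — the "power exceeding 5× baseline" criterion
presumes a scalar. Both are provided; they are not interchangeable.

## Seizure detection

A seizure is a maximal run of consecutive bins at or above `threshold_x`
(ties count as supra-threshold) lasting at least the minimum duration —
30 s (6 bins) for amplitude, 20 s (4 bins) for β–low γ power. Durations are
bin-quantized; no sub-threshold dips are tolerated inside a run unless
`merge_gap_s` is explicitly set (default 0 — no merge rule is part of the
protocol). Bins before `analysis_start_s` (normally the KA injection) are
excluded so baseline bins can never self-detect. The detector is tested for
exact agreement with a brute-force run-length scan on random step traces,
and the threshold sweep (3×/5×/10×) is checked for per-bin monotonicity of
time-in-seizure.

## Status epilepticus state machines

*Behavioral*: opens at the start of the first ≥30 s run of contiguous
Racine 3–5 seconds ("uninterrupted" is strict — one second of any other code
breaks an onset run); any later Racine 3–5 activity within 120 s sustains
the episode; the offset is the end of the **last** Racine 3–5 second, i.e.
the silent ≤2 min tail is not counted as SE (the definition is ambiguous on
this; excluding it is the package's choice and is configurable by post-hoc
extension of episodes).

*Electrographic*: on normalized amplitude, opens at the start of a ≥30 s run
≥10×; closes at the **start** of the first ≥30 s run <3×; values in
[3×, 10×) sustain. These parameters capture severe merging seizures without
classifying earlier isolated (~5×–8×) seizures as SE. Both machines are
verified against independent per-second/per-bin simulations.

SE latency is reported relative to the KA injection, consistent with
first-seizure latency.

## EEG–behavior cross-correlation

Behavior is binarized per 5 s bin — present if **any** scored second in the
bin carries the label (a majority rule is available) — and Pearson's r is
computed at lag 0 against the binned normalized EEG series. Bins outside a
behavior's scoring horizon are excluded pairwise. Zero variance yields an
explicitly flagged invalid result, never a silent r = 0. Raw r is reported
(per-animal coefficients are what enter group comparisons); a Fisher-z
transform is exposed as a property on the result for users who prefer it.

## Microdialysis and immunoassay

The 4PL calibration y = d + (a−d)/(1+(x/c)^b) is fit by least squares in a
(a, log b, log c, d) parameterization, which enforces c > 0 and pins the
curve direction; initial values come from the extreme responses, a
logit-vs-log-concentration slope, and the geometric-mean concentration.
Noiseless curves are recovered to ~1e-14 relative error; inversion rejects
responses at or beyond the asymptotes. Standards follow the 6-point
2.5-fold dilution from 200 to 2.048 pg/ml.

Unit conversion uses the estradiol molar mass 272.38 g/mol
(pM = pg/ml ÷ 272.38 × 1000), e.g. 16.7 pg/ml → 61.3 pM and
30.0 pg/ml → 110.1 pM to one decimal. One commonly quoted basal pair
(6.3 pg/ml, 23.3 pM) is inconsistent with this constant at one decimal (it
gives 23.1) — presumably rounding of an unrounded mean — and is documented
here rather than asserted in tests. Recovery-corrected tissue
estimates divide dialysate concentration by the recovery fraction; because
in vitro recovery (~30%) was measured without carrier protein it is a
*maximum*, so tissue estimates are lower bounds. Percent-baseline series are
per-subject ratios formed before any group averaging. Severity classes use
time in Racine 1–5 over the 2 h horizon with boundaries [0, 30) min mild,
[30, 90] moderate, (90, ∞) severe; the closed 30 and 90 min boundaries are a
package decision (the source range notation carries no bracket convention).
Assay CVs use the sample SD (ddof = 1) per level, averaged across levels in
range.

## Histology

Stack volume is xy² × z (450 × 450 × 5 µm → 1.0125 × 10⁶ µm³;
z = 10 µm → 2.025 × 10⁶ µm³). Densities are pooled **within** animal — sum
of counts over sum of volume per subject × subregion, scaled to cells per
10⁶ µm³ — then averaged across animals (n = animals). Pooling order matters
when stack volumes differ and sum/sum is the package's choice; the test
suite carries a constructed counterexample separating the two orders.

## Group statistics

Mixed (drug × time) ANOVA and ANCOVA are delegated to pingouin and verified
against closed-form sums-of-squares / nested-OLS oracles; sphericity
corrections are off (two within-levels make them moot, and classical
uncorrected df are reported). Post-hoc unpaired t tests default to pooled
variance with Bonferroni adjustment p_adj = min(1, k·p). χ² is Pearson's
without continuity correction by default. Newman–Keuls is implemented
directly: means ordered, each pair tested against the studentized-range
quantile for its span (scipy's numerical distribution, not table lookup) at
the one-way error df, harmonic-mean n for unbalanced groups, with the
standard stepwise blocking rule. Note one caveat inherited from the design
it implements: with an orthogonal covariate, ANCOVA's F for the group effect
does *not* equal the plain ANOVA F — the error df differ (N−3 vs N−2) — so
equivalence tests are written against the nested-model oracle, not the
unadjusted F.

The adaptive sample-size rule used in the original workflow (analyze at
n≈4–5, extend if p < 0.2) affects realized error rates; it is documented
here but deliberately not modeled. Type-I calibration of the interaction
test is instead verified on null synthetic cohorts (5% ± 2% over 1000
simulations at n = 8/group).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
seizure biophysics:

* **Baseline**: 1/f^α Gaussian colored noise, α = 1 (the baseline EEG is not
  otherwise characterized statistically); artifacts are 0.3–1 s broadband
  transients at ~20× RMS, too brief to satisfy any duration criterion.
* **Discrete seizures** (KA → escalation onset): a renewal process with
  exponential gaps (rate 10/h by default), 40–120 s durations, amplitude
  gain 8× baseline, half broadband scaling and half added 10–50 Hz
  band-limited oscillation. Gains are defined on the >1 Hz analysis band:
  because quantification high-passes at 1 Hz (discarding part of the 1/f
  baseline power), the added oscillation is scaled by the baseline's
  high-pass retention factor so the *normalized* in-seizure amplitude lands
  on the configured multiple. The realized multiple still scatters ~±15%
  with the slow 1/f noise-level drift.
* **Merging phase** (after `escalation_onset_s`): durations grow by
  1.3^(1−drug_effect) and gaps shrink by 0.7^(1−drug_effect) per event —
  geometric shrinkage is the simplest process producing individual seizures
  that coalesce — with a 1.5× amplitude gain (12× baseline by default) so
  the 10× electrographic-SE criterion is exercised. `drug_effect` = 1
  freezes escalation entirely. Ground-truth SE spans are merging-event
  clusters ≥5 min long with ≤2 min gaps and ≥60% seizure coverage.
* **Behavior**: mild limbic codes (staring, C-HW) occur inside
  electrographic seizure intervals with probability `mild_match_prob`
  (default 0.9) per second; convulsive codes couple loosely
  (`convulsive_match_prob`, default 0.3). Inside SE spans, convulsive
  behavior is a sparse bout process — a 35–60 s uninterrupted onset run,
  then 2–8 s motor acts separated by 20–80 s lulls, with overhang past the
  SE offset — deliberately ignoring the instantaneous EEG, while mild codes
  fill remaining seconds tracking the momentary merging events. This
  reproduces the key asymmetry (mild behaviors are sustained states tightly
  synced to hippocampal activity; convulsions are brief, loosely timed
  extra-limbic acts) that makes r(C-HW) > r(FLC).
* **Dialysis**: 30 min samples with severity profiles per sample relative to
  baseline — mild (1.0, 1.2, 1.6, 1.9): a small delayed rise; moderate
  (3.0, 3.2, 3.0, 2.8): a threefold rise within the first post-KA sample;
  severe (≈1.0 throughout) with a 1.65× elevated baseline. Multiplicative
  noise CV 0.10 by default; zero noise gives the profiles exactly. Inter-
  seizure interval distributions and these noise levels are generator
  choices, not estimates from data.

What passing tests therefore show: the *operations* (normalization,
detection, state machines, correlations, calibrations, statistics) are
correct on data with exactly the assumed structure. They do not show
robustness to real-world features the generator omits: electrode drift and
chewing artifact spectra, non-stationary 1/f slopes, spike-wave morphology,
observer noise in Racine scoring, assay matrix effects, or pharmacokinetics
of the inhibitors.

## Problem sizes and determinism

Unit and property tests use a structurally complete 2400 s protocol
(baseline window at 800–920 s, KA at 1200 s, escalation at 1800 s); the
acceptance suite runs detector recall/precision on the full default 8400 s
protocol over 10 seeds, cross-correlation structure over 20 seeds, 4PL
recovery over 100 draws, and ANOVA calibration over 1000 null cohorts —
sizes chosen to estimate each quantity stably. Every stochastic component
draws from one seeded `numpy` generator per call; identical configuration
and seed give bitwise-identical traces, tables and reports. All time
coordinates are seconds from recording start with half-open [onset, offset)
intervals.

## Known limitations

* Artifact *detection* is out of scope; masks are caller-supplied.
* EDF files can be read (optional `mne` dependency) but output is delimited
  text only.
* The behavioral-SE offset convention (excluding the silent tail) and the
  severity-boundary brackets are documented choices; alternative conventions
  change totals by bounded, predictable amounts.
* Electrographic SE episodes left open at the end of a recording are closed
  at the recording edge.
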