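# Methods

## The score and the clinical problem

The reverse shock index multiplied by the Glasgow Coma Scale,
rSIG = (SBP/HR)·GCS, is a bedside severity score for trauma: shock
depresses SBP and raises HR, brain injury depresses GCS, and all three
push rSIG down. It is dimensionless; in a healthy school-age child
SBP ≈ HR and GCS = 15, so rSIG sits near 15–20, while a child in
decompensated shock with deep coma scores in the low single digits.

Pediatric vital-sign norms drift with age — SBP rises, HR falls — so the
survivor rSIG distribution shifts upward by roughly a factor of two
between infancy and late adolescence. A triage rule built on one cutoff
therefore cannot hit sensible operating points across 0–18 years. The
package's job is to (a) find age bands within which one cutoff is
adequate, and (b) derive the cutoff per band.

## Cleaning and the analysis dataset

Implausible vitals (SBP outside [30, 300] mmHg, HR outside [30, 200] bpm)
are converted to missing, not dropped, and tallied; the bounds themselves
are retained (the plausibility rule is a strict inequality). GCS entries
outside 3–15 are handled the same way — the admissible range is part of
the scale's definition, and an out-of-range entry is a recording error
indistinguishable from a missing value. Rows are then excluded for:
age > 18 completed years; non-trauma mechanism (only when a whitelist is
supplied — the synthetic generator emits trauma mechanisms only);
a truthy optional `dead_on_arrival`/`transfer_out` column (absent columns
mean no exclusion, since registries differ in whether they carry these
fields); arrival more than 360 minutes after injury; missing outcome; and
missing SBP/HR/GCS. The exclusion log reconciles exactly:
`n_in = n_out + rows dropped`, with field conversions counted separately.

## Partition search

All contiguous partitions of integer ages 0–18 (inclusive band ends,
completed years) into k = 2 or 3 bands are enumerated — 18 and 153
candidates. Each is scored by a logistic regression of death on rSIG with
a separate intercept and slope per band. Because parameters do not cross
bands, the model factorizes into independent per-band fits; the total
log-likelihood is their sum, AIC = 2·(2k) − 2·log L, and the AUC is the
rank (Mann–Whitney) AUC of the pooled fitted probabilities. This is the
simplest model in which the choice of partition changes both fit and
discrimination; the scoring function is a plain function of
(records, partition) and can be swapped.

Per-band fits use Newton/IRLS on the standardized predictor, relative
log-likelihood tolerance 1e-8, at most 100 iterations, with step-halving.
With a handful of deaths per band, complete separation (all death rSIG
below all survivor rSIG) is a live possibility and leaves the MLE
divergent; such bands fall back to Firth's penalized likelihood
(Jeffreys-prior score correction), which always has a finite maximizer,
and the band is flagged in the score. AIC then uses the *unpenalized*
log-likelihood evaluated at the penalized estimate — a pragmatic choice
that keeps AIC comparable across partitions; flagged scores should be
interpreted cautiously, which is why the flag is carried through.

A band with zero deaths or zero survivors is unevaluable; the partition
is excluded from selection and its heatmap cell is flagged. Selection
takes the arg-min AIC and arg-max AUC over evaluable partitions, ties
broken by enumeration order (lexicographic in the boundary ages).

## Cutoff derivation

Classification direction: a patient is high-risk iff rSIG is **strictly
below** the cutoff. Strict inequality means a patient exactly at the
cutoff is not flagged; the complementary convention would change results
only when the cutoff coincides with an observed value, but one convention
must be fixed and this one is tested throughout.

**Youden.** Candidate thresholds are midpoints between consecutive
distinct observed rSIG values plus ∓∞ sentinels — observed-value
resolution, not a grid, so the cutoff can land on values like 9.643.
The cutoff maximizes J = sensitivity + specificity − 1; ties break toward
the smaller cutoff (fewer patients flagged).

**Triage-goal optimization.** Field-triage practice tolerates moderate
over-triage but penalizes under-triage; the accepted targets are
under-triage (false-negative rate) below 5 % and over-triage
(false-positive rate) below 35 %. The cutoff is swept in 0.1-unit steps
from floor(min rSIG) to ceil(max rSIG) + step; the objective is the
summed exceedance max(UT − 5, 0) + max(OT − 35, 0); among minimizers the
lowest UT + OT wins, then the smallest cutoff. Rates on the grid are
computed as exact count ratios so that a rate exactly at its goal does
not register as exceedance through round-off.

**Combined evaluation.** Applying one cutoff per band dichotomizes the
score; the overall AUC of a dichotomized predictor is
(sensitivity + specificity)/2, which is what is reported, with a
stratified percentile bootstrap CI (deaths and survivors resampled
separately; default B = 2000, reducible; seeded). Pooled under-triage is
algebraically the death-weighted mean of per-band under-triage rates,
which is verified as a property test.

## Synthetic registry generator

The generator emulates a national emergency-department injury registry.
Defaults:

| parameter | default | meaning |
|---|---|---|
| `mortality_rate` | 0.0007 | marginal death probability (registry-scale rarity) |
| `sbp_curve` | (90, 2) | survivor median SBP = 90 + 2·age mmHg (standard pediatric reference) |
| `hr_curve` | (130, −4, 70) | survivor median HR, floored at 70 bpm |
| `vital_cv` | 0.12 | coefficient of variation of vitals around the age median |
| `death_shift` | (0.90, 1.15) | SBP/HR multipliers in the death stratum |
| `gcs_survivor_pmf` | mass 0.95 at 15 | survivors alert: median and quartiles 15 |
| `gcs_death_pmf` | mode at 3–4, long tail | deaths comatose: median 4, quartiles (3, 8) |
| `age_weights` | front-loaded | toddlers over-represented; cohort median age in high single digits |

Sampling is outcome-first: the death label is drawn first and vitals
conditional on it, which makes calibration to per-stratum quantiles
direct. With these defaults the survivor rSIG median lands near 16
(inside the reference interquartile band 14.10–21.15) and the death
stratum near 4.2 (inside 2.78–8.62). Vitals are truncated normals around
the age-dependent medians, rounded to integers as registries record them;
arrival times are lognormal (median 60 min, deaths faster), so roughly
2 % of rows naturally exercise the late-arrival exclusion.

Test suites and the recovery harness run at 1–2 % mortality rather than
the registry-scale 0.07 %: at desk-scale n the rare rate yields a handful
of deaths and no statistical power, and the rate is an explicit
configuration knob, not part of the method.

What the generator deliberately does **not** model: correlation between
SBP, HR and GCS within an outcome stratum (they are conditionally
independent given outcome and age); mechanism-of-injury effects on
mortality; inter-hospital transfer; and severity scores beyond rSIG.
Passing tests therefore demonstrate that the *procedure* behaves
correctly on data with the assumed structure, not that the published
cutoff values generalize — those depend on the real registry.

**Latent-severity mode.** For partition-recovery validation, vitals are
drawn unconditionally from the survivor model and the death probability
is expit(c + s·(thr_b − rSIG)), with band thresholds (12, 17, 22) over
true bands {0–6, 7–12, 13–18}, slope s = 0.9, and the global intercept c
bisected so the cohort event rate hits its target (2 % by default). The
risk-vs-rSIG curve jumps at the true boundaries — a child of 6 and a
child of 7 with the same rSIG face very different risks — which is
exactly the signal the band-specific logistic model can pick up. At
n = 50,000 the AIC-selected three-band partition recovers the true
boundaries exactly in 20 of 20 harness seeds.

## Numerical conventions

* Quantiles/IQRs: linear-interpolation convention (numpy default).
* Reported precision: percentages to two decimals, AUCs to three;
  machine-readable CSVs keep full precision.
* Rank AUC uses midrank tie handling; it equals the trapezoidal area
  under the full ROC polygon (asserted to 1e-12 in tests).
* All randomness flows through `numpy.random.Generator` seeded from the
  run seed; derived seeds use `SeedSequence` spawning and stay below 2^31.
* Degenerate inputs: single-class score sets are rejected; an
  all-excluded cohort is a warning, not an error; constant scores yield
  an ROC with only the sentinel operating points.

## Known limitations

* The AIC/AUC partition scores depend on the chosen band-logistic model;
  other plausible scoring models (e.g., cutoff-based binary AUC per
  partition) can rank partitions differently. The scorer is pluggable for
  this reason.
* Firth-flagged bands mix penalized estimates into an unpenalized AIC
  comparison (see above).
* Bootstrap CIs are percentile CIs; no continuity or acceleration
  correction.
* The generator's conditional-independence assumption understates the
  real covariance of shock physiology; operating characteristics measured
  on synthetic cohorts should be read as internal validation only.
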