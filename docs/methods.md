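# Methods note

This note records the models behind `fcmid`, the meaning and defaults of
every tunable parameter, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## 1. Mass arithmetic (`fcmid.chem`)

Monoisotopic masses are computed from a fixed table of isotope masses
(H 1.00782503207, C 12 exactly, N 14.00307400443, O 15.99491461957, plus S,
Na, K, P) summed over parsed element counts. Ion m/z for an adduct with
formula delta Δm and charge z is `(M + Δm − z·mₑ)/|z|` with the electron
mass mₑ = 0.000548579909 Da included; registered defaults are [M−H]⁻,
[M+CHO2]⁻ (formate), [M+H]⁺, [M+NH4]⁺, [M+Na]⁺. Formula-delta classes used
for family linkage are O, H2O, CH2, H2, succinate ester (C4H4O3,
100.01604 Da) and succinate ester + NH3 (C4H7NO3, 117.04259 Da); a pair of
masses classifies to a delta when the absolute difference matches the
expected delta within `tol_ppm` (default 10) of the larger mass, with the
sign reported in the low→high direction. Expected deltas are always computed
from the element table, never tabulated, so they cannot drift from the
masses they are compared against.

One reference subtlety: the commonly printed 5-decimal mass of C21H34O5 is
366.24063, but the value computed from the isotope table is 366.2406242 —
the printed figure rounds the sixth decimal up. Tests therefore hold this
entry to |Δ| ≤ 1e-5 rather than exact 5-dp equality.

## 2. Synthetic challenge study (`fcmid.simulate`)

**Design.** Two animals ("Harvey", "Pixie") receive 35 and 21 mg i.v. at
t = 0 (≈5 mg/kg); faeces are collected from −24 h to +72 h.

**Defecation schedule.** A gamma renewal process: inter-defecation intervals
are Gamma(shape = `interval_shape` = 3.0, mean = `mean_interval_h` = 2.0 h).
Schedules are redrawn (deterministically under the seed) until each animal
has ≥ `min_bc_samples` = 5 baseline and ≥ `min_ac_samples` = 15
post-administration samples, so epoch statistics are always defined.
Defecation frequency is not an observable we can cite; these values were
chosen so that the sustained-elevation invariant of the screen (≥3
consecutive high samples) is actually expressed by the excretion kernels at
the noise level below — i.e. the generator is calibrated to produce the
phenomenon the pipeline is designed to detect, not to any particular test
outcome. With sparser sampling (mean 3 h) the metabolite peak is regularly
straddled by only 1–2 samples and the "sustained elevation" concept itself
becomes ill-posed.

**Excretion kernels.** Each compound's faecal concentration is
`dose_ng × fraction_excreted × gamma.pdf(t − lag; shape, scale) /
faecal_rate_g_per_h`, zero before administration and during the lag.
Parent-like species (the administered ester and its ammonium-adduct
artifact): lag 0.5 h, shape 2.0, scale 6.0 h → kernel mode ≈ 6.5 h, ~80%
declined by 24 h. Metabolite-like species (the THF family): lag 2.0 h,
shape 2.2, scale 6.67 h → mode 10 h, FWHM ≈ 20 h. Faecal output is a
constant `faecal_rate_g_per_h` = 5 g/h. Excreted fractions (0.2–1% of dose)
put the principal metabolite in the low thousands of ng/g.

**Measurement model.** True-feature intensity =
concentration × `response_factor` (100 counts per ng/g) with multiplicative
lognormal noise (σ = `intensity_sigma` = 0.15) plus a detection floor
(50 × |N(0,1)|). Neutral masses carry Gaussian error of
`mass_error_ppm` = 1.5. Background: 2000 stationary lognormal decoys per
animal (median intensity 1e4, lognormal σ = 0.8) whose masses are shared
across animals (common chemical background — this makes the cross-animal
intersection a real test, not a free pass), plus 25 spike artifacts with 1–2
non-consecutive high post-administration samples. EIA readouts are
cross-reactivity-weighted sums over compound concentrations with additive
truncated-normal noise (`eia_noise_sd` = 5 ng/g).

**Fractionation.** The preparative gradient runs 57 min; fractions are 60 s
wide except between 22 and 37 min where they are 30 s (72 fractions).
Compounds elute as Gaussians (σ = `elution_sd_min` = 0.2 min) integrated
exactly over fraction boundaries via the normal CDF, which conserves mass to
<0.1%. The two 3β-reduced stereoisomers are placed 0.4 min apart (26.3 and
26.7 min) so they land in adjacent 30-s fractions — the co-elution scenario
the attribution stage must resolve. The fraction study gives the first
animal THF + cortisol + both 3β isomers and the second animal THF + cortisol
only, scaled by dose.

**What the generator does not emulate:** matrix suppression, drift in mass
calibration or retention time, inter-day batch effects, chromatographic
peak-shape asymmetry, EIA non-linearity near assay limits, enterohepatic
recirculation (multi-peaked excretion), and correlated noise between
features. Conclusions about robustness to those effects cannot be drawn from
this generator.

## 3. Feature screen (`fcmid.screen`)

Stage 1 — fold filter: AC max ≥ `fold_threshold` (10) × max(BC max, floor).
The floor defaults to 1% of the feature table's median nonzero intensity;
without it, any nonzero AC sample would be an infinite fold change over an
all-zero baseline. Stage 2 — persistence: the longest run of consecutive AC
samples at ≥ `high_fraction` (0.5) × AC max must reach `min_run` (3).
Raising either threshold can only remove retentions (tested as a
monotonicity property). Screening is per animal; the intersection pairs
retained features across animals greedily by nearest neutral mass within
`intersect_ppm` (10) and identical polarity — retention times are *not*
used, since runs are acquired independently.

**Kinetic classification.** Both classes must have declined (mean of the
final quarter of the window < 10% of max); the discriminator is the
intensity-weighted centroid of the ≥50%-max region: metabolite-like iff
centroid ≥ `centroid_delay_h` (10 h), else parent-like when the raw peak
falls in the first quarter of the window. The centroid is used instead of
the argmax or an onset sample index because it averages over every elevated
sample: with 2-h sampling and 15% multiplicative noise, index-based onset
rules collapse (the first AC samples of a delayed metabolite sit near
half-max by noise). The two kernel families genuinely overlap (modes 6.5 vs
10 h), so labels remain stochastic: measured over 20 simulated studies
(240 true features), ~3% are mislabeled. The label is descriptive and feeds
no downstream decision.

## 4. Annotation (`fcmid.annotate`)

Mass matching returns *every* standard whose formula mass lies within
`tol_ppm` (10); standards sharing a formula are grouped into one annotation
listing all isomers (the C21H34O5 query returns six: THF, allo-THF, 3β-THF,
3β-allo-THF and both cortolones). Retention time then accepts a candidate
iff |observed − standard| ≤ `rt_tol_min` (0.15 min) in the named
chromatography mode; a standard with no RT in that mode is *inconclusive*,
never rejected (β-cortolone is the library's deliberate example). MS/MS
cosine similarity (greedy peak pairing within `mz_tol` = 0.01) at
≥ `msms_threshold` (0.7) upgrades the evidence level. Evidence is an
explicit ladder — mass-only → mass+RT → mass+RT+MS2 — and unmatched features
are reported `unassigned` rather than dropped, because family membership
without identity is a valid scientific outcome. The family graph links
features whose pairwise mass differences classify to a known delta; the hub
is the maximal-degree node.

## 5. EIA attribution (`fcmid.eia`)

**Forward model.** response = Σ CR[assay, compound]/100 × amount. Cells
reported only as upper bounds ("<0.001") are kept for reporting but
contribute exactly zero: a compound with negligible cross-reactivity cannot
absorb signal. The bundled matrix covers the cortisol, 50c and 37e assays
against the THF isomer panel and cortisol itself (100% on its own assay by
definition).

**Inversion.** Per fraction, candidates are the compounds with LC-MS
evidence: peak area > max(`area_floor` = 0, `rel_area_floor` = 1e-3 × that
compound's maximum area over the series). The relative floor matters:
Gaussian elution tails are never exactly zero, and without it a 1e-4 tail of
a high-cross-reactivity compound in a neighbouring fraction "explains" the
signal there and silently absorbs its true owner's amount. Candidates with
zero (or bound-only) cross-reactivity are excluded from the fit; the rest
are fit by non-negative least squares (`scipy.optimize.nnls`) with the
cross-reactivity row as design. Candidates whose cross-reactivities agree
within `cr_merge_rtol` (1%) are chromatographically/immunologically
unresolvable and are fit as a merged group reported in `unresolved_groups`
rather than silently split. Fractions whose residual exceeds
`residual_fraction` (0.2) × the series maximum are flagged *unexplained* —
activity with no reactive candidate is surfaced, not attributed. A compound
is named *responsible* iff its fitted amount is positive and its
cross-reactivity ≥ `cr_floor_pct` (1%); everything else seen by LC-MS is
listed as excluded with the reason.

Noise-free forward-then-inverse recovery is better than 0.1% relative. The
"5% noise" robustness figure scales the noise to the *assay's own* maximum
fraction response (median recovery error over 20 replicates: 2–4%). Scaling
to the global maximum across assays would make nominal 5% noise ~35% of the
weakest assay's signal, which is not what an assay noise figure means.

**Ranking.** Assays are sorted by (1) fraction of animals in which the
assay's primary compound was detected, descending; (2) the compound's
abundance rank; (3) mean unexplained-activity share, ascending; (4) assay
code. The sort is a stable mergesort, so ties cannot reorder
non-deterministically. Single-animal inputs are ranked with an explicit
caveat column rather than refused.

## 6. Numerical and engineering choices

- All randomness flows from one `numpy.random.default_rng(seed)` per study;
  replicate seeds in tests and in `scripts/acceptance.py` are derived via
  `SeedSequence` and kept below 2³¹.
- NNLS is solved independently per fraction (1–3 unknowns each) rather than
  jointly over the series; with non-overlapping designs the problems are
  separable, and per-fraction solves keep the unexplained-residual flag
  local to the fraction that earned it.
- Timecourse assembly from tidy CSVs is a single pandas pivot, not a
  per-feature groupby (4062 features × ~40 samples ≈ 160k rows in ~0.2 s).
- Property-based tests (hypothesis) run derandomized so the suite is
  reproducible in CI.
- Problem sizes: default study ≈ 4062 features × 36–46 samples per animal;
  fraction study 72 fractions × ≤4 compounds × 3 assays. Full test suite
  ~20 s; acceptance script ~16 s.

## 7. Limitations

- The screen assumes a stationary baseline epoch; a secular trend in the
  background would need detrending that is out of scope here.
- Kinetic labels are descriptive and ~3% noisy at the default study
  conditions (overlapping kernels); do not gate decisions on them.
- The cross-reactivity matrix is treated as exact; assay CV is not
  propagated into attribution uncertainty.
- The intersection step assumes every animal expresses every true
  metabolite; a metabolite genuinely absent in one animal is (correctly,
  per design) dropped from the cross-animal list but still visible in the
  per-animal reports.
- Greedy nearest-mass intersection can in principle mis-pair features
  closer than the ppm tolerance to two different partners; at 10 ppm and
  the observed feature density this was never observed in 40 simulated
  animal-screens.
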