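# Methods

## The class-level fold-change model

Lipidomics of small cohorts (three biological replicates per genotype) cannot
support per-species inference; the unit of inference here is the lipid
*class*. For a comparison g vs WT, each species i of a class contributes one
paired observation

    d_i = log( x̄_i,g / x̄_i,WT ),

the log ratio of its genotype mean concentrations after cleanup. Under the
null hypothesis that the class is unchanged in aggregate, the d_i are
symmetric about zero, and the class is tested with a Wilcoxon signed-rank
test of the d_i against 0. The test is *paired across species, not across
animals*: replicate averaging precedes the ratio, because animals of
different genotypes are not paired, while the numerator and denominator of
each d_i describe the same molecular species. The assumptions are therefore:
(a) species within a class respond exchangeably enough that sign-symmetry of
d_i is the right null; (b) species log fold-changes are mutually independent
given the class effect — co-regulation within a class makes the test
anticonservative and this is a real limitation on interpretation, not on
implementation.

Two class summaries are reported side by side, since either may be the
quantity of interest: the **median per-species fold-change** (the headline
column) and the **total-mass fold-change** (ratio of summed genotype means
over the same species set). With one species they coincide.

### Exact p-values

Class sizes are small (typically 2–25 species), so the null distribution of
the positive rank sum W⁺ is computed exactly. Zeros are removed first
(classical convention); absolute values receive average ranks on ties; the
distribution of W⁺ is then built over all 2ⁿ equiprobable sign assignments
of the *realized* rank vector, so exactness holds under ties. The
implementation convolves the polynomials (1 + x^r) over the doubled ranks
(average ranks are half-integers; doubling makes them exact integers) —
algebraically identical to full enumeration at O(n·Σr) cost, feasible far
beyond the n ≤ 25 default cutoff (`FamilyConfig.exact_n_max`). The test
suite checks this branch against a literal 2ⁿ enumeration oracle.

The two-sided p uses the doubling rule, p = min(1, 2·min(P(W⁺ ≤ w),
P(W⁺ ≥ w))), which yields the familiar dyadic values (e.g. 0.0625 for five
concordant species). A minimum-likelihood alternative (sum of null
probabilities no larger than the observed one) is available as
`p_convention="min_likelihood"` but is not the default. Above the exact
cutoff a normal approximation with tie-corrected variance Σr²/4 and a 0.5
continuity correction is used and flagged `method="approximate"`; it matches
scipy's approximate Wilcoxon to machine precision. An empty or all-zero
difference vector is reported `method="untestable"` with NaN p — never a
silent 1.0.

### Family-wise control

All class × comparison tests form one Bonferroni family of size m
(default 26 = 13 classes × 2 comparisons). Because Bonferroni is
conservative at this family size, significance is dual-reported:
`*` for p < α and `***` for p < α/m (α default 0.05, so the post-correction
threshold is ≈ 0.00192). Feeding the study's 26 reported class p-values
through this stage reproduces its 26 published markers exactly, which pins
down the family size: thresholds between 0.0007 and 0.0027 are the only ones
consistent with the published marker pattern, and 0.05/26 is the simple
Bonferroni family in that bracket. `m` is configurable for other designs;
a warning is emitted if fewer tests than m are supplied the other way
(m smaller than the family actually tested).

## Peak-table cleanup

Thresholds follow the vendor-score convention "strictly less than fails":
SNR ≥ 2.0 and PQ ≥ 0.8 are retained (`QCConfig`). The depleted-group rule is
applied per (species, adduct, genotype) replicate group *before* adduct
summing — reading the cleanup steps in their stated order — and removes the
whole group when fewer than two observations survive; for complete
triplicates this is exactly "if two of three were excluded, exclude the
third". Adduct aggregation sums concentrations within one sample only and
refuses duplicated (species, adduct, sample) rows. Replicate averaging is an
arithmetic mean whose denominator is the count of surviving replicates; a
genotype with no survivors simply has no mean, and such species are later
excluded from fold-changes (ratio undefined) with a warning, not an error.
The chain is monotone in both thresholds, idempotent, conserves retained
concentration per sample, and is equivariant under global rescaling.

## Derived cardiac indices

All indices are computed per animal and then summarized, because EF, FS and
CO are ratios: the mean of per-animal ratios differs from the ratio of means
on any cohort with variance (a property the tests assert both ways —
stroke volume, being linear, matches exactly either way). LV volumes are
treated as inputs (they come from the echo vendor software), never derived
from diameters. LV mass uses the corrected-cube convention, 1.053·((LVID;d +
LVPW;d + LVAW;d)³ − LVID;d³), with the standard 0.8 correction factor — the
factor is pinned by the exact 0.8 ratio between the uncorrected and
corrected reference group means in all three genotypes. Mitral E and A
velocities are carried in mm/s. Group comparison is one-way ANOVA followed
by Tukey HSD (scipy); this stage is conventional statistics, and the test
suite cross-checks it against statsmodels to 1e-8.

## Stereology and expression

Volume density uses the pooled (ratio-of-sums) estimator Σmito/Σtotal rather
than the mean of per-field ratios: when fields contribute different point
totals the pooled form weights by information. Per-field densities are also
exposed for dispersion checks. ΔΔCt centering uses the arithmetic mean of
the control group's ΔCt, i.e. the geometric mean of control RQs is exactly
1 — the conventional reading; RQ = 2^(−ΔΔCt). Adding any constant to the
reference-gene Ct of every sample leaves all RQs unchanged.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis assumes,
with study-design defaults: triplicate cohorts of WT/HET/KO; 13 lipid
classes with the study's class-level fold-change presets (e.g. AcCa 1.68×
HET, 3.07× KO; LPC 0.62×/0.52×); species baselines log-normal
(`baseline_log_mean` 3.0, `baseline_log_sd` 1.0, arbitrary units — the
pipeline is scale-equivariant so the units are immaterial); per-species log
fold-changes normal about the class log fold-change with SD `species_fc_sd`
(default 0.1), making the class *median* the configured value; replicate
noise multiplicative log-normal with SD `noise_log_sd` (default 0.2,
a realistic ~20% CV for replicate lipid quantification); two adducts per
species with weights 0.7/0.3; and a `qc_fail_rate` fraction of peaks
(default 0.05) emitted with a failing score, SNR or PQ chosen with equal
probability. Echo cohorts draw each field independently from per-genotype
truncated normals at the preset group means/SDs (cohort sizes 5/9/3), with
the volume pair redrawn until diastolic exceeds systolic; body weight
presets encode the knockout's 40% deficit against an unchanged 150 mg heart
weight, so the hypertrophy index rises ≈1/0.6-fold. Grid counts are
Binomial(points, density) per field with density preset 0.33 (mitochondria
occupy roughly a third of cardiomyocyte volume); Ct tables encode an
expression fold-change f as a −log₂f shift of the target Ct, with the
default preset carrying the heterozygote's 1.9× Nd1 elevation.

Deliberately **not** emulated: per-animal random effects shared across
species (each peak's noise is independent, so within-class correlation is
absent — the null-calibration result holds under this independence and would
degrade under real co-regulation); per-sample normalization error (a
sample-level scale factor is invisible to the scale-equivariant pipeline);
raw spectra, retention times, m/z, adduct identification, isotope effects;
and any relation between echo fields (they are drawn independently, so
derived-index variances are not faithful covariances). Passing tests
therefore demonstrate correctness of the *procedures* under the assumed
structure, not robustness to violations real data may carry.

## Numerical and design choices

* Even species counts use the conventional midpoint median.
* Exact-test rank doubling keeps tie ranks integral; comparisons against the
  observed rank sum use an absolute guard of 1e-12 where float sums enter.
* Fold-changes require a positive denominator mean; offending species are
  excluded with a warning and a count, never silently.
* Derived indices validate physiologic ordering (systolic ≤ diastolic) and
  positivity, raising `DomainError` otherwise; EF accepts the degenerate
  complete-emptying bound (systolic volume 0 → 100%).
* Tables are tab-separated text with headers; floats are written at 12
  significant digits so write/read round-trips are lossless at that
  precision. Report p-values are printed to 4 decimals, fold-changes to 2.
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives per-stage seeds from the run seed via `SeedSequence`, and
  a run manifest (config echo, seed, library versions) is written alongside
  every output set.

## Problem sizes in the shipped checks

The validation suite simulates at sizes chosen to keep the checks sharp but
quick: 500 null classes of 10 species for calibration (the 99% binomial band
around 0.05 at n = 500 is ±0.025); 200 simulated studies of a 14-species
acylcarnitine class at fold-change 3.07 with species SD 0.1 and replicate
noise SD 0.05 for power/recovery (at the default 0.2 replicate noise the
±10% median-recovery band is ~1.5 standard errors wide and holds in only
~88% of cohorts — a sampling-error statement about three-replicate designs,
not a defect of the estimator); and 500 random cases of n ≤ 8 against the
brute-force enumeration oracle.

## Known limitations

Within-class co-regulation is unmodelled (see above); the signed-rank test
treats species as exchangeable and weighting by abundance is only reflected
in the separate total-mass summary; Bonferroni is conservative when classes
are correlated; the echo generator's independent fields make multivariate
summaries (e.g. correlations between EF and FS) unrealistic; and the
depleted-group rule's generalization below triplicates is a design choice
(any group with fewer than two survivors is dropped when the design expects
at least two replicates).
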