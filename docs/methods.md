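# Methods

`neglectdisc` implements three complementary analyses of how a focal
subcortical stroke lesion may disrupt brain networks and produce
spatial neglect, together with a synthetic-cohort generator that makes
every stage testable against known ground truth. This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic validation does and does not show.

## Behavioural severity: the Centre of Cancellation

Cancellation tests present targets scattered over a sheet centred on
the patient's sagittal midline. The Centre of Cancellation (CoC) is the
mean horizontal position of the successfully cancelled targets,
normalised by the largest absolute target position so the extreme
targets score exactly ±1. Positive scores mean the patient found mostly
right-sided targets (left neglect). Severity is the arithmetic mean of
the per-test CoC over the available tests (a single available test is
used as-is); the binary neglect diagnosis is positive when the CoC of
at least one test *strictly* exceeds its cutoff.

Choices worth stating:

* The normalisation denominator is the maximum |target position| on the
  sheet, not the sheet half-width, so the printed −1…1 range is
  attainable.
* Cutoffs are configuration, not constants (`neglect_cutoffs`); the
  synthetic cohorts use 0.08 per test, a conventional order of
  magnitude for cancellation cutoffs.
* A sheet with zero cancelled targets has an undefined CoC and
  propagates as missing rather than ±1; there is no principled value
  for it.

## Lesion-network mapping

A patient's binary lesion mask seeds resting-state fMRI of healthy
reference subjects: per subject, the mean seed time course is Pearson-
correlated with every voxel, the r map is Fisher z-transformed
(z = atanh r, |r| clipped at 1−10⁻⁷), and z maps are averaged
voxel-wise across subjects. Voxels with undefined correlations
(constant series) are missing, never zero; a voxel must be valid in at
least half the subjects to enter the average. Because tissue inside and
around the seed correlates with itself, maps are masked to cortical
grey matter (parcellation labels in `cortical_ids`) before statistics —
masking and averaging commute, so the order is immaterial. Normative
time series are consumed as preprocessed; an optional linear detrend is
available behind a flag.

## Voxel-wise inference

**Frequentist.** Per voxel, the t statistic of the slope in
severity ~ voxel value (equivalently r·√((n−2)/(1−r²)), n−2 df; single
regressor plus intercept, no covariates). Family-wise error is
controlled by maximum-statistic permutation: severity is permuted, the
whole map recomputed, and the max over voxels of |t| (two-tailed) or t
(one-tailed) recorded; the critical value is the (1−α) empirical
quantile (`numpy` "higher" method) of that max distribution, and
observed statistics must strictly exceed it. When n! ≤ the requested
permutation count and n ≤ 8, all permutations are enumerated instead of
sampled, making small-sample thresholds exact. Per-voxel FWE p-values
use the add-one rule p = (1 + #{perm max ≥ t}) / (1 + n_perm), so p > 0
always. Only voxels valid in all patients are tested (complete-case).
Numerically perfect fits are capped at |t| = 10⁶.

**Bayesian.** Per voxel, the Bayes factor BF₁₀ for a nonzero
standardised slope under a zero-centred Cauchy prior of scale s
(default √2⁄2) — the Zellner–Siow/JZS construction, i.e. the Zellner
g-prior marginalised over g ~ InverseGamma(½, n·s²/2):

BF₁₀ = ∫₀^∞ (1+g)^{(n−2)/2} (1 + g(1−R²))^{−(n−1)/2} π(g) dg,

evaluated by quadrature in log g after locating the integrand peak on a
coarse grid and shifting (stable up to astronomically large BF). Bayes
factors are binned by the usual evidence conventions: BF < 1/3
moderate-or-more for the null, 1/3–1 anecdotal null, 1–3 anecdotal
alternative (a BF of exactly 1 falls here; a measure-zero tie), 3–10
moderate, 10–30 strong, > 30 very strong; the reported fractions
partition the tested voxels. This BF is a documented stand-in for
whatever prior an external Bayesian mapping toolbox uses; no numeric
agreement with any particular toolbox is claimed.

## Streamline disconnection

A streamline counts as disconnected by a lesion when any point along it
falls inside a lesion voxel. Polylines are resampled at arc-length
steps of ≤ 0.5 mm (half the 1 mm template voxel, keeping original
vertices), so a segment crossing a voxel between coarse vertices is not
missed; voxel membership is nearest-integer rounding of the inverse
affine (a voxel owns the half-open cube around its lattice point).
Refining the step can only add detections; at 0.5 mm the decisions
match 0.01 mm dense sampling throughout the synthetic suite (an
adversarial segment clipping a voxel corner over < 0.5 mm of arc could
differ, but tract-following streamlines do not do this).

The patients × streamlines binary matrix is filtered to streamlines
disconnected in ≥ k patients (default 5) *before* the permutation null
is formed. Each surviving streamline is tested with a pooled-variance
two-sample t (disconnected minus not; identical decisions to a
point-biserial correlation test), one-tailed because damage is expected
to increase severity, under the same max-statistic permutation FWE.
Constant indicator columns are excluded. Significant streamlines are
aggregated by the tract labels carried with the streamline file; tract
recognition itself is an upstream tool's job and is not re-implemented.

## Tract-wise lesion load

Probabilistic tract maps are binarised at p ≥ 0.3 (inclusive; the
conventional cut-off for histology-based tract atlases), and the load
is the damaged fraction of the tract, |lesion ∩ tract| / |tract| — the
denominator is tract size, so loads are comparable across lesion sizes.
The weighted variant sums tract probability over lesioned voxels and
normalises by total tract probability mass, keeping both measures on
[0, 1] (on a binary map the two coincide). Associations with severity
use Kendall's tau-b (tie-corrected, asymptotic two-sided p),
Bonferroni-corrected across tracts; the presence of any load is
compared between neglect groups with a Pearson chi-square without
continuity correction — the only variant consistent with the worked
example the package reproduces (χ²(1, N=43) = 3.88 from the presence
table [[12, 2], [16, 13]]).

## Random-forest classification

Binary neglect is predicted from the four tract loads with a shallow
random forest (100 trees, max depth 3, ≥ 5 samples to split) evaluated
as the mean ROC AUC over 100 stratified 80/20 train/test splits —
per-split AUCs are averaged, not pooled. Significance comes from a
permutation test: labels are shuffled and the entire repeated-CV
procedure re-run (same split-generation procedure and RNG stream;
stratification is on the shuffled labels, which preserves class counts
and guarantees both classes in every test fold), 2500 times by default,
with the add-one p-value. Everything is deterministic under a fixed
seed. Desk-scale work reduces splits/trees/permutations through the
config; the calibration suites use 2 splits and 5 trees per forest so
200 null runs × 100 CV procedures finish on one CPU in minutes — the
calibration of the permutation p does not depend on the forest size.

## Synthetic cohorts and ground truth

The generator builds, on a 32³ grid at 1 mm (all geometry scales with
the grid): a spherical brain with a 12-parcel cortical shell; two
subcortical blobs (pseudo basal ganglia and thalamus); four
probabilistic tracts — Gaussian cross-sections (σ = 1.5 mm) around
Bezier centrelines anchored on the shell and bowing past the blobs;
streamlines as centreline copies under constant offsets ≤ 1.2σ, which
keeps them inside their tract's p ≥ 0.3 region; a normative connectome
in which each parcel mixes its own latent signal and the two blobs
share a network latent with exactly one planted cortical parcel, plus
spatial smoothing; and ellipsoidal lesions centred in a blob, with
volumes log-uniform over 8–150 voxels (the emulated study's 0–10.8 cm³
range scaled to the grid, enforced exactly by accept/retry) and an
encroachment fraction e ∈ [0, 1] shifting the lesion centre toward the
nearest tract centreline, so e drives tract load.

**Severity link.** The noiseless severity signal is the Blom normal
score of total tract load; the observed signal mixes it with Gaussian
noise at correlation ρ = sin(π·τ/2) — the Gaussian-copula inversion of
Kendall's tau — so the target rank correlation `effect_size` (default
0.3 at n = 43) is attained in expectation *by construction*, not by
tuning. A linear-in-load link was considered and rejected: its realised
tau depends on the load distribution and would have required post-hoc
calibration. The severity score is placed on the CoC scale through
coc = 0.041·exp(1.49·z), a strictly monotone, right-skewed map chosen
so the cohort reproduces the emulated study's severity profile (overall
mean ≈ 0.15, about one third of patients above the 0.08 cutoff,
non-neglect scores piling up near zero). Cancellation sheets (60-target
letters, 35-target bells, symmetric layouts) are realised by greedily
un-cancelling targets until the computed CoC matches the intended value
within ~0.02, so the scoring code is exercised end to end.

**What passing the synthetic suite shows — and what it does not.** It
shows the statistics are calibrated (FWER ≈ α, uniform permutation p),
that planted effects of stated size are recovered at stated power, and
that every I/O and bookkeeping step is lossless. It does not show
robustness to real-data complications the generator omits: realistic
haemodynamics and autocorrelated BOLD noise, vascular-territory lesion
shapes, registration error, atlas disagreement, or behavioural floor
effects.

## Numerical and design choices, in brief

* Volumes in one analysis must share shape and affine (tolerance 1e-4);
  no resampling is performed, ever — registration is upstream.
* Streamlines are normalised to world mm on load; TRK/TCK label
  round-tripping uses a `.labels.json` sidecar (one name per
  streamline) because the formats carry numeric data at best.
* Missing values propagate as NaN and are excluded, never imputed.
* All randomness flows from one seeded `numpy` Generator per run; run
  reports embed config, seed, package version and input hashes, carry
  no wall-clock content, and serialise with sorted keys, so identical
  runs are byte-identical.
* Per-group analyses (basal ganglia / thalamus) reuse the same code
  path with a patient filter; groups with < 3 patients are skipped with
  a logged reason.

## Problem sizes used by the validation suites

FWER: 500 null cohorts, n = 20, 500 columns, 200 permutations. Rank
effect: 500 cohorts, n = 43, τ = 0.3. Streamline sensitivity: 50
replicates, 300 streamlines, 10 planted, 2 SD shift, 500 permutations.
Classifier: 200 null runs at n = 60 with 99 permutations each, and one
separable cohort at 199 permutations. The acceptance script's
end-to-end demonstration runs 43 patients with a 4-subject connectome,
60 timepoints and 500 permutations per stage. These sizes are the
package's desk-scale profile; the statistical expectations they test
are size-free.

## Known limitations

* The Bayes factor is one principled default (JZS); other priors give
  other magnitudes, and evidence bins near boundaries will shift.
* The streamline GLM tests marginal association per streamline; spatially
  correlated streamlines are handled only through the max-stat null.
* The generator's tau calibration is exact for the *target* CoC; sheet
  realisation adds ±0.02 discretisation, negligible at the tested
  effect sizes but visible at τ near 1.
* No covariates (e.g. lesion volume) are supported in the voxel-wise
  designs.
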