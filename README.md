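# neglectdisc

Indirect disconnection analysis of spatial neglect after subcortical
stroke — a tested, reusable implementation of three complementary
lesion-mapping analyses, plus a synthetic-cohort generator with known
ground truth so the whole pipeline can be validated end to end without
any clinical data.

## Who this is for and what it does

Strokes confined to the basal ganglia or thalamus sometimes cause
spatial neglect — a deficit of contralesional attention usually linked
to right-hemisphere *cortical* networks. One candidate explanation is
that such lesions act indirectly, by disrupting connections: either
subcortico-cortical functional connectivity, or cortico-cortical
association fibre tracts (SLF, IOF, SOF, UF) that pass directly
adjacent to these grey-matter structures. `neglectdisc` implements the
analysis toolkit for testing these hypotheses from nothing but binary
lesion masks, behavioural scores, and normative reference data:

1. **Lesion-network mapping** — each lesion mask seeds normative
   resting-state fMRI; per reference subject the seed's mean time
   course is correlated with every voxel, Fisher z-transformed
   (z = atanh r) and averaged, giving a cortically masked
   lesion-network map per patient. Association with neglect severity
   is tested voxel-wise by a GLM with maximum-statistic permutation
   FWE correction (two-tailed), and in parallel with Bayes-factor
   mapping (JZS prior on the standardised slope) binned into the
   conventional evidence categories (BF > 3 moderate, > 10 strong,
   > 30 very strong, < 1/3 moderate for the null).
2. **Streamline disconnection** — normative streamlines intersecting
   each lesion (arc-length resampling at 0.5 mm, nearest-voxel
   membership) give a patients × streamlines binary matrix; after a
   ≥ 5-patient prevalence filter, each streamline is tested one-tailed
   (two-sample t, max-statistic permutation FWE) and significant
   streamlines are aggregated by fibre tract.
3. **Tract-wise lesion load** — per tract, the damaged fraction
   |lesion ∩ tract| / |tract| after binarising the probabilistic
   atlas at p ≥ 0.3 (or probability-weighted); association with
   severity by Kendall's tau-b with Bonferroni correction, a Pearson
   chi-square on load presence vs neglect diagnosis, and random-forest
   classification of neglect from the four loads (100 stratified 80/20
   splits, mean test AUC, permutation p).

Behavioural severity is the Centre of Cancellation (CoC): the mean
normalised horizontal position of cancelled targets, 0 for symmetric
search, +1 when only the rightmost target is found (left neglect);
severity is the mean CoC over the letters and bells tests and the
binary diagnosis applies per-test cutoffs.

The synthetic-data module generates complete cohorts — parcellated
template, probabilistic tracts, labelled streamlines, a normative
connectome with one planted subcortico-cortical network, subcortical
lesions with variable tract encroachment, and cancellation sheets whose
severity is a noisy monotone function of total tract load with a
calibrated rank effect (Kendall τ) — so every statistical claim above
is testable against ground truth. See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```python
import numpy as np
from neglectdisc import synthetic_data as sd
from neglectdisc.tract_load import kendall_tau, presence_chi_square

cfg = sd.SynthConfig(seed=7)                      # 43 patients, tau target 0.3
anatomy = sd.make_anatomy(cfg)
cohort = sd.make_cohort(cfg, anatomy)

total = cohort.load_table.total.to_numpy()        # per-patient total tract load
severity = cohort.severity                        # mean CoC over both tests
tau, p = kendall_tau(total, severity)
print(f"total lesion load vs severity: tau = {tau:.2f}, p = {p:.4f}")

neglect = cohort.neglect_labels()                 # CoC cutoff 0.08 per test
present = total > 0
table = np.array([[np.sum(present & (neglect == 1)), np.sum(~present & (neglect == 1))],
                  [np.sum(present & (neglect == 0)), np.sum(~present & (neglect == 0))]])
chi2, df, pc = presence_chi_square(table)
print(f"load presence vs neglect: chi2({df}, N={table.sum()}) = {chi2:.2f}, p = {pc:.3f}")
```

prints

```
total lesion load vs severity: tau = 0.31, p = 0.0038
load presence vs neglect: chi2(1, N=43) = 2.60, p = 0.107
```

The rank correlation recovers the planted effect (the generator targets
τ = 0.3; any single 43-patient cohort scatters around it), and the
presence table shows how often patients with any tract damage are the
ones diagnosed with neglect — in this particular draw the ratio is
elevated but not significant at N = 43, a realistic outcome at this
sample size.

The full three-experiment pipeline runs from a cohort directory:

```sh
neglectdisc synth --out cohort/ --seed 7 --n-subjects 8
neglectdisc run-all --config run.yaml     # paths, alpha, permutations, seed
```

writing per-experiment JSON reports (FWE thresholds and significant
voxel counts, Bayes-factor bin fractions, significant streamlines per
tract, load tables, tau/chi-square/classifier statistics) that embed
the config, seed and input hashes, and are byte-identical across
reruns of the same configuration.

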