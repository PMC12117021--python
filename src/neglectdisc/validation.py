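"""Simulation-based calibration and recovery checks for the pipeline.

These routines measure, on synthetic cohorts with known ground truth,
the operating characteristics the statistical machinery promises:
family-wise error control of the max-statistic permutation tests,
recovery of a planted rank effect between tract load and severity,
sensitivity to planted streamline disconnections, and calibration of
the classifier permutation test.  They are used by the test suite and
by the acceptance script, and are runnable by users who want to verify
an installation.
"""

from __future__ import annotations

import numpy as np

from .classifier import ClassifierConfig, permutation_test_auc, repeated_cv_auc
from .streamline_disconnection import (DisconnectionMatrix, streamline_glm,
                                       _two_sample_t_perm, two_sample_t)
from .synthetic_data import (SynthConfig, make_anatomy, make_cohort,
                             make_planted_disconnection)
from .tract_load import kendall_tau
from .voxel_stats import max_stat_fwe_array

__all__ = [
    "fwer_calibration",
    "tau_recovery",
    "streamline_sensitivity",
    "classifier_null_calibration",
    "classifier_separable_check",
]


def fwer_calibration(n_runs: int = 500, n_patients: int = 20, n_voxels: int = 500,
                     n_perm: int = 200, alpha: float = 0.05,
                     statistic: str = "regression", seed: int = 0) -> float:
    """Fraction of pure-null cohorts with any FWE-significant column.

    ``statistic='regression'`` exercises the two-tailed voxel GLM on
    Gaussian maps; ``'two_sample'`` exercises the one-tailed streamline
    GLM on binary disconnection indicators.  Under exact FWE control the
    rate estimates alpha.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        y = rng.standard_normal(n_patients)
        if statistic == "regression":
            X = rng.standard_normal((n_patients, n_voxels))
            res = max_stat_fwe_array(X, y, n_perm=n_perm, alpha=alpha,
                                     tails="two", rng=rng)
        else:
            # binary columns with prevalence in [5, n-5], like a filtered matrix
            k = rng.integers(5, n_patients - 4, size=n_voxels)
            ranks = rng.random((n_voxels, n_patients)).argsort(axis=1).argsort(axis=1)
            X = (ranks < k[:, None]).T.astype(float)
            res = max_stat_fwe_array(X, y, n_perm=n_perm, alpha=alpha,
                                     tails="one", rng=rng,
                                     statistic=two_sample_t,
                                     perm_statistic=_two_sample_t_perm)
        hits += bool(res["sig"].any())
    return hits / n_runs


def tau_recovery(n_replicates: int = 500, effect_size: float = 0.3,
                 n_patients: int = 43, alpha: float = 0.05,
                 seed: int = 0) -> dict:
    """Realised Kendall tau between total tract load and severity.

    Generates ``n_replicates`` full synthetic cohorts at the target rank
    effect, recomputes lesions, loads and behaviour each time, and
    returns the mean realised tau and the rejection rate (power) of the
    tau test at ``alpha``.
    """
    base = SynthConfig(seed=seed, n_patients=n_patients,
                       effect_size=effect_size, n_subjects=1, n_timepoints=2)
    anatomy = make_anatomy(base)
    taus, rejections = [], []
    for rep in range(n_replicates):
        cfg = SynthConfig(seed=seed + 1000 + rep, n_patients=n_patients,
                          effect_size=effect_size, n_subjects=1, n_timepoints=2)
        cohort = make_cohort(cfg, anatomy)
        tau, p = kendall_tau(cohort.load_table.total.to_numpy(), cohort.severity)
        taus.append(tau)
        rejections.append(p < alpha)
    return {"mean_tau": float(np.mean(taus)), "sd_tau": float(np.std(taus)),
            "power": float(np.mean(rejections)), "n_replicates": n_replicates,
            "target_tau": effect_size}


def streamline_sensitivity(n_replicates: int = 50, n_patients: int = 50,
                           shift: float = 2.0, n_perm: int = 500,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Mean recovery rate of planted streamline disconnections.

    Each replicate plants a disconnection pattern whose carriers are
    shifted by ``shift`` severity SDs, runs the one-tailed FWE GLM, and
    scores the fraction of planted streamlines declared significant.
    """
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_replicates):
        X, y, planted = make_planted_disconnection(n_patients=n_patients,
                                                   shift=shift, rng=rng)
        m = DisconnectionMatrix(X, [f"p{i}" for i in range(n_patients)],
                                np.arange(X.shape[1]))
        res = streamline_glm(m, y, n_perm=n_perm, alpha=alpha, rng=rng)
        rates.append(np.isin(planted, res["significant"]).mean())
    return float(np.mean(rates))


#: desk-scale forest/CV profile for the repeated-null calibration runs,
#: sized so 200 runs x 100 CV procedures complete on one CPU in minutes
NULL_PROFILE = dict(n_splits=2, n_trees=5)


def classifier_null_calibration(n_runs: int = 200, n_patients: int = 60,
                                n_perm: int = 99, seed: int = 0) -> dict:
    """Observed AUCs and permutation p-values on label-independent cohorts.

    Under the null the mean CV AUC centres on 0.5 and the permutation
    p-value is (discretely) uniform on {1/(n_perm+1), ..., 1}.
    """
    rng = np.random.default_rng(seed)
    aucs, pvals = [], []
    for run in range(n_runs):
        X = rng.random((n_patients, 4))
        y = (rng.random(n_patients) < 0.4).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        cfg = ClassifierConfig(n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                               **NULL_PROFILE)
        res = permutation_test_auc(X, y, cfg)
        aucs.append(res.mean_auc)
        pvals.append(res.p_value)
    p = np.asarray(pvals)
    return {"mean_auc": float(np.mean(aucs)), "mean_p": float(p.mean()),
            "frac_p_le_10pct": float(np.mean(p <= 0.1)), "n_runs": n_runs}


def classifier_separable_check(n_patients: int = 60, n_perm: int = 199,
                               seed: int = 0) -> dict:
    """Mean AUC and permutation p on a cohort separable by one feature."""
    rng = np.random.default_rng(seed)
    X = rng.random((n_patients, 4))
    y = (rng.random(n_patients) < 0.4).astype(int)
    X[:, 0] = y + 0.02 * rng.standard_normal(n_patients)
    cfg = ClassifierConfig(n_splits=8, n_trees=25, n_perm=n_perm, seed=seed)
    res = permutation_test_auc(X, y, cfg)
    return {"mean_auc": res.mean_auc, "p_value": res.p_value}
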