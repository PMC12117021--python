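"""Voxel-wise mass-univariate statistics on lesion-network map stacks.

Two inference routes over the same design (severity ~ voxel value, one
regressor plus intercept):

* a frequentist GLM whose per-voxel t statistic is thresholded by
  maximum-statistic permutation testing, controlling the family-wise
  error rate over all tested voxels, and
* a Bayesian GLM producing a voxel-wise Bayes factor BF10 for a nonzero
  standardised slope under a zero-centred Cauchy prior (Zellner-Siow /
  JZS), binned into conventional evidence categories.

The permutation engine works on a plain ``(n_patients, n_voxels)``
matrix so the same code drives image-level analyses, the streamline GLM
and the calibration simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy import integrate

from .core_io import Volume3D

__all__ = [
    "StatMap",
    "BFMap",
    "voxelwise_t",
    "voxelwise_glm",
    "max_stat_fwe",
    "max_stat_fwe_array",
    "bayes_factor_regression",
    "bayes_factor_map",
    "bin_bayes_factors",
    "BF_BIN_NAMES",
]

#: cap for |t| when the fit is numerically perfect (1 - r^2 underflows)
T_CAP = 1e6

BF_BIN_NAMES = (
    "h0_moderate_or_more",  # BF < 1/3
    "h0_anecdotal",         # 1/3 <= BF < 1
    "h1_anecdotal",         # 1 <= BF <= 3
    "h1_moderate",          # 3 < BF <= 10
    "h1_strong",            # 10 < BF <= 30
    "h1_very_strong",       # BF > 30
)


@dataclass
class StatMap:
    tmap: Volume3D
    fwe_threshold: float
    sig_mask: Volume3D
    n_perm: int
    tails: str
    alpha: float
    max_distribution: np.ndarray = field(repr=False, default=None)


@dataclass
class BFMap:
    bfmap: Volume3D
    bins: Volume3D          # integer codes indexing BF_BIN_NAMES; -1 = untested
    bin_fractions: dict[str, float]
    prior_scale: float


def _as_matrix(maps) -> tuple[np.ndarray, np.ndarray, Volume3D]:
    """Stack per-patient volumes to (n, v) over complete-case voxels."""
    vols = [m.zmap if hasattr(m, "zmap") else m for m in maps]
    data = np.stack([np.asarray(v.data, dtype=float) for v in vols])
    valid = np.all(np.isfinite(data), axis=0)
    X = data[:, valid]
    return X, valid, vols[0]


def voxelwise_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t statistic of the slope in y ~ x per column of X (n-2 df).

    Equals the Pearson-correlation t, r*sqrt((n-2)/(1-r^2)).  Columns
    with zero variance return NaN; numerically perfect fits are capped
    at +/-T_CAP.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    yc = y - y.mean()
    ynorm = np.sqrt(np.sum(yc ** 2))
    if ynorm == 0:
        raise ValueError("severity vector is constant")
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt(np.sum(Xc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Xc) / (xnorm * ynorm)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    t[xnorm == 0] = np.nan
    return np.clip(t, -T_CAP, T_CAP)


def _permutation_matrix(y: np.ndarray, n_perm: int, rng: np.random.Generator,
                        exhaustive: bool | None = None) -> np.ndarray:
    """(n_perm, n) matrix of permuted y; exhaustive when n! <= n_perm."""
    from itertools import permutations as iperm
    from math import factorial

    n = len(y)
    if exhaustive is None:
        exhaustive = n <= 8 and factorial(n) <= n_perm
    if exhaustive:
        return np.array([np.asarray(p) for p in iperm(y)])
    return np.array([rng.permutation(y) for _ in range(n_perm)])


def max_stat_fwe_array(X: np.ndarray, y: np.ndarray, n_perm: int = 10000,
                       alpha: float = 0.05, tails: str = "two",
                       rng: np.random.Generator | int | None = 0,
                       statistic=None, perm_statistic=None) -> dict:
    """Max-statistic permutation FWE on a (n, v) matrix.

    For each permutation of y the whole statistic map is recomputed and
    its maximum (|t| for two-tailed, t for one-tailed) recorded; the
    critical value is the (1-alpha) empirical quantile of that max
    distribution and the observed map is thresholded against it
    (strictly).  Per-column FWE p-values use the add-one rule
    p = (1 + #{perm max >= t_obs}) / (1 + n_perm), so p > 0 always.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if statistic is None:
        statistic = voxelwise_t
    if perm_statistic is None:
        perm_statistic = (_t_for_permutations if statistic is voxelwise_t
                          else lambda X_, P_: np.stack([statistic(X_, p) for p in P_]))
    y = np.asarray(y, dtype=float)
    t_obs = statistic(X, y)
    perms = _permutation_matrix(y, n_perm, rng)

    stat_obs = np.abs(t_obs) if tails == "two" else t_obs
    # the permuted maps are computed in blocks to bound memory; each
    # block is a single BLAS product for the built-in statistics.
    maxes = np.empty(len(perms))
    block = max(1, int(2e7 // max(X.shape[1], 1)))
    for start in range(0, len(perms), block):
        chunk = perms[start:start + block]
        t_chunk = perm_statistic(X, chunk)
        s = np.abs(t_chunk) if tails == "two" else t_chunk
        maxes[start:start + len(chunk)] = np.nanmax(s, axis=1)
    threshold = float(np.quantile(maxes, 1 - alpha, method="higher"))
    with np.errstate(invalid="ignore"):
        sig = stat_obs > threshold
    sig = np.where(np.isfinite(stat_obs), sig, False)
    pvals = (1 + (maxes[:, None] >= stat_obs[None, :]).sum(axis=0)) / (1 + len(perms))
    return {
        "t": t_obs, "sig": sig, "threshold": threshold,
        "max_distribution": maxes, "p_fwe": pvals, "n_perm": len(perms),
    }


def _t_for_permutations(X: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Slope t statistics for every permuted y (rows of perms) at once."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt(np.sum(Xc ** 2, axis=0))
    P = perms - perms.mean(axis=1, keepdims=True)
    pnorm = np.sqrt(np.sum(P ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (P @ Xc) / (pnorm[:, None] * xnorm[None, :])
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    t[:, xnorm == 0] = np.nan
    return np.clip(t, -T_CAP, T_CAP)


def voxelwise_glm(maps, y: np.ndarray) -> Volume3D:
    """Per-voxel slope t map over a stack of per-patient volumes.

    Only voxels valid (finite) in all patients are tested; others are NaN.
    """
    X, valid, ref = _as_matrix(maps)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    t = voxelwise_t(X, np.asarray(y, dtype=float))
    out = np.full(ref.shape, np.nan)
    out[valid] = t
    return Volume3D(data=out, affine=ref.affine, space_tag=ref.space_tag)


def max_stat_fwe(maps, y: np.ndarray, n_perm: int = 10000, alpha: float = 0.05,
                 tails: str = "two", rng: np.random.Generator | int | None = 0) -> StatMap:
    """Volume-level max-statistic permutation FWE over a map stack."""
    X, valid, ref = _as_matrix(maps)
    res = max_stat_fwe_array(X, np.asarray(y, dtype=float), n_perm=n_perm,
                             alpha=alpha, tails=tails, rng=rng)
    tvol = np.full(ref.shape, np.nan)
    tvol[valid] = res["t"]
    sigvol = np.zeros(ref.shape, dtype=np.uint8)
    sigvol[valid] = res["sig"]
    return StatMap(
        tmap=Volume3D(data=tvol, affine=ref.affine, space_tag=ref.space_tag),
        fwe_threshold=res["threshold"],
        sig_mask=Volume3D(data=sigvol, affine=ref.affine, space_tag=ref.space_tag),
        n_perm=res["n_perm"], tails=tails, alpha=alpha,
        max_distribution=res["max_distribution"],
    )


def bayes_factor_regression(r2: float, n: int, prior_scale: float = np.sqrt(2) / 2) -> float:
    """JZS Bayes factor BF10 for a single-covariate linear model.

    Marginalises the Zellner g-prior over the Zellner-Siow hyperprior
    g ~ InverseGamma(1/2, n*s^2/2), i.e. a zero-centred Cauchy prior of
    scale ``s`` on the standardised slope:

        BF10 = int_0^inf (1+g)^((n-2)/2) (1 + g(1-R^2))^(-(n-1)/2) pi(g) dg

    evaluated by numerical quadrature in log space for stability.
    """
    if not (0 <= r2 <= 1):
        raise ValueError("R^2 must be in [0,1]")
    if n < 5:
        raise ValueError("need at least 5 observations")
    s2 = prior_scale ** 2
    half_log_nu = 0.5 * np.log(n * s2 / 2)
    log_gamma_half = lgamma(0.5)
    one_minus_r2 = max(1.0 - r2, 1e-15)

    def log_integrand(u: float) -> float:
        g = np.exp(u)
        return (
            0.5 * (n - 2) * np.log1p(g)
            - 0.5 * (n - 1) * np.log1p(g * one_minus_r2)
            + half_log_nu - log_gamma_half
            - 1.5 * u - n * s2 / (2 * g)
            + u  # Jacobian of g = e^u
        )

    # locate the integrand peak on a coarse grid, then shift
    grid = np.linspace(-30, 60, 181)
    logs = np.array([log_integrand(u) for u in grid])
    shift = float(np.max(logs))
    val, _ = integrate.quad(lambda u: np.exp(log_integrand(u) - shift), -30, 60, limit=200)
    bf = float(np.exp(shift) * val) if shift < 700 else float("inf")
    return bf


def bayes_factor_map(maps, y: np.ndarray, prior_scale: float = np.sqrt(2) / 2) -> BFMap:
    """Voxel-wise JZS Bayes factor map over a stack of per-patient volumes."""
    X, valid, ref = _as_matrix(maps)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 patients")
    if np.ptp(y) == 0:
        raise ValueError("severity vector is constant")
    n = X.shape[0]
    yc = y - y.mean()
    ynorm = np.sqrt(np.sum(yc ** 2))
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt(np.sum(Xc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Xc) / (xnorm * ynorm)
    bf = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        if xnorm[j] == 0 or not np.isfinite(r[j]):
            continue
        try:
            val = bayes_factor_regression(min(r[j] ** 2, 1.0), n, prior_scale)
        except Exception:
            continue
        if np.isfinite(val) and val > 0:
            bf[j] = val
        elif np.isinf(val):
            bf[j] = np.finfo(float).max
    bfvol = np.full(ref.shape, np.nan)
    bfvol[valid] = bf
    bf_volume = Volume3D(data=bfvol, affine=ref.affine, space_tag=ref.space_tag)
    bins, fractions = bin_bayes_factors(bf_volume)
    return BFMap(bfmap=bf_volume, bins=bins, bin_fractions=fractions, prior_scale=prior_scale)


def bin_bayes_factors(bfmap: Volume3D) -> tuple[Volume3D, dict[str, float]]:
    """Assign conventional evidence categories to a Bayes-factor map.

    BF < 1/3 moderate-or-more evidence for h0; 1/3 <= BF < 1 anecdotal
    h0; 1 <= BF <= 3 anecdotal h1; 3 < BF <= 10 moderate h1;
    10 < BF <= 30 strong h1; BF > 30 very strong h1.  Returns the coded
    bin volume (-1 outside the tested region) and the fraction of tested
    voxels per bin (summing to 1).
    """
    bf = np.asarray(bfmap.data, dtype=float)
    tested = np.isfinite(bf)
    if np.any(bf[tested] <= 0):
        raise ValueError("Bayes factors must be positive")
    codes = np.full(bf.shape, -1, dtype=np.int8)
    v = bf[tested]
    c = np.empty(v.shape, dtype=np.int8)
    c[v < 1 / 3] = 0
    c[(v >= 1 / 3) & (v < 1)] = 1
    c[(v >= 1) & (v <= 3)] = 2
    c[(v > 3) & (v <= 10)] = 3
    c[(v > 10) & (v <= 30)] = 4
    c[v > 30] = 5
    codes[tested] = c
    n_tested = int(tested.sum())
    fractions = {
        name: (float(np.sum(c == i)) / n_tested if n_tested else 0.0)
        for i, name in enumerate(BF_BIN_NAMES)
    }
    return Volume3D(data=codes, affine=bfmap.affine, space_tag=bfmap.space_tag), fractions
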