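"""Mass-univariate GLM, permutation FWE and Bayes-factor mapping."""

import numpy as np
import pytest
from scipy import stats

from neglectdisc.core_io import Volume3D
from neglectdisc.voxel_stats import (BF_BIN_NAMES, T_CAP, bayes_factor_map,
                                     bayes_factor_regression, bin_bayes_factors,
                                     max_stat_fwe, max_stat_fwe_array,
                                     voxelwise_glm, voxelwise_t)


def _vols(stack):
    return [Volume3D(data=np.asarray(s, dtype=float), affine=np.eye(4)) for s in stack]


class TestVoxelwiseT:
    def test_matches_closed_form_on_hand_built_data(self, rng):
        """t = r*sqrt((n-2)/(1-r^2)) against scipy's pearsonr, n = 6."""
        X = rng.standard_normal((6, 10))
        y = rng.standard_normal(6)
        t = voxelwise_t(X, y)
        for j in range(10):
            r = stats.pearsonr(X[:, j], y).statistic
            assert t[j] == pytest.approx(r * np.sqrt(4 / (1 - r ** 2)))

    def test_constant_voxel_is_missing(self, rng):
        X = rng.standard_normal((5, 3))
        X[:, 1] = 2.0
        t = voxelwise_t(X, rng.standard_normal(5))
        assert np.isnan(t[1]) and np.isfinite(t[[0, 2]]).all()

    def test_perfect_fit_reported_as_capped_max(self):
        x = np.arange(5.0)[:, None]
        t = voxelwise_t(x, 2 * x.ravel() + 1)
        assert t[0] == T_CAP

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            voxelwise_t(rng.standard_normal((5, 2)), np.ones(5))

    def test_volume_wrapper_restricts_to_complete_cases(self, rng):
        stack = rng.standard_normal((4, 2, 2, 2))
        stack[0, 0, 0, 0] = np.nan
        tmap = voxelwise_glm(_vols(stack), rng.standard_normal(4)).data
        assert np.isnan(tmap[0, 0, 0])
        assert np.isfinite(tmap[1, 1, 1])


class TestMaxStatFWE:
    def test_single_voxel_reduces_to_permutation_correlation_test(self, rng):
        """With one voxel, max-stat FWE is an ordinary permutation test."""
        n = 7
        x = rng.standard_normal((n, 1))
        y = 0.9 * x.ravel() + 0.3 * rng.standard_normal(n)
        res = max_stat_fwe_array(x, y, n_perm=5040, alpha=0.05, tails="two", rng=0)
        # exhaustive oracle: permutation p of |t| by direct enumeration
        from itertools import permutations
        t_obs = abs(voxelwise_t(x, y)[0])
        null = [abs(voxelwise_t(x, np.asarray(p))[0]) for p in permutations(y)]
        p_exact = np.mean(np.asarray(null) >= t_obs)
        assert res["sig"][0] == (p_exact <= 0.05)

    def test_exhaustive_threshold_matches_enumeration(self, rng):
        """n=6 -> all 720 permutations are enumerated, not sampled."""
        from itertools import permutations
        X = rng.standard_normal((6, 15))
        y = rng.standard_normal(6)
        res = max_stat_fwe_array(X, y, n_perm=720, alpha=0.05, tails="two", rng=0)
        assert res["n_perm"] == 720
        maxes = []
        for p in permutations(y):
            ts = [abs(stats.pearsonr(X[:, j], p).statistic) for j in range(15)]
            ts = [t * np.sqrt(4 / (1 - t ** 2)) for t in ts]
            maxes.append(max(ts))
        oracle = float(np.quantile(maxes, 0.95, method="higher"))
        assert res["threshold"] == pytest.approx(oracle, rel=1e-9)

    def test_threshold_monotone_in_number_of_voxels(self, rng):
        y = rng.standard_normal(15)
        X = rng.standard_normal((15, 400))
        t_small = max_stat_fwe_array(X[:, :20], y, n_perm=300, rng=1)["threshold"]
        t_large = max_stat_fwe_array(X, y, n_perm=300, rng=1)["threshold"]
        assert t_large >= t_small

    def test_addone_p_values_are_positive(self, rng):
        X = rng.standard_normal((8, 5))
        y = X[:, 0] * 2  # strong effect -> smallest possible p
        res = max_stat_fwe_array(X, y, n_perm=99, rng=0)
        assert np.all(res["p_fwe"] >= 1 / 100)

    def test_volume_wrapper_marks_suprathreshold_voxels(self, rng):
        stack = rng.standard_normal((12, 3, 3, 3))
        y = 1.5 * stack[:, 1, 1, 1] + 0.2 * rng.standard_normal(12)
        sm = max_stat_fwe(_vols(stack), y, n_perm=300, alpha=0.05, rng=0)
        assert sm.sig_mask.data[1, 1, 1] == 1
        assert sm.sig_mask.data.sum() <= 3
        assert abs(sm.tmap.data[1, 1, 1]) > sm.fwe_threshold

    def test_invalid_parameters_rejected(self, rng):
        X, y = rng.standard_normal((6, 2)), rng.standard_normal(6)
        with pytest.raises(ValueError):
            max_stat_fwe_array(X, y, alpha=1.5)
        with pytest.raises(ValueError):
            max_stat_fwe_array(X, y, n_perm=0)


class TestBayesFactors:
    def test_null_data_gives_bf_below_one(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert bayes_factor_regression(r2, 40) < 1

    def test_strong_effect_gives_very_strong_evidence(self):
        assert bayes_factor_regression(0.81, 40) > 30

    def test_bf_moves_away_from_one_with_n_at_fixed_r(self):
        """Duplicating rows (fixed r, growing n) is monotone evidence."""
        grow = [bayes_factor_regression(0.25, n) for n in (10, 40, 160)]
        assert grow[0] < grow[1] < grow[2]
        shrink = [bayes_factor_regression(0.0, n) for n in (10, 40, 160)]
        assert shrink[0] > shrink[1] > shrink[2]

    def test_map_wrapper_and_bins(self, rng):
        stack = rng.standard_normal((40, 2, 2, 1))
        y = 2.0 * stack[:, 0, 0, 0] + 0.1 * rng.standard_normal(40)
        bfm = bayes_factor_map(_vols(stack), y)
        assert bfm.bfmap.data[0, 0, 0] > 30
        assert sum(bfm.bin_fractions.values()) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            bayes_factor_regression(1.5, 40)
        with pytest.raises(ValueError):
            bayes_factor_regression(0.2, 3)


class TestBinning:
    @pytest.mark.parametrize("bf,expected", [
        (0.2, "h0_moderate_or_more"),
        (0.5, "h0_anecdotal"),
        (1.0, "h1_anecdotal"),
        (2.9, "h1_anecdotal"),
        (5.0, "h1_moderate"),
        (10.0, "h1_moderate"),
        (12.0, "h1_strong"),
        (30.0, "h1_strong"),
        (31.0, "h1_very_strong"),
    ])
    def test_evidence_category_boundaries(self, bf, expected):
        vol = Volume3D(data=np.full((1, 1, 1), bf), affine=np.eye(4))
        codes, fractions = bin_bayes_factors(vol)
        assert BF_BIN_NAMES[int(codes.data[0, 0, 0])] == expected
        assert fractions[expected] == 1.0

    def test_fractions_partition_tested_voxels(self, rng):
        data = np.exp(rng.normal(0, 2, (4, 4, 4)))
        data[0, 0, 0] = np.nan  # untested
        codes, fractions = bin_bayes_factors(Volume3D(data=data, affine=np.eye(4)))
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert codes.data[0, 0, 0] == -1

    def test_nonpositive_bf_rejected(self):
        vol = Volume3D(data=np.zeros((1, 1, 1)), affine=np.eye(4))
        with pytest.raises(ValueError, match="positive"):
            bin_bayes_factors(vol)
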