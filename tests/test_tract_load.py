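"""Tract lesion load measures and the Experiment-3 association statistics."""

import numpy as np
import pytest

from neglectdisc.core_io import Volume3D
from neglectdisc.tract_load import (TractAtlas, binarize_tract, bonferroni,
                                    build_load_table, kendall_tau, lesion_load,
                                    presence_chi_square, weighted_lesion_load)


def _vol(data):
    return Volume3D(data=np.asarray(data, dtype=float), affine=np.eye(4))


class TestBinarize:
    def test_threshold_is_inclusive(self):
        prob = np.zeros((2, 2, 2))
        prob[0, 0, 0] = 0.3
        prob[1, 1, 1] = 0.29
        mask = binarize_tract(_vol(prob), 0.3).data
        assert mask[0, 0, 0] == 1 and mask[1, 1, 1] == 0

    def test_threshold_one_keeps_only_certain_voxels(self):
        prob = np.zeros((2, 2, 2))
        prob[0, 0, 0] = 1.0
        prob[0, 0, 1] = 0.999
        assert binarize_tract(_vol(prob), 1.0).data.sum() == 1

    def test_vanishing_tract_is_an_error_naming_it(self):
        with pytest.raises(ValueError, match="uf_like"):
            binarize_tract(_vol(np.full((2, 2, 2), 0.2)), 0.3, name="uf_like")


class TestLoadMeasures:
    def test_lesion_superset_gives_full_load(self, rng):
        tract = (rng.random((5, 5, 5)) < 0.3).astype(float)
        tract[0, 0, 0] = 1.0
        assert lesion_load(_vol(np.ones((5, 5, 5))), _vol(tract)) == 1.0

    def test_disjoint_masks_give_zero(self):
        lesion = np.zeros((4, 4, 4)); lesion[0] = 1
        tract = np.zeros((4, 4, 4)); tract[3] = 1
        assert lesion_load(_vol(lesion), _vol(tract)) == 0.0
        assert weighted_lesion_load(_vol(lesion), _vol(tract * 0.7)) == 0.0

    def test_partial_overlap_fraction(self):
        tract = np.zeros((10, 1, 1)); tract[:, 0, 0] = 1  # 10 voxels
        lesion = np.zeros((10, 1, 1)); lesion[:3, 0, 0] = 1
        assert lesion_load(_vol(lesion), _vol(tract)) == pytest.approx(0.3)

    def test_weighted_load_direct_sum(self):
        prob = np.zeros((4, 1, 1))
        prob[:, 0, 0] = [0.5, 0.3, 0.7, 0.5]  # mass 2.0
        lesion = np.zeros((4, 1, 1)); lesion[:2, 0, 0] = 1
        assert weighted_lesion_load(_vol(lesion), _vol(prob)) == pytest.approx(0.4)

    def test_weighted_equals_binary_on_binary_map(self, rng):
        tract = (rng.random((6, 6, 6)) < 0.4).astype(float)
        tract[0, 0, 0] = 1.0
        lesion = (rng.random((6, 6, 6)) < 0.3).astype(float)
        assert weighted_lesion_load(_vol(lesion), _vol(tract)) == pytest.approx(
            lesion_load(_vol(lesion), _vol(tract)))

    def test_loads_match_bruteforce_voxel_enumeration(self, rng):
        """Both measures equal the brute-force voxel count/sum exactly."""
        for _ in range(25):
            shape = tuple(rng.integers(3, 7, 3))
            lesion = (rng.random(shape) < 0.3).astype(float)
            prob = rng.random(shape) * (rng.random(shape) < 0.5)
            prob.flat[0] = 0.9
            num = den = wnum = 0.0
            for idx in np.ndindex(shape):
                if prob[idx] >= 0.3:
                    den += 1
                    num += lesion[idx]
                wnum += prob[idx] * lesion[idx]
            if den:
                mask = binarize_tract(_vol(prob), 0.3)
                assert lesion_load(_vol(lesion), mask) == pytest.approx(num / den)
            assert weighted_lesion_load(_vol(lesion), _vol(prob)) == pytest.approx(
                wnum / prob.sum())

    def test_monotone_in_lesion_growth(self, rng):
        tract = rng.random((6, 6, 6))
        tract[tract < 0.2] = 0
        small = (rng.random((6, 6, 6)) < 0.2).astype(float)
        grown = np.clip(small + (rng.random((6, 6, 6)) < 0.3), 0, 1)
        assert (weighted_lesion_load(_vol(grown), _vol(tract))
                >= weighted_lesion_load(_vol(small), _vol(tract)))

    def test_load_table_shape_and_bounds(self, cohort, anatomy):
        table = build_load_table(cohort.lesions, anatomy.tract_atlas,
                                 cohort.patient_ids)
        assert table.load.shape == (len(cohort.lesions), 4)
        assert ((table.load >= 0) & (table.load <= 1)).all().all()
        np.testing.assert_allclose(table.total, table.load.sum(axis=1))


class TestKendall:
    def test_perfect_concordance_and_reversal(self):
        load = np.arange(8.0)
        tau, _ = kendall_tau(load, load * 2 + 1)
        assert tau == pytest.approx(1.0)
        tau, _ = kendall_tau(load, -load)
        assert tau == pytest.approx(-1.0)

    def test_tau_b_matches_allpairs_oracle_with_ties(self, rng):
        """tau-b from brute-force pair counting with tie correction, n = 8."""
        for _ in range(10):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 4, 8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            conc = disc = tx = ty = 0
            for i in range(8):
                for j in range(i + 1, 8):
                    a, b = x[i] - x[j], y[i] - y[j]
                    if a == 0 and b == 0:
                        continue
                    if a == 0:
                        tx += 1
                    elif b == 0:
                        ty += 1
                    elif a * b > 0:
                        conc += 1
                    else:
                        disc += 1
            n0 = 8 * 7 / 2
            n1 = sum(t * (t - 1) / 2 for t in np.unique(x, return_counts=True)[1])
            n2 = sum(t * (t - 1) / 2 for t in np.unique(y, return_counts=True)[1])
            oracle = (conc - disc) / np.sqrt((n0 - n1) * (n0 - n2))
            tau, _ = kendall_tau(x, y)
            assert tau == pytest.approx(oracle)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau(np.ones(6), np.arange(6.0))


class TestBonferroni:
    def test_multiplies_by_test_count(self):
        np.testing.assert_allclose(bonferroni(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.08, 0.12, 0.16])

    def test_caps_at_one_and_identity_for_single_test(self):
        assert bonferroni(np.array([0.5, 0.5, 0.5, 0.5]))[0] == 1.0
        assert bonferroni(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.2]))


class TestPresenceChiSquare:
    def test_independent_table_gives_zero(self):
        chi2, df, p = presence_chi_square(np.array([[5, 5], [5, 5]]))
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_perfect_association_equals_n(self):
        chi2, _, _ = presence_chi_square(np.array([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)

    def test_transpose_invariance(self, rng):
        t = rng.integers(1, 20, (2, 2))
        a = presence_chi_square(t)
        b = presence_chi_square(t.T)
        assert a[0] == pytest.approx(b[0]) and a[2] == pytest.approx(b[2])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            presence_chi_square(np.array([[0, 0], [5, 5]]))


def test_tract_atlas_validation(rng):
    bad = {"t": _vol(np.full((3, 3, 3), 1.2))}
    with pytest.raises(ValueError, match="outside"):
        TractAtlas(tracts=bad)
    empty = {"t": _vol(np.zeros((3, 3, 3)))}
    with pytest.raises(ValueError, match="mass"):
        TractAtlas(tracts=empty)
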