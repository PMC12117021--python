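"""Lesion-streamline intersection and the streamline-wise permutation GLM."""

import numpy as np
import pytest

from neglectdisc.core_io import StreamlineSet, Volume3D
from neglectdisc.streamline_disconnection import (DisconnectionMatrix,
                                                  assign_tracts, build_matrix,
                                                  filter_prevalence,
                                                  resample_polyline,
                                                  streamline_glm,
                                                  streamline_intersects,
                                                  two_sample_t)
from neglectdisc.synthetic_data import make_planted_disconnection


def _lesion(shape, coords):
    data = np.zeros(shape, dtype=np.uint8)
    for c in coords:
        data[tuple(c)] = 1
    return Volume3D(data=data, affine=np.eye(4))


class TestIntersection:
    def test_vertex_inside_lesion_voxel(self):
        lesion = _lesion((5, 5, 5), [(2, 2, 2)])
        line = np.array([[0.0, 0, 0], [2.1, 2.0, 2.2]])
        assert streamline_intersects(lesion, line)

    def test_line_outside_bounding_box(self):
        lesion = _lesion((5, 5, 5), [(2, 2, 2)])
        line = np.array([[0.0, 0, 0], [0.0, 4, 0], [0.0, 4, 4]])
        assert not streamline_intersects(lesion, line)

    def test_segment_crossing_between_coarse_vertices(self):
        """A 1-voxel lesion crossed mid-segment is caught only by resampling."""
        lesion = _lesion((9, 9, 9), [(4, 4, 4)])
        line = np.array([[4.0, 4.0, 0.0], [4.0, 4.0, 8.0]])  # passes through (4,4,4)
        vox_hits_vertices_only = any(
            lesion.data[tuple(np.round(p).astype(int))] for p in line)
        assert not vox_hits_vertices_only
        assert streamline_intersects(lesion, line, step_mm=0.5)

    def test_step_refinement_agrees_with_dense_sampling(self, cohort, anatomy):
        """step 0.5 mm decisions match a 0.01 mm dense-sampling oracle on
        the synthetic suite (tract streamlines against cohort lesions)."""
        lines = anatomy.streamlines.streamlines[::5]
        for lesion in cohort.lesions[:6]:
            for line in lines:
                coarse = streamline_intersects(lesion, line, step_mm=0.5)
                dense = streamline_intersects(lesion, line, step_mm=0.01)
                assert coarse == dense

    def test_decreasing_step_never_loses_a_hit(self, rng):
        """Refining the sampling step can only add detections."""
        lesion = Volume3D(data=(rng.random((12, 12, 12)) < 0.03).astype(np.uint8),
                          affine=np.eye(4))
        for _ in range(40):
            pts = rng.uniform(0, 11, (4, 3))
            if streamline_intersects(lesion, pts, step_mm=0.5):
                assert streamline_intersects(lesion, pts, step_mm=0.01)

    def test_monotone_in_lesion_growth(self, rng):
        small = (rng.random((10, 10, 10)) < 0.05).astype(np.uint8)
        grown = np.clip(small + (rng.random((10, 10, 10)) < 0.1), 0, 1)
        for _ in range(20):
            line = rng.uniform(0, 9, (5, 3))
            hit_small = streamline_intersects(Volume3D(data=small, affine=np.eye(4)), line)
            hit_grown = streamline_intersects(Volume3D(data=grown, affine=np.eye(4)), line)
            if hit_small:
                assert hit_grown

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            resample_polyline(np.zeros((1, 3)), 0.5)
        with pytest.raises(ValueError):
            resample_polyline(np.zeros((3, 3)), -1.0)


class TestMatrix:
    def test_build_matrix_matches_pairwise_oracle(self, rng):
        lesions = [Volume3D(data=(rng.random((8, 8, 8)) < 0.05).astype(np.uint8),
                            affine=np.eye(4)) for _ in range(3)]
        lines = [rng.uniform(0, 7, (5, 3)) for _ in range(4)]
        sset = StreamlineSet(streamlines=lines)
        m = build_matrix(lesions, sset)
        for i in range(3):
            for j in range(4):
                assert m.matrix[i, j] == streamline_intersects(lesions[i], lines[j])

    def test_empty_lesion_gives_zero_row(self, rng):
        lesions = [_lesion((6, 6, 6), []), _lesion((6, 6, 6), [(3, 3, 3)])]
        sset = StreamlineSet(streamlines=[np.array([[3.0, 3, 0], [3.0, 3, 5]])])
        m = build_matrix(lesions, sset)
        assert m.matrix[0].sum() == 0
        assert m.matrix[1, 0] == 1

    @pytest.mark.parametrize("k,expected", [(5, 2), (1, 3), (99, 0)])
    def test_prevalence_filter_column_sums(self, k, expected):
        matrix = np.zeros((10, 3), dtype=np.uint8)
        matrix[:3, 0] = 1   # column sums 3, 5, 7
        matrix[:5, 1] = 1
        matrix[:7, 2] = 1
        m = DisconnectionMatrix(matrix, [f"p{i}" for i in range(10)], np.arange(3))
        assert filter_prevalence(m, k).matrix.shape[1] == expected

    def test_filter_preserves_original_streamline_indices(self):
        matrix = np.zeros((6, 3), dtype=np.uint8)
        matrix[:, 2] = 1
        m = DisconnectionMatrix(matrix, [f"p{i}" for i in range(6)], np.arange(3))
        assert filter_prevalence(m, 5).streamline_index.tolist() == [2]


class TestStreamlineGLM:
    def test_two_sample_t_matches_scipy(self, rng):
        from scipy import stats
        X = (rng.random((20, 6)) < 0.4).astype(float)
        y = rng.standard_normal(20)
        t = two_sample_t(X, y)
        for j in range(6):
            g1, g0 = y[X[:, j] == 1], y[X[:, j] == 0]
            if len(g1) and len(g0):
                ref = stats.ttest_ind(g1, g0, equal_var=True).statistic
                assert t[j] == pytest.approx(ref)

    def test_planted_disconnection_detected(self, rng):
        """Disconnected patients shifted by 2 sigma must be found at n=50."""
        X, y, planted = make_planted_disconnection(n_patients=50, rng=rng)
        m = DisconnectionMatrix(X, [f"p{i}" for i in range(50)], np.arange(X.shape[1]))
        res = streamline_glm(m, y, n_perm=500, rng=rng)
        assert np.isin(planted, res["significant"]).mean() >= 0.8

    def test_single_column_reduces_to_permutation_t_test(self, rng):
        n = 7
        x = (np.arange(n) < 3).astype(float)[:, None]
        y = rng.standard_normal(n) + 1.5 * x.ravel()
        m = DisconnectionMatrix(x.astype(np.uint8), [f"p{i}" for i in range(n)],
                                np.arange(1))
        res = streamline_glm(m, y, n_perm=5040, alpha=0.05, rng=0)
        # exhaustive one-tailed permutation t-test oracle
        from itertools import permutations
        t_obs = two_sample_t(x, y)[0]
        null = [two_sample_t(x, np.asarray(p))[0] for p in permutations(y)]
        p_exact = np.mean(np.asarray(null) >= t_obs)
        assert (len(res["significant"]) == 1) == (p_exact <= 0.05)

    def test_empty_matrix_returns_empty_result(self):
        m = DisconnectionMatrix(np.zeros((5, 0), dtype=np.uint8),
                                [f"p{i}" for i in range(5)], np.arange(0))
        res = streamline_glm(m, np.arange(5.0))
        assert len(res["significant"]) == 0 and res["n_tested"] == 0

    def test_filter_then_glm_uses_only_surviving_columns(self, rng):
        """The permutation null must not leak filtered-out columns."""
        X, y, _ = make_planted_disconnection(n_patients=30, n_streamlines=50,
                                             prevalence=(2, 12), rng=rng)
        m = DisconnectionMatrix(X, [f"p{i}" for i in range(30)], np.arange(50))
        filtered = filter_prevalence(m, 5)
        res_a = streamline_glm(filtered, y, n_perm=200, rng=7)
        keep = X.sum(axis=0) >= 5
        m_b = DisconnectionMatrix(X[:, keep], [f"p{i}" for i in range(30)],
                                  np.flatnonzero(keep))
        res_b = streamline_glm(m_b, y, n_perm=200, rng=7)
        assert res_a["threshold"] == res_b["threshold"]
        np.testing.assert_array_equal(res_a["significant"], res_b["significant"])


class TestAssignTracts:
    def test_homogeneous_label_set(self):
        sset = StreamlineSet(streamlines=[np.zeros((2, 3)) + i for i in range(12)],
                             tract_labels=["corticostriatal"] * 12)
        assert assign_tracts(np.arange(12), sset) == {"corticostriatal": 12}

    def test_empty_selection(self):
        sset = StreamlineSet(streamlines=[np.zeros((2, 3))], tract_labels=["a"])
        assert assign_tracts(np.array([]), sset) == {}

    def test_mixed_and_missing_labels(self):
        sset = StreamlineSet(streamlines=[np.zeros((2, 3)) + i for i in range(3)],
                             tract_labels=["a", "a", "b"])
        assert assign_tracts(np.array([0, 1, 2]), sset) == {"a": 2, "b": 1}
        unlabelled = StreamlineSet(streamlines=[np.zeros((2, 3))])
        assert assign_tracts(np.array([0]), unlabelled) == {"unlabelled": 1}
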