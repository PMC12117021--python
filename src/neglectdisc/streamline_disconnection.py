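"""Streamline-level structural disconnection analysis.

Each lesion mask is intersected with a normative streamline set: a
streamline counts as disconnected when any point along it (the original
vertices plus dense arc-length resampling, so segments crossing a voxel
between vertices are not missed) falls inside a lesion voxel.  The
resulting patients x streamlines binary matrix is filtered to
streamlines disconnected in at least k patients, tested streamline-wise
against severity with a one-tailed two-sample t statistic under
max-statistic permutation FWE, and the significant streamlines are
aggregated per fibre tract using the labels carried by the streamline
set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core_io import StreamlineSet, Volume3D, check_same_grid, world_to_voxel
from .voxel_stats import max_stat_fwe_array

__all__ = [
    "DisconnectionMatrix",
    "resample_polyline",
    "streamline_intersects",
    "build_matrix",
    "filter_prevalence",
    "two_sample_t",
    "streamline_glm",
    "assign_tracts",
]

#: default arc-length sampling step, half of a 1 mm voxel edge
DEFAULT_STEP_MM = 0.5


@dataclass
class DisconnectionMatrix:
    """Binary patients x streamlines disconnection indicators."""

    matrix: np.ndarray
    patient_ids: list[str]
    streamline_index: np.ndarray  # indices into the originating StreamlineSet

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        self.streamline_index = np.asarray(self.streamline_index, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2D")
        if not np.all(np.isin(self.matrix, (0, 1))):
            raise ValueError("matrix entries must be binary")
        if self.matrix.shape != (len(self.patient_ids), len(self.streamline_index)):
            raise ValueError("matrix shape inconsistent with ids/index")


def resample_polyline(line: np.ndarray, step_mm: float) -> np.ndarray:
    """Original vertices plus points every <= step_mm of arc length."""
    line = np.asarray(line, dtype=float)
    if line.shape[0] < 2:
        raise ValueError("degenerate polyline")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    pieces = [line[[0]]]
    for a, b in zip(line[:-1], line[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n_extra = int(np.ceil(length / step_mm)) if length > 0 else 1
        ts = np.linspace(0.0, 1.0, n_extra + 1)[1:]
        pieces.append(a + ts[:, None] * seg)
    return np.vstack(pieces)


def streamline_intersects(lesion: Volume3D, line: np.ndarray,
                          step_mm: float = DEFAULT_STEP_MM) -> bool:
    """True iff any resampled point of the polyline maps to a lesion voxel."""
    pts = resample_polyline(line, step_mm)
    vox = world_to_voxel(lesion, pts)
    shape = np.array(lesion.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    if not inside.any():
        return False
    v = vox[inside]
    return bool(np.any(lesion.data[v[:, 0], v[:, 1], v[:, 2]] > 0.5))


def build_matrix(lesions: list[Volume3D], sset: StreamlineSet,
                 patient_ids: list[str] | None = None,
                 step_mm: float = DEFAULT_STEP_MM) -> DisconnectionMatrix:
    """Disconnection indicator for every (lesion, streamline) pair.

    Streamlines are resampled once and converted to flat voxel indices,
    so each lesion reduces to one vectorised lookup.
    """
    if patient_ids is None:
        patient_ids = [f"p{i:03d}" for i in range(len(lesions))]
    check_same_grid(*lesions)
    ref = lesions[0]
    shape = np.array(ref.shape)
    # precompute in-bounds flat voxel indices per streamline
    flat_per_line: list[np.ndarray] = []
    for line in sset.streamlines:
        vox = world_to_voxel(ref, resample_polyline(line, step_mm))
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        v = vox[inside]
        flat = np.unique(np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), tuple(shape))) \
            if len(v) else np.empty(0, dtype=int)
        flat_per_line.append(flat)
    matrix = np.zeros((len(lesions), len(sset)), dtype=np.uint8)
    for i, lesion in enumerate(lesions):
        flat_lesion = lesion.data.reshape(-1) > 0.5
        for j, flat in enumerate(flat_per_line):
            if len(flat) and flat_lesion[flat].any():
                matrix[i, j] = 1
    return DisconnectionMatrix(matrix=matrix, patient_ids=list(patient_ids),
                               streamline_index=np.arange(len(sset)))


def filter_prevalence(m: DisconnectionMatrix, k: int) -> DisconnectionMatrix:
    """Keep streamlines disconnected in at least k patients."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = m.matrix.sum(axis=0) >= k
    return DisconnectionMatrix(matrix=m.matrix[:, keep],
                               patient_ids=m.patient_ids,
                               streamline_index=m.streamline_index[keep])


def two_sample_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per binary column of X.

    Sign convention: disconnected minus not-disconnected, so positive t
    means disconnection goes with higher severity.  Columns with a
    constant indicator (all 0 or all 1) return NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n1 = X.sum(axis=0)
    n0 = n - n1
    sum1 = y @ X
    sumsq1 = (y ** 2) @ X
    sum_all = y.sum()
    sumsq_all = (y ** 2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = sum1 / n1
        m0 = (sum_all - sum1) / n0
        ss1 = sumsq1 - n1 * m1 ** 2
        ss0 = (sumsq_all - sumsq1) - n0 * m0 ** 2
        sp2 = (ss1 + ss0) / (n - 2)
        t = (m1 - m0) / np.sqrt(np.maximum(sp2, 1e-300) * (1 / n1 + 1 / n0))
    t = np.asarray(t)
    t[(n1 == 0) | (n0 == 0)] = np.nan
    return t


def _two_sample_t_perm(X: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """two_sample_t for every permuted y (rows of perms) at once."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n1 = X.sum(axis=0)
    n0 = n - n1
    sum1 = perms @ X                      # (n_perm, cols)
    sumsq1 = (perms ** 2) @ X
    sum_all = perms.sum(axis=1, keepdims=True)
    sumsq_all = (perms ** 2).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = sum1 / n1
        m0 = (sum_all - sum1) / n0
        ss1 = sumsq1 - n1 * m1 ** 2
        ss0 = (sumsq_all - sumsq1) - n0 * m0 ** 2
        sp2 = (ss1 + ss0) / (n - 2)
        t = (m1 - m0) / np.sqrt(np.maximum(sp2, 1e-300) * (1 / n1 + 1 / n0))
    t[:, (n1 == 0) | (n0 == 0)] = np.nan
    return t


def streamline_glm(m: DisconnectionMatrix, y: np.ndarray, n_perm: int = 10000,
                   alpha: float = 0.05,
                   rng: np.random.Generator | int | None = 0) -> dict:
    """One-tailed max-t permutation FWE across streamline indicators.

    Tests whether disconnection of each streamline is associated with
    higher severity; the null is formed by permuting severity and
    recording the maximum t over the tested (post-filter) columns only.
    Returns significant original streamline indices plus the threshold
    and per-column statistics.
    """
    if m.matrix.shape[1] == 0:
        return {"significant": np.empty(0, dtype=int), "t": np.empty(0),
                "threshold": np.nan, "n_tested": 0, "n_perm": n_perm}
    X = m.matrix.astype(float)
    col_sums = X.sum(axis=0)
    testable = (col_sums > 0) & (col_sums < len(y))  # constant columns excluded
    res = max_stat_fwe_array(X[:, testable], np.asarray(y, float), n_perm=n_perm,
                             alpha=alpha, tails="one", rng=rng,
                             statistic=two_sample_t,
                             perm_statistic=_two_sample_t_perm)
    sig_local = np.flatnonzero(testable)[res["sig"]]
    t_full = np.full(m.matrix.shape[1], np.nan)
    t_full[testable] = res["t"]
    return {
        "significant": m.streamline_index[sig_local],
        "t": t_full,
        "threshold": res["threshold"],
        "n_tested": int(testable.sum()),
        "n_perm": res["n_perm"],
    }


def assign_tracts(indices: np.ndarray, sset: StreamlineSet) -> dict[str, int]:
    """Count significant streamlines per tract label ('unlabelled' if absent)."""
    counts: Counter[str] = Counter()
    for idx in np.asarray(indices, dtype=int):
        if sset.tract_labels is None:
            counts["unlabelled"] += 1
        else:
            counts[sset.tract_labels[idx] or "unlabelled"] += 1
    return dict(counts)
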