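"""Tract-wise lesion load and its association statistics.

Lesion load of a fibre tract is the damaged fraction of the tract: the
probabilistic tract map is binarised at p >= 0.3 (the conventional
cut-off for histology-based tract atlases) and the load is
|lesion AND tract| / |tract|.  A weighted variant keeps the full
probabilistic information, summing tract probability over lesioned
voxels and normalising by the tract's total probability mass so both
measures live on [0, 1].

Association with neglect severity is assessed per tract and on the
total load with Kendall's tau-b, Bonferroni-corrected over tracts, and
the binary presence of any load is compared between neglect groups with
a Pearson chi-square test (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Volume3D, check_same_grid

__all__ = [
    "TractAtlas",
    "LesionLoadTable",
    "binarize_tract",
    "lesion_load",
    "weighted_lesion_load",
    "build_load_table",
    "kendall_tau",
    "bonferroni",
    "presence_chi_square",
]

DEFAULT_THRESHOLD = 0.3


@dataclass
class TractAtlas:
    """Named probabilistic tract maps (values in [0,1]) on one grid."""

    tracts: dict[str, Volume3D]

    def __post_init__(self) -> None:
        for name, vol in self.tracts.items():
            d = np.asarray(vol.data)
            if np.any(d < 0) or np.any(d > 1):
                raise ValueError(f"tract {name}: probabilities outside [0,1]")
            if d.sum() <= 0:
                raise ValueError(f"tract {name}: zero probability mass")
        check_same_grid(*self.tracts.values())

    @property
    def names(self) -> list[str]:
        return list(self.tracts)


@dataclass
class LesionLoadTable:
    load: pd.DataFrame      # patients x tracts, values in [0,1]
    weighted: bool

    def __post_init__(self) -> None:
        vals = self.load.to_numpy(dtype=float)
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("lesion loads must lie in [0,1]")

    @property
    def total(self) -> pd.Series:
        return self.load.sum(axis=1)


def binarize_tract(prob: Volume3D, threshold: float = DEFAULT_THRESHOLD,
                   name: str = "tract") -> Volume3D:
    """Binary tract mask: 1 where probability >= threshold (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0,1]")
    mask = (np.asarray(prob.data, dtype=float) >= threshold).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError(f"tract '{name}' vanishes at threshold {threshold}")
    return Volume3D(data=mask, affine=prob.affine, space_tag=prob.space_tag)


def lesion_load(lesion: Volume3D, tract_mask: Volume3D) -> float:
    """Damaged fraction of a binary tract mask: |lesion & tract| / |tract|."""
    check_same_grid(lesion, tract_mask)
    tract = np.asarray(tract_mask.data) > 0.5
    n_tract = int(tract.sum())
    if n_tract == 0:
        raise ValueError("empty tract mask")
    overlap = int(np.sum(tract & (np.asarray(lesion.data) > 0.5)))
    return overlap / n_tract


def weighted_lesion_load(lesion: Volume3D, prob: Volume3D) -> float:
    """Probability-weighted load: sum of tract probability over lesioned
    voxels, normalised by the tract's total probability mass."""
    check_same_grid(lesion, prob)
    p = np.asarray(prob.data, dtype=float)
    mass = p.sum()
    if mass <= 0:
        raise ValueError("tract has zero probability mass")
    return float(p[np.asarray(lesion.data) > 0.5].sum() / mass)


def build_load_table(lesions: list[Volume3D], atlas: TractAtlas,
                     patient_ids: list[str] | None = None,
                     weighted: bool = False,
                     threshold: float = DEFAULT_THRESHOLD) -> LesionLoadTable:
    """Per-patient, per-tract lesion load table (binary or weighted mode)."""
    if patient_ids is None:
        patient_ids = [f"p{i:03d}" for i in range(len(lesions))]
    masks = None
    if not weighted:
        masks = {name: binarize_tract(vol, threshold, name)
                 for name, vol in atlas.tracts.items()}
    rows = {}
    for pid, lesion in zip(patient_ids, lesions):
        if weighted:
            rows[pid] = {name: weighted_lesion_load(lesion, vol)
                         for name, vol in atlas.tracts.items()}
        else:
            rows[pid] = {name: lesion_load(lesion, masks[name])
                         for name in atlas.tracts}
    df = pd.DataFrame.from_dict(rows, orient="index")[atlas.names]
    return LesionLoadTable(load=df, weighted=weighted)


def kendall_tau(load: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b with tie correction; two-sided normal-approximation p."""
    load = np.asarray(load, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(load) != len(y) or len(load) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    if np.ptp(load) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.kendalltau(load, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """min(1, m*p) for m simultaneous tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0,1]")
    return np.minimum(1.0, p * p.size)


def presence_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (df=1, no Yates correction) on a 2x2 count table."""
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
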