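"""Lesion-network mapping from a normative resting-state connectome.

A patient's binary lesion mask is used as a seed region in resting-state
fMRI of healthy reference subjects: per subject, the mean seed time
course is correlated with every brain voxel, the Pearson r map is Fisher
z-transformed, and the z maps are averaged voxel-wise across subjects.
The result estimates the functional network of the lesioned tissue
without needing any patient fMRI.

Because voxels inside (or near) the seed trivially correlate with the
seed mean, the map is usually masked to cortical grey matter before
statistics, removing the subcortical seed region and white matter where
autocorrelation would inflate apparent connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Parcellation, Volume3D, Volume4D, check_same_grid

__all__ = [
    "LesionNetworkMap",
    "seed_timecourse",
    "correlation_map",
    "fisher_z",
    "lesion_network_map",
]

#: |r| at or beyond this is clipped before atanh, keeping z finite
R_CLIP = 1.0 - 1e-7


@dataclass
class LesionNetworkMap:
    """Subject-averaged Fisher-z map for one lesion; NaN marks missing."""

    zmap: Volume3D
    patient_id: str
    n_subjects: int
    masked: bool


def seed_timecourse(ts: Volume4D, seed: Volume3D) -> np.ndarray:
    """Mean time series over the seed voxels."""
    check_same_grid(ts, seed)
    mask = np.asarray(seed.data) > 0.5
    if not mask.any():
        raise ValueError("seed mask is empty")
    return ts.data[mask].mean(axis=0)


def correlation_map(ts: Volume4D, seed_tc: np.ndarray) -> Volume3D:
    """Voxel-wise Pearson correlation with a seed time course.

    Constant voxels get NaN (undefined correlation), never 0.
    """
    seed_tc = np.asarray(seed_tc, dtype=float)
    if seed_tc.ndim != 1 or seed_tc.size != ts.n_timepoints:
        raise ValueError("seed time course length must equal the time dimension")
    s = seed_tc - seed_tc.mean()
    s_norm = np.sqrt(np.sum(s ** 2))
    if s_norm == 0:
        raise ValueError("constant seed time course")
    x = ts.data - ts.data.mean(axis=3, keepdims=True)
    x_norm = np.sqrt(np.sum(x ** 2, axis=3))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.tensordot(x, s, axes=([3], [0])) / (x_norm * s_norm)
    r[x_norm == 0] = np.nan
    return Volume3D(data=np.clip(r, -1.0, 1.0), affine=ts.affine, space_tag="synth")


def fisher_z(r: np.ndarray | float | Volume3D):
    """Fisher z = atanh(r), with |r| clipped just below 1 to stay finite."""
    if isinstance(r, Volume3D):
        return Volume3D(data=fisher_z(r.data), affine=r.affine, space_tag=r.space_tag)
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr[np.isfinite(arr)]) > 1):
            raise ValueError("|r| > 1")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def lesion_network_map(seed: Volume3D,
                       connectome: list[Volume4D],
                       parcellation: Parcellation | None = None,
                       mask_cortex: bool = True,
                       patient_id: str = "",
                       detrend: bool = False,
                       min_valid_fraction: float = 0.5) -> LesionNetworkMap:
    """Average Fisher-z seed-correlation map across normative subjects.

    Per subject: seed mean time course -> Pearson r map -> Fisher z.
    Voxels valid in fewer than ``min_valid_fraction`` of subjects are set
    missing.  With ``mask_cortex``, voxels outside the cortical labels of
    ``parcellation`` (the subcortical seed region, white matter) are set
    to NaN after averaging; averaging and masking commute.
    """
    if not connectome:
        raise ValueError("empty connectome")
    if mask_cortex and parcellation is None:
        raise ValueError("mask_cortex requires a parcellation")
    zsum = np.zeros(seed.shape)
    zcount = np.zeros(seed.shape, dtype=int)
    for subj in connectome:
        check_same_grid(subj, seed)
        data = subj.data
        if detrend:
            t = np.arange(data.shape[3], dtype=float)
            t -= t.mean()
            slope = np.tensordot(data - data.mean(axis=3, keepdims=True), t,
                                 axes=([3], [0])) / np.sum(t ** 2)
            data = data - slope[..., None] * t
            subj = Volume4D(data=data, affine=subj.affine, subject_id=subj.subject_id)
        tc = seed_timecourse(subj, seed)
        z = fisher_z(correlation_map(subj, tc).data)
        valid = np.isfinite(z)
        zsum[valid] += z[valid]
        zcount += valid
    n = len(connectome)
    with np.errstate(invalid="ignore"):
        zmean = np.where(zcount >= max(1, int(np.ceil(min_valid_fraction * n))),
                         zsum / np.maximum(zcount, 1), np.nan)
    if mask_cortex:
        assert parcellation is not None
        cortical = parcellation.cortical_mask()
        zmean = np.where(cortical, zmean, np.nan)
    vol = Volume3D(data=zmean, affine=seed.affine, space_tag=seed.space_tag)
    return LesionNetworkMap(zmap=vol, patient_id=patient_id, n_subjects=n, masked=mask_cortex)
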