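"""Spatial data model and I/O for volumes, streamlines and tables.

All volumes in one analysis are required to live on the same voxel grid
(shape and affine equal within a small tolerance); no resampling is ever
performed here.  Streamlines are normalised to world millimetre
coordinates on load, so downstream code never sees the on-disk
voxel-space dialects of TRK files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

__all__ = [
    "Volume3D",
    "Volume4D",
    "Parcellation",
    "StreamlineSet",
    "read_volume",
    "write_volume",
    "read_streamlines",
    "write_streamlines",
    "world_to_voxel",
    "voxel_to_world",
    "check_same_grid",
]

#: tolerance for affine / grid equality checks (mm)
GRID_ATOL = 1e-4

#: tolerance when validating that a mask is binary
BINARY_ATOL = 1e-6


@dataclass
class Volume3D:
    """A 3D scalar volume with its voxel->world affine.

    ``data`` is binary {0,1} for masks, float for statistical maps and
    probabilistic atlases.  ``space_tag`` names the template space so
    volumes from different spaces are never silently combined.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "synth"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"Volume3D needs a non-empty 3D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_binary(self, atol: float = BINARY_ATOL) -> bool:
        d = self.data
        return bool(np.all((np.abs(d) <= atol) | (np.abs(d - 1) <= atol)))


@dataclass
class Volume4D:
    """A 4D (x, y, z, t) BOLD-like time-series volume for one subject."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("Volume4D needs a 4D array")
        if self.data.shape[3] < 2:
            raise ValueError("time dimension must be >= 2")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class Parcellation:
    """Integer-labelled brain parcellation; 0 is background.

    ``cortical_ids`` is the subset of labels forming the cerebral cortex,
    used to mask lesion-network maps to cortical grey matter.
    """

    labels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)
    cortical_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        self.cortical_ids = frozenset(int(i) for i in self.cortical_ids)
        present = set(np.unique(self.labels).tolist())
        missing = self.cortical_ids - present
        if missing:
            raise ValueError(f"cortical ids absent from label volume: {sorted(missing)}")

    def cortical_mask(self) -> np.ndarray:
        """Boolean mask of voxels whose label is cortical."""
        return np.isin(self.labels, list(self.cortical_ids))


@dataclass
class StreamlineSet:
    """Streamline polylines in world mm coordinates, optionally labelled by tract."""

    streamlines: list[np.ndarray]
    tract_labels: list[str] | None = None

    def __post_init__(self) -> None:
        cleaned = []
        for i, line in enumerate(self.streamlines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i}: need >= 2 points of dim 3, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i}: non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned
        if self.tract_labels is not None and len(self.tract_labels) != len(cleaned):
            raise ValueError("tract_labels length must match number of streamlines")

    def __len__(self) -> int:
        return len(self.streamlines)


def read_volume(path: str | Path, expect_binary: bool = False, space_tag: str = "synth") -> Volume3D:
    """Read a 3D NIfTI volume; optionally enforce binary {0,1} data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {data.ndim}D")
    vol = Volume3D(data=data, affine=np.asarray(img.affine), space_tag=space_tag)
    if expect_binary:
        if not vol.is_binary():
            bad = np.unique(data[(np.abs(data) > BINARY_ATOL) & (np.abs(data - 1) > BINARY_ATOL)])
            raise ValueError(f"{path}: expected binary mask, found values {bad[:5]}")
        vol.data = (data > 0.5).astype(np.uint8)
    return vol


def write_volume(vol: Volume3D, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine), str(path))


def read_volume4d(path: str | Path, subject_id: str = "") -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D data, got {data.ndim}D")
    return Volume4D(data=data, affine=np.asarray(img.affine), subject_id=subject_id)


def write_volume4d(vol: Volume4D, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine), str(path))


def read_streamlines(path: str | Path) -> StreamlineSet:
    """Read a TRK or TCK file into world-mm polylines.

    nibabel's tractogram loaders handle the voxel-space conventions of
    each format; `to_world` guarantees RAS+ mm output either way.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".trk":
        tf = TrkFile.load(str(path))
    elif suffix == ".tck":
        tf = TckFile.load(str(path))
    else:
        raise ValueError(f"unsupported streamline format: {suffix} (TRK/TCK only)")
    tractogram = tf.tractogram.to_world()
    lines = [np.asarray(s, dtype=float) for s in tractogram.streamlines]
    if not lines:
        raise ValueError(f"{path}: empty streamline file")
    labels = None
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        import json
        labels = json.loads(sidecar.read_text())
        if len(labels) != len(lines):
            raise ValueError(f"{sidecar}: label count does not match streamlines")
    elif "tract_id" in tractogram.data_per_streamline:
        ids = [int(np.asarray(v).ravel()[0])
               for v in tractogram.data_per_streamline["tract_id"]]
        labels = [f"tract_{i}" for i in ids]
    return StreamlineSet(streamlines=lines, tract_labels=labels)


def write_streamlines(sset: StreamlineSet, path: str | Path,
                      affine_to_rasmm: np.ndarray | None = None,
                      label_ids: dict[str, int] | None = None) -> None:
    """Write streamlines (already world mm) to TRK or TCK.

    Tract labels are written to a ``.labels.json`` sidecar (one name per
    streamline, in order) because TRK/TCK carry numeric per-streamline
    data at best; TRK additionally stores an integer ``tract_id``
    (assignment from ``label_ids`` or alphabetical order) so the file
    remains interpretable in external viewers.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    data_per_streamline = {}
    if sset.tract_labels is not None:
        if label_ids is None:
            label_ids = {lab: i for i, lab in enumerate(sorted(set(sset.tract_labels)))}
        if suffix == ".trk":
            data_per_streamline["tract_id"] = np.array(
                [[float(label_ids[lab])] for lab in sset.tract_labels]
            )
        import json
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        sidecar.write_text(json.dumps(list(sset.tract_labels)) + "\n")
    tractogram = Tractogram(streamlines=sset.streamlines,
                            data_per_streamline=data_per_streamline or None,
                            affine_to_rasmm=np.eye(4))
    suffix = path.suffix.lower()
    if suffix == ".trk":
        header = TrkFile.create_empty_header()
        if affine_to_rasmm is not None:
            header["voxel_to_ras"] = np.asarray(affine_to_rasmm, dtype=np.float32)
            header["voxel_sizes"] = np.abs(np.diag(affine_to_rasmm)[:3]).astype(np.float32)
        TrkFile(tractogram, header=header).save(str(path))
    elif suffix == ".tck":
        TckFile(tractogram).save(str(path))
    else:
        raise ValueError(f"unsupported streamline format: {suffix}")


def voxel_to_world(vol: Volume3D, indices: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Map voxel indices (possibly fractional) to world mm coordinates."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    homog = np.c_[idx, np.ones(len(idx))]
    return (vol.affine @ homog.T).T[:, :3]


def world_to_voxel(vol: Volume3D, points: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Map world mm points to nearest-integer voxel indices.

    A voxel occupies the half-open cube centred on its lattice point, so
    nearest-integer rounding is the membership rule.  Indices may fall
    outside the array; the caller filters.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(vol.affine)
    homog = np.c_[pts, np.ones(len(pts))]
    vox = (inv @ homog.T).T[:, :3]
    return np.round(vox).astype(int)


def check_same_grid(*vols: Volume3D | Volume4D, atol: float = GRID_ATOL) -> None:
    """Hard-error unless all volumes share spatial shape and affine."""
    if len(vols) < 2:
        return
    ref = vols[0]
    ref_shape = ref.data.shape[:3]
    for v in vols[1:]:
        if v.data.shape[:3] != ref_shape:
            raise ValueError(f"grid shape mismatch: {v.data.shape[:3]} vs {ref_shape}")
        if not np.allclose(v.affine, ref.affine, atol=atol):
            raise ValueError("affine mismatch between volumes on one grid")
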