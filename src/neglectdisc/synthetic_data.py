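"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates, on a small 1 mm-isotropic grid, the data a
subcortical-stroke disconnection study consumes: a spherical "brain"
with a shell of cortical parcels, two subcortical grey-matter blobs
(pseudo basal ganglia and pseudo thalamus), four probabilistic fibre
tracts whose centrelines pass directly adjacent to the subcortical
blobs, streamlines sampled inside those tracts, a normative rs-fMRI
connectome with a planted seed-to-cortex network, subcortically centred
lesions with variable encroachment on the tracts, and cancellation-test
behaviour whose severity is a noisy monotone function of total tract
lesion load.

Severity link: the noiseless severity signal is the normal score of the
patient's total tract load; the observed signal mixes it with Gaussian
noise at correlation rho = sin(pi*tau/2), the Gaussian-copula inversion
of Kendall's tau, so the target rank correlation ``effect_size`` is
attained in expectation by construction rather than by tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, stats

from . import behaviour as beh
from .core_io import (Parcellation, StreamlineSet, Volume3D, Volume4D,
                      write_streamlines, write_volume, write_volume4d)
from .tract_load import TractAtlas

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "Anatomy",
    "make_anatomy",
    "make_connectome",
    "make_lesions",
    "make_behaviour",
    "make_cohort",
    "make_planted_disconnection",
    "write_cohort",
]

#: per-test CoC cutoff used for the synthetic neglect diagnosis
DEFAULT_CUTOFF = 0.08

TRACT_NAMES = ("slf_like", "iof_like", "sof_like", "uf_like")
TRACT_SIGMA_MM = 1.5          # Gaussian half-width of the tract profiles
STREAMLINE_JITTER = 1.2       # max offset (x sigma) keeps lines inside p>=0.3


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the clinical study being emulated where it states
    them: 43 patients split ~27/16 between basal-ganglia and thalamic
    stroke, a 100-subject normative connectome, a target rank effect of
    tau ~ 0.3 between total tract load and severity, and lesion volumes
    spanning roughly 8-150 voxels (the study's 0-10.8 cm^3 range scaled
    to the 32^3 grid).
    """

    grid: tuple[int, int, int] = (32, 32, 32)
    n_patients: int = 43
    bg_fraction: float = 27 / 43
    n_subjects: int = 100
    n_timepoints: int = 120
    effect_size: float = 0.3      # target Kendall tau of severity vs total load
    noise_sd: float = 1.0         # scale of the noise component of severity
    lesion_size_range: tuple[int, int] = (8, 150)
    neglect_cutoff: float = DEFAULT_CUTOFF
    # CoC link: coc = coc_scale * exp(coc_shape * severity_z), a strictly
    # monotone, right-skewed placement reproducing the emulated cohort's
    # severity profile (overall mean ~0.15, ~1/3 above the 0.08 cutoff,
    # non-neglect scores piling up near 0)
    coc_scale: float = 0.041
    coc_shape: float = 1.49
    n_streamlines_per_tract: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 24:
            raise ValueError("grid too small to host the anatomy")
        if not (0 <= self.effect_size < 1):
            raise ValueError("effect_size must be in [0,1)")
        for name in ("n_patients", "n_subjects", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 timepoints")


@dataclass
class GroundTruth:
    true_loads: "object"                     # patients x tracts DataFrame
    true_severity_signal: np.ndarray         # noiseless severity (normal scores)
    target_coc: np.ndarray                   # intended CoC per patient
    planted_network_parcel: int
    planted_streamline_ids: np.ndarray | None = None
    groups: list[str] = field(default_factory=list)


@dataclass
class Anatomy:
    parcellation: Parcellation
    brain_mask: Volume3D
    subcortical_rois: dict[str, Volume3D]    # basal_ganglia, thalamus
    tract_atlas: TractAtlas
    streamlines: StreamlineSet
    tract_centrelines: dict[str, np.ndarray]  # world mm polylines


def _affine(grid: tuple[int, int, int]) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, 3] = -np.asarray(grid, dtype=float) / 2  # centre the template
    return aff


def _sphere(grid, centre, radii) -> np.ndarray:
    idx = np.indices(grid).astype(float)
    d2 = sum(((idx[k] - centre[k]) / radii[k]) ** 2 for k in range(3))
    return d2 <= 1.0


def _bezier(p0, p1, p2, n=80) -> np.ndarray:
    t = np.linspace(0, 1, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def make_anatomy(cfg: SynthConfig, rng: np.random.Generator | None = None) -> Anatomy:
    """Deterministic template anatomy for a given config.

    The cortical shell (outer ~2.5 voxels of the brain sphere) is split
    into 12 angular parcels; tract probability maps are Gaussian
    profiles of the distance to a Bezier centreline anchored on the
    shell and bowing past a subcortical blob; streamlines are the
    centrelines under small constant offsets, which keeps every point
    inside the tract's own p >= 0.3 region.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    grid = cfg.grid
    aff = _affine(grid)
    centre = np.asarray(grid, dtype=float) / 2 - 0.5
    r_brain = min(grid) / 2 - 2.0

    idx = np.indices(grid).astype(float)
    rel = np.stack([idx[k] - centre[k] for k in range(3)])
    radius = np.sqrt((rel ** 2).sum(axis=0))
    brain = radius <= r_brain
    shell = (radius <= r_brain) & (radius >= r_brain - 2.5)

    # 12 cortical parcels: 3 polar bands x 4 azimuthal sectors
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(rel[2] / np.maximum(radius, 1e-9), -1, 1))
        phi = np.arctan2(rel[1], rel[0])
    band = np.minimum((theta / np.pi * 3).astype(int), 2)
    sector = ((phi + np.pi) / (2 * np.pi) * 4).astype(int) % 4
    labels = np.zeros(grid, dtype=np.int32)
    labels[shell] = (band * 4 + sector + 1)[shell]
    cortical_ids = frozenset(range(1, 13))

    # subcortical blobs near the centre
    bg_centre = centre + np.array([-4.0, 0.0, 0.0])
    th_centre = centre + np.array([4.0, 1.0, -1.0])
    bg = _sphere(grid, bg_centre, (3.0, 3.5, 3.0)) & brain
    th = _sphere(grid, th_centre, (2.5, 2.5, 2.5)) & brain
    th &= ~bg
    labels[bg] = 101
    labels[th] = 102
    label_table = {i: f"cortex_{i:02d}" for i in cortical_ids}
    label_table.update({101: "basal_ganglia", 102: "thalamus"})

    # tract centrelines: shell-to-shell Bezier arcs bowing past a blob
    s = r_brain - 1.2
    anchors = {
        "slf_like": (centre + [-s * 0.55, -s * 0.8, 0.2 * s],
                     bg_centre + [-4.5, 0.0, 0.5],
                     centre + [-s * 0.55, s * 0.8, 0.2 * s]),
        "iof_like": (centre + [-0.2 * s, -s * 0.9, -0.3 * s],
                     bg_centre + [0.0, 0.0, -4.5],
                     centre + [-0.2 * s, s * 0.9, -0.3 * s]),
        "sof_like": (centre + [0.3 * s, -s * 0.85, 0.35 * s],
                     th_centre + [0.0, 0.0, 4.0],
                     centre + [0.3 * s, s * 0.85, 0.35 * s]),
        "uf_like": (centre + [s * 0.6, -s * 0.75, -0.25 * s],
                    th_centre + [4.0, -1.0, -0.5],
                    centre + [s * 0.6, s * 0.75, -0.25 * s]),
    }
    vox_coords = np.stack([idx[k] for k in range(3)], axis=-1).reshape(-1, 3)
    tracts: dict[str, Volume3D] = {}
    centrelines: dict[str, np.ndarray] = {}
    from scipy.spatial import cKDTree
    for name in TRACT_NAMES:
        p0, p1, p2 = (np.asarray(a, dtype=float) for a in anchors[name])
        line_vox = _bezier(p0, p1, p2, n=120)
        tree = cKDTree(line_vox)
        dist, _ = tree.query(vox_coords, k=1)
        prob = np.exp(-0.5 * (dist / TRACT_SIGMA_MM) ** 2).reshape(grid)
        prob[~brain] = 0.0
        prob[prob < 0.01] = 0.0
        tracts[name] = Volume3D(data=prob, affine=aff)
        # world mm coordinates of the centreline (voxel indices -> mm)
        homog = np.c_[line_vox, np.ones(len(line_vox))]
        centrelines[name] = (aff @ homog.T).T[:, :3]

    # streamlines: constant small offsets of the centreline
    lines: list[np.ndarray] = []
    tract_labels: list[str] = []
    for name in TRACT_NAMES:
        base = centrelines[name]
        for _ in range(cfg.n_streamlines_per_tract):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = direction * rng.uniform(0, STREAMLINE_JITTER * TRACT_SIGMA_MM)
            lines.append(base + offset)
            tract_labels.append(name)

    parc = Parcellation(labels=labels, affine=aff, label_table=label_table,
                        cortical_ids=cortical_ids)
    return Anatomy(
        parcellation=parc,
        brain_mask=Volume3D(data=brain.astype(np.uint8), affine=aff),
        subcortical_rois={
            "basal_ganglia": Volume3D(data=bg.astype(np.uint8), affine=aff),
            "thalamus": Volume3D(data=th.astype(np.uint8), affine=aff),
        },
        tract_atlas=TractAtlas(tracts=tracts),
        streamlines=StreamlineSet(streamlines=lines, tract_labels=tract_labels),
        tract_centrelines=centrelines,
    )


# latent-signal weights of the synthetic BOLD model
_W_NET = 0.7      # planted seed-to-cortex latent
_W_PARCEL = 0.5   # per-parcel latent
_W_NOISE = 0.7
_PLANTED_PARCEL = 6
_SMOOTH_SIGMA = 0.8


def make_connectome(cfg: SynthConfig, anatomy: Anatomy,
                    rng: np.random.Generator | None = None,
                    network_coupling: float = _W_NET) -> list[Volume4D]:
    """Normative rs-fMRI subjects with a planted subcortico-cortical network.

    Each subject mixes a per-parcel latent signal into its parcel's
    voxels; the two subcortical blobs and one cortical parcel
    additionally share a network latent (strength ``network_coupling``;
    0 gives a null connectome).  Spatial smoothing adds the local
    autocorrelation real BOLD data shows.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    labels = anatomy.parcellation.labels
    brain = anatomy.brain_mask.data > 0
    T = cfg.n_timepoints
    subjects = []
    parcel_ids = sorted(anatomy.parcellation.cortical_ids) + [101, 102]
    for s in range(cfg.n_subjects):
        latents = {pid: rng.standard_normal(T) for pid in parcel_ids}
        net = rng.standard_normal(T)
        data = _W_NOISE * rng.standard_normal((*labels.shape, T))
        for pid in parcel_ids:
            mask = labels == pid
            if not mask.any():
                continue
            sig = _W_PARCEL * latents[pid]
            if pid == _PLANTED_PARCEL or pid in (101, 102):
                sig = sig + network_coupling * net
            data[mask] += sig
        if _SMOOTH_SIGMA > 0:
            data = ndimage.gaussian_filter(data, sigma=(_SMOOTH_SIGMA,) * 3 + (0,))
        data[~brain] = 0.01 * rng.standard_normal((int((~brain).sum()), T))
        subjects.append(Volume4D(data=data, affine=anatomy.parcellation.affine,
                                 subject_id=f"sub{s:03d}"))
    return subjects


def make_lesions(cfg: SynthConfig, anatomy: Anatomy,
                 rng: np.random.Generator | None = None
                 ) -> tuple[list[Volume3D], list[str], np.ndarray]:
    """Subcortically centred ellipsoidal lesions with variable tract encroachment.

    Each patient draws a subcortical group, a target volume (log-uniform
    over ``lesion_size_range``) and an encroachment fraction e in [0,1];
    the lesion centre is shifted from the blob centre toward the nearest
    tract centreline by e of the distance, so e (returned for ground
    truth) modulates how much the lesion invades the adjacent tracts.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    grid = cfg.grid
    aff = anatomy.parcellation.affine
    brain = anatomy.brain_mask.data > 0
    roi_centres = {}
    for name, roi in anatomy.subcortical_rois.items():
        roi_centres[name] = np.array(np.nonzero(roi.data)).mean(axis=1)
    inv = np.linalg.inv(aff)
    centrelines_vox = {
        name: (inv @ np.c_[line, np.ones(len(line))].T).T[:, :3]
        for name, line in anatomy.tract_centrelines.items()
    }
    lo, hi = cfg.lesion_size_range
    lesions, groups, encroachment = [], [], []
    for i in range(cfg.n_patients):
        group = "basal_ganglia" if rng.random() < cfg.bg_fraction else "thalamus"
        roi = anatomy.subcortical_rois[group]
        c_roi = roi_centres[group]
        # nearest tract centreline point to this blob
        best = None
        for line in centrelines_vox.values():
            d = np.linalg.norm(line - c_roi, axis=1)
            j = int(np.argmin(d))
            if best is None or d[j] < best[0]:
                best = (d[j], line[j])
        target_pt = best[1]
        for _attempt in range(200):
            e = rng.random()
            vol_target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            r0 = (3 * vol_target / (4 * np.pi)) ** (1 / 3)
            aniso = rng.uniform(0.7, 1.4, size=3)
            aniso /= np.prod(aniso) ** (1 / 3)  # volume-preserving anisotropy
            radii = r0 * aniso
            centre = c_roi + e * (target_pt - c_roi) + rng.normal(0, 0.8, size=3)
            blob = _sphere(grid, centre, radii) & brain
            n_vox = int(blob.sum())
            if n_vox < lo or n_vox > hi or not (blob & (roi.data > 0)).any():
                continue  # out of size range, escaped the brain, or missed its blob
            lesions.append(Volume3D(data=blob.astype(np.uint8), affine=aff))
            groups.append(group)
            encroachment.append(e)
            break
        else:
            raise RuntimeError("could not place a lesion inside the brain")
    return lesions, groups, np.asarray(encroachment)


def _normal_scores(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blom normal scores; exact ties broken by an infinitesimal jitter."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate all-equal values")
    jitter = rng.normal(0, 1e-9 * max(np.ptp(x), 1e-12), size=x.shape)
    ranks = stats.rankdata(x + jitter, method="ordinal")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def _choose_hits(positions: np.ndarray, target: float) -> np.ndarray:
    """Greedy hit pattern whose normalised mean approximates ``target``.

    Starts from all targets cancelled and repeatedly un-cancels the
    target whose removal moves the mean position closest to the target
    CoC, mimicking the spatially graded omissions of neglect.
    """
    p = positions / np.max(np.abs(positions))
    hits = np.ones(len(p), dtype=bool)
    current = p.mean()
    while hits.sum() > 1 and abs(current - target) > 0.005:
        k = hits.sum()
        cand = np.flatnonzero(hits)
        new_means = (p[hits].sum() - p[cand]) / (k - 1)
        j = cand[np.argmin(np.abs(new_means - target))]
        new = (p[hits].sum() - p[j]) / (k - 1)
        if abs(new - target) >= abs(current - target):
            break
        hits[j] = False
        current = new
    return hits


# fixed symmetric sheet layouts (cm, midline = 0)
LETTER_X = np.repeat(np.array([-12.5, -10.0, -7.5, -5.0, -2.5, 2.5, 5.0, 7.5, 10.0, 12.5]), 6)
BELLS_X = np.repeat(np.array([-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0]), 5)


def make_behaviour(cfg: SynthConfig, total_load: np.ndarray,
                   rng: np.random.Generator | None = None,
                   patient_ids: list[str] | None = None,
                   groups: list[str] | None = None
                   ) -> tuple[list[beh.BehaviouralRecord],
                              list[tuple[str, str, beh.CancellationRecord]],
                              GroundTruth]:
    """Severity and cancellation sheets from total tract lesion load.

    The severity signal is the normal score of total load; observed
    severity mixes it with noise at rho = sin(pi*effect_size/2) (the
    Gaussian-copula inversion of Kendall's tau), is placed on the CoC
    scale and clipped to [-1, 1].  Letters and bells sheets are realised
    so that their computed CoC reproduces the intended value within
    ~0.02; the neglect label applies the configured cutoff per test.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    n = len(total_load)
    if patient_ids is None:
        patient_ids = [f"p{i:03d}" for i in range(n)]
    z = _normal_scores(total_load, rng)
    eps = rng.standard_normal(n) * cfg.noise_sd
    if cfg.noise_sd == 0:
        sev = z.copy()
    else:
        rho = np.sin(np.pi * cfg.effect_size / 2)
        sev = rho * z + np.sqrt(1 - rho ** 2) * eps
    coc_target = np.clip(cfg.coc_scale * np.exp(cfg.coc_shape * sev), -1.0, 1.0)

    records: list[beh.BehaviouralRecord] = []
    sheets: list[tuple[str, str, beh.CancellationRecord]] = []
    for i, pid in enumerate(patient_ids):
        per_test: dict[str, float] = {}
        for test, xs in (("letters", LETTER_X), ("bells", BELLS_X)):
            hits = _choose_hits(xs, coc_target[i])
            sheet = beh.CancellationRecord(test_name=test, target_x=xs, hit_flags=hits)
            sheets.append((pid, test, sheet))
            per_test[test] = beh.compute_coc(sheet)
        rec = beh.BehaviouralRecord(patient_id=pid, coc_per_test=per_test,
                                    group=(groups[i] if groups else ""))
        records.append(rec)
    gt = GroundTruth(true_loads=None, true_severity_signal=z,
                     target_coc=coc_target, planted_network_parcel=_PLANTED_PARCEL,
                     groups=list(groups) if groups else [])
    return records, sheets, gt


@dataclass
class Cohort:
    """A fully generated synthetic study, ready for all three experiments."""

    cfg: SynthConfig
    anatomy: Anatomy
    lesions: list[Volume3D]
    patient_ids: list[str]
    groups: list[str]
    records: list[beh.BehaviouralRecord]
    sheets: list[tuple[str, str, beh.CancellationRecord]]
    ground_truth: GroundTruth
    load_table: "object"

    @property
    def severity(self) -> np.ndarray:
        return np.array([r.mean_coc for r in self.records])

    def neglect_labels(self, cutoff: float | None = None) -> np.ndarray:
        c = self.cfg.neglect_cutoff if cutoff is None else cutoff
        cut = {"letters": c, "bells": c}
        return np.array([r.neglect(cut) for r in self.records], dtype=int)


def make_cohort(cfg: SynthConfig, anatomy: Anatomy | None = None) -> Cohort:
    """Generate lesions, loads and behaviour (no connectome) for a config."""
    from .tract_load import build_load_table

    anatomy = anatomy or make_anatomy(cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    lesions, groups, _enc = make_lesions(cfg, anatomy, rng)
    patient_ids = [f"p{i:03d}" for i in range(cfg.n_patients)]
    table = build_load_table(lesions, anatomy.tract_atlas, patient_ids)
    records, sheets, gt = make_behaviour(
        cfg, table.total.to_numpy(), np.random.default_rng(cfg.seed + 3),
        patient_ids=patient_ids, groups=groups)
    gt.true_loads = table.load
    return Cohort(cfg=cfg, anatomy=anatomy, lesions=lesions,
                  patient_ids=patient_ids, groups=groups, records=records,
                  sheets=sheets, ground_truth=gt, load_table=table)


def make_planted_disconnection(n_patients: int = 50, n_streamlines: int = 300,
                               n_planted: int = 10, shift: float = 2.0,
                               prevalence: tuple[int, int] = (5, 20),
                               rng: np.random.Generator | int | None = 0
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matrix-level cohort for the streamline experiment's power checks.

    Background columns are random binary indicators; ``n_planted``
    columns share one disconnection pattern whose carriers receive a
    severity shift of ``shift`` standard deviations.  Returns
    (matrix, severity, planted column indices).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.zeros((n_patients, n_streamlines), dtype=np.uint8)
    for j in range(n_streamlines):
        k = int(rng.integers(prevalence[0], prevalence[1] + 1))
        X[rng.choice(n_patients, size=k, replace=False), j] = 1
    planted = rng.choice(n_streamlines, size=n_planted, replace=False)
    carriers = rng.choice(n_patients,
                          size=int(rng.integers(prevalence[0], prevalence[1] + 1)),
                          replace=False)
    for j in planted:
        X[:, j] = 0
        X[carriers, j] = 1
    y = rng.standard_normal(n_patients)
    y[carriers] += shift
    return X, y, np.sort(planted)


def write_cohort(cohort: Cohort, outdir: str | Path,
                 connectome: list[Volume4D] | None = None) -> Path:
    """Write a self-contained cohort directory (NIfTI/TRK/CSV/YAML/JSON)."""
    import json

    outdir = Path(outdir)
    (outdir / "lesions").mkdir(parents=True, exist_ok=True)
    (outdir / "tracts").mkdir(exist_ok=True)
    anat = cohort.anatomy
    aff = anat.parcellation.affine
    write_volume(Volume3D(data=anat.parcellation.labels.astype(float), affine=aff),
                 outdir / "parcellation.nii.gz")
    write_volume(anat.brain_mask, outdir / "brain_mask.nii.gz")
    for name, roi in anat.subcortical_rois.items():
        write_volume(roi, outdir / f"roi_{name}.nii.gz")
    tract_manifest = {}
    for name, vol in anat.tract_atlas.tracts.items():
        path = outdir / "tracts" / f"{name}.nii.gz"
        write_volume(vol, path)
        tract_manifest[name] = str(path.relative_to(outdir))
    with open(outdir / "tract_atlas.yaml", "w") as fh:
        yaml.safe_dump(tract_manifest, fh)
    write_streamlines(anat.streamlines, outdir / "streamlines.trk", affine_to_rasmm=aff)
    lesion_manifest = {}
    for pid, lesion in zip(cohort.patient_ids, cohort.lesions):
        path = outdir / "lesions" / f"{pid}.nii.gz"
        write_volume(lesion, path)
        lesion_manifest[pid] = str(path.relative_to(outdir))
    with open(outdir / "lesions.yaml", "w") as fh:
        yaml.safe_dump(lesion_manifest, fh)
    beh.write_behaviour_table(cohort.sheets, outdir / "behaviour.csv",
                              groups=dict(zip(cohort.patient_ids, cohort.groups)))
    if connectome is not None:
        (outdir / "connectome").mkdir(exist_ok=True)
        paths = []
        for subj in connectome:
            p = outdir / "connectome" / f"{subj.subject_id}.nii.gz"
            write_volume4d(subj, p)
            paths.append(str(p.relative_to(outdir)))
        with open(outdir / "connectome.yaml", "w") as fh:
            yaml.safe_dump(paths, fh)
    parcel_meta = {
        "cortical_ids": sorted(anat.parcellation.cortical_ids),
        "label_table": {int(k): v for k, v in anat.parcellation.label_table.items()},
    }
    with open(outdir / "parcellation.yaml", "w") as fh:
        yaml.safe_dump(parcel_meta, fh)
    gt = cohort.ground_truth
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({
            "planted_network_parcel": int(gt.planted_network_parcel),
            "true_severity_signal": [float(v) for v in gt.true_severity_signal],
            "target_coc": [float(v) for v in gt.target_coc],
            "groups": cohort.groups,
            "total_load": [float(v) for v in cohort.load_table.total],
            "seed": cohort.cfg.seed,
        }, fh, indent=2, sort_keys=True)
    return outdir
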