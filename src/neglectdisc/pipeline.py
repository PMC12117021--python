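"""Configuration-driven orchestration of the three experiments.

Experiment 1: lesion-network maps from the normative connectome, then
frequentist max-stat permutation mapping and Bayesian BF mapping of the
association with neglect severity, per patient group.

Experiment 2: streamline disconnection matrix, prevalence filter,
one-tailed permutation GLM, tract assignment of significant
streamlines, per patient group.

Experiment 3: binary and weighted tract lesion-load tables, Kendall tau
associations with Bonferroni correction, the load-presence chi-square,
and the random-forest classification with permutation AUC.

All randomness derives from the single run seed; reports are JSON with
sorted keys and no wall-clock content, so a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behaviour import read_behaviour_table
from .classifier import ClassifierConfig, permutation_test_auc
from .core_io import (Parcellation, StreamlineSet, Volume3D,
                      read_streamlines, read_volume, read_volume4d)
from .lesion_network import lesion_network_map
from .streamline_disconnection import (assign_tracts, build_matrix,
                                       filter_prevalence, streamline_glm)
from .tract_load import (TractAtlas, bonferroni, build_load_table, kendall_tau,
                         presence_chi_square)
from .voxel_stats import bayes_factor_map, max_stat_fwe

logger = logging.getLogger("neglectdisc")

__all__ = ["RunConfig", "StudyInputs", "load_inputs", "run_experiment1",
           "run_experiment2", "run_experiment3", "run_all"]


@dataclass
class RunConfig:
    cohort_dir: str
    output_dir: str
    seed: int = 0
    alpha: float = 0.05
    n_perm_voxel: int = 10000
    n_perm_streamline: int = 10000
    min_streamline_prevalence: int = 5
    tract_threshold: float = 0.3
    neglect_cutoff: float = 0.08
    prior_scale: float = float(np.sqrt(2) / 2)
    n_connectome_subjects: int | None = None   # subsample for desk-scale runs
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    experiments: tuple[str, ...] = ("exp1", "exp2", "exp3")

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if min(self.n_perm_voxel, self.n_perm_streamline) < 1:
            raise ValueError("permutation counts must be >= 1")
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierConfig(**self.classifier)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StudyInputs:
    lesions: list[Volume3D]
    patient_ids: list[str]
    groups: list[str]
    severity: np.ndarray
    neglect: np.ndarray
    parcellation: Parcellation | None = None
    connectome_paths: list[Path] | None = None
    streamlines: StreamlineSet | None = None
    tract_atlas: TractAtlas | None = None
    file_hashes: dict[str, str] = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_inputs(cfg: RunConfig) -> StudyInputs:
    """Read a cohort directory (as written by the synthetic generator)."""
    root = Path(cfg.cohort_dir)
    hashes: dict[str, str] = {}

    with open(root / "lesions.yaml") as fh:
        lesion_manifest = yaml.safe_load(fh)
    patient_ids = sorted(lesion_manifest)
    lesions = []
    for pid in patient_ids:
        p = root / lesion_manifest[pid]
        lesions.append(read_volume(p, expect_binary=True))
        hashes[str(p.relative_to(root))] = _hash_file(p)

    records = {r.patient_id: r for r in read_behaviour_table(root / "behaviour.csv")}
    hashes["behaviour.csv"] = _hash_file(root / "behaviour.csv")
    cut = {"letters": cfg.neglect_cutoff, "bells": cfg.neglect_cutoff}
    severity = np.array([records[pid].mean_coc for pid in patient_ids])
    neglect = np.array([int(records[pid].neglect(cut)) for pid in patient_ids])
    groups = [records[pid].group for pid in patient_ids]

    parc = None
    parc_path = root / "parcellation.nii.gz"
    if parc_path.exists():
        vol = read_volume(parc_path)
        with open(root / "parcellation.yaml") as fh:
            meta = yaml.safe_load(fh)
        parc = Parcellation(labels=np.round(vol.data).astype(np.int32),
                            affine=vol.affine,
                            label_table={int(k): v for k, v in meta["label_table"].items()},
                            cortical_ids=frozenset(meta["cortical_ids"]))
        hashes["parcellation.nii.gz"] = _hash_file(parc_path)

    connectome_paths = None
    if (root / "connectome.yaml").exists():
        with open(root / "connectome.yaml") as fh:
            connectome_paths = [root / p for p in yaml.safe_load(fh)]
        if cfg.n_connectome_subjects:
            connectome_paths = connectome_paths[: cfg.n_connectome_subjects]

    streamlines = None
    if (root / "streamlines.trk").exists():
        streamlines = read_streamlines(root / "streamlines.trk")
        hashes["streamlines.trk"] = _hash_file(root / "streamlines.trk")

    atlas = None
    if (root / "tract_atlas.yaml").exists():
        with open(root / "tract_atlas.yaml") as fh:
            manifest = yaml.safe_load(fh)
        atlas = TractAtlas(tracts={name: read_volume(root / p)
                                   for name, p in sorted(manifest.items())})

    return StudyInputs(lesions=lesions, patient_ids=patient_ids, groups=groups,
                       severity=severity, neglect=neglect, parcellation=parc,
                       connectome_paths=connectome_paths, streamlines=streamlines,
                       tract_atlas=atlas, file_hashes=hashes)


def _group_indices(inputs: StudyInputs) -> dict[str, np.ndarray]:
    out = {"all": np.arange(len(inputs.patient_ids))}
    for g in sorted(set(inputs.groups)):
        if g:
            out[g] = np.flatnonzero(np.asarray(inputs.groups) == g)
    return out


def run_experiment1(cfg: RunConfig, inputs: StudyInputs,
                    connectome=None) -> dict:
    """Lesion-network symptom mapping: frequentist FWE + Bayesian BF maps."""
    if connectome is None:
        if not inputs.connectome_paths:
            raise ValueError("no connectome available")
        connectome = [read_volume4d(p, subject_id=p.stem) for p in inputs.connectome_paths]
    lnms = [
        lesion_network_map(lesion, connectome, inputs.parcellation,
                           mask_cortex=True, patient_id=pid)
        for pid, lesion in zip(inputs.patient_ids, inputs.lesions)
    ]
    report: dict = {"stage": "experiment1", "n_subjects": len(connectome), "groups": {}}
    maps_out: dict = {}
    rng = np.random.default_rng(cfg.seed)
    for gname, idx in _group_indices(inputs).items():
        if gname == "all":
            continue  # per-group design: basal ganglia and thalamus separately
        if len(idx) < 3:
            logger.warning("experiment1: group %s has <3 patients, skipped", gname)
            report["groups"][gname] = {"skipped": "fewer than 3 patients"}
            continue
        gmaps = [lnms[i] for i in idx]
        y = inputs.severity[idx]
        stat = max_stat_fwe(gmaps, y, n_perm=cfg.n_perm_voxel, alpha=cfg.alpha,
                            tails="two", rng=rng)
        bf = bayes_factor_map(gmaps, y, prior_scale=cfg.prior_scale)
        n_tested = int(np.isfinite(stat.tmap.data).sum())
        report["groups"][gname] = {
            "n_patients": int(len(idx)),
            "n_voxels_tested": n_tested,
            "fwe_threshold": round(float(stat.fwe_threshold), 6),
            "n_significant_voxels": int(stat.sig_mask.data.sum()),
            "alpha": cfg.alpha, "n_perm": stat.n_perm, "tails": stat.tails,
            "bf_bin_fractions": {k: round(v, 6) for k, v in bf.bin_fractions.items()},
            "prior_scale": cfg.prior_scale,
        }
        maps_out[gname] = {"stat": stat, "bf": bf, "lnms": gmaps}
    return {"report": report, "maps": maps_out, "lnms": lnms}


def run_experiment2(cfg: RunConfig, inputs: StudyInputs) -> dict:
    """Streamline disconnection: prevalence filter, one-tailed FWE GLM, tracts."""
    if inputs.streamlines is None:
        raise ValueError("no streamlines available")
    matrix = build_matrix(inputs.lesions, inputs.streamlines, inputs.patient_ids)
    report: dict = {"stage": "experiment2", "n_streamlines": len(inputs.streamlines),
                    "groups": {}}
    results: dict = {}
    rng = np.random.default_rng(cfg.seed + 10)
    for gname, idx in _group_indices(inputs).items():
        if gname == "all":
            continue
        sub = filter_prevalence(
            type(matrix)(matrix.matrix[idx], [inputs.patient_ids[i] for i in idx],
                         matrix.streamline_index),
            cfg.min_streamline_prevalence)
        if sub.matrix.shape[1] == 0:
            report["groups"][gname] = {"n_tested": 0, "n_significant": 0,
                                       "note": "no streamline met the prevalence filter"}
            results[gname] = {"significant": np.empty(0, dtype=int), "tract_counts": {}}
            continue
        glm = streamline_glm(sub, inputs.severity[idx],
                             n_perm=cfg.n_perm_streamline, alpha=cfg.alpha, rng=rng)
        counts = assign_tracts(glm["significant"], inputs.streamlines)
        report["groups"][gname] = {
            "n_patients": int(len(idx)),
            "n_disconnected_any": int((matrix.matrix[idx].sum(axis=0) > 0).sum()),
            "n_tested": glm["n_tested"],
            "n_significant": int(len(glm["significant"])),
            "fwe_threshold": round(float(glm["threshold"]), 6) if np.isfinite(glm["threshold"]) else None,
            "n_perm": glm["n_perm"], "alpha": cfg.alpha, "tails": "one",
            "tract_counts": {k: int(v) for k, v in sorted(counts.items())},
        }
        results[gname] = {"significant": glm["significant"], "tract_counts": counts,
                          "t": glm["t"]}
    return {"report": report, "matrix": matrix, "results": results}


def run_experiment3(cfg: RunConfig, inputs: StudyInputs) -> dict:
    """Tract-wise lesion load: tau associations, presence chi-square, classifier."""
    if inputs.tract_atlas is None:
        raise ValueError("no tract atlas available")
    report: dict = {"stage": "experiment3", "groups": {}}
    tables = {
        "binary": build_load_table(inputs.lesions, inputs.tract_atlas,
                                   inputs.patient_ids, weighted=False,
                                   threshold=cfg.tract_threshold),
        "weighted": build_load_table(inputs.lesions, inputs.tract_atlas,
                                     inputs.patient_ids, weighted=True),
    }
    for gname, idx in _group_indices(inputs).items():
        y = inputs.severity[idx]
        neg = inputs.neglect[idx]
        entry: dict = {"n_patients": int(len(idx))}
        for mode, table in tables.items():
            loads = table.load.to_numpy()[idx]
            total = loads.sum(axis=1)
            per_tract = {}
            pvals = []
            for j, name in enumerate(table.load.columns):
                col = loads[:, j]
                if np.ptp(col) == 0 or np.ptp(y) == 0:
                    per_tract[name] = {"tau": None, "p": None}
                    pvals.append(1.0)
                    continue
                tau, p = kendall_tau(col, y)
                per_tract[name] = {"tau": round(tau, 4), "p": round(p, 6)}
                pvals.append(p)
            adj = bonferroni(np.array(pvals))
            for name, a in zip(table.load.columns, adj):
                per_tract[name]["p_bonferroni"] = round(float(a), 6)
            entry[mode] = {"per_tract": per_tract}
            if np.ptp(total) > 0 and np.ptp(y) > 0:
                tau, p = kendall_tau(total, y)
                entry[mode]["total"] = {"tau": round(tau, 4), "p": round(p, 6)}
            else:
                entry[mode]["total"] = {"tau": None, "p": None}
        # presence of any (binary) load vs neglect diagnosis
        present = tables["binary"].load.to_numpy()[idx].sum(axis=1) > 0
        table2 = np.array([
            [np.sum(present & (neg == 1)), np.sum(~present & (neg == 1))],
            [np.sum(present & (neg == 0)), np.sum(~present & (neg == 0))],
        ])
        entry["presence_table"] = table2.astype(int).tolist()
        if np.all(table2.sum(axis=0) > 0) and np.all(table2.sum(axis=1) > 0):
            chi2, dof, p = presence_chi_square(table2)
            entry["presence_chi_square"] = {"chi2": round(chi2, 4), "df": dof,
                                            "p": round(p, 6)}
        else:
            entry["presence_chi_square"] = None
        report["groups"][gname] = entry

    clf_result = None
    if len(np.unique(inputs.neglect)) == 2:
        clf_cfg = ClassifierConfig(**{**asdict(cfg.classifier), "seed": cfg.seed + 20})
        clf_result = permutation_test_auc(tables["binary"].load.to_numpy(),
                                          inputs.neglect, clf_cfg)
        report["classifier"] = {
            "mean_auc": round(clf_result.mean_auc, 4),
            "p_value": round(clf_result.p_value, 6),
            "n_splits": clf_cfg.n_splits, "n_perm": clf_cfg.n_perm,
            "config": asdict(clf_cfg),
        }
    else:
        logger.warning("experiment3: single-class labels, classifier skipped")
        report["classifier"] = {"skipped": "single-class labels"}
    return {"report": report, "tables": tables, "classifier": clf_result}


def _provenance(cfg: RunConfig, inputs: StudyInputs) -> dict:
    c = asdict(cfg)
    c["classifier"] = asdict(cfg.classifier) if not isinstance(cfg.classifier, dict) else cfg.classifier
    return {"config": c, "seed": cfg.seed, "version": __version__,
            "input_hashes": dict(sorted(inputs.file_hashes.items()))}


def run_all(cfg: RunConfig, inputs: StudyInputs | None = None,
            connectome=None) -> dict:
    """Run the configured experiments and write JSON reports.

    Reports carry a config echo, the seed, the package version and input
    file hashes, and are serialised with sorted keys so identical runs
    are byte-identical.
    """
    import pandas as pd

    from .core_io import write_streamlines, write_volume

    inputs = inputs or load_inputs(cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg, inputs)
    reports: dict = {}
    if "exp1" in cfg.experiments:
        res1 = run_experiment1(cfg, inputs, connectome=connectome)
        reports["experiment1"] = res1["report"]
        for gname, maps in res1["maps"].items():
            write_volume(maps["stat"].tmap, outdir / f"exp1_{gname}_tmap.nii.gz")
            write_volume(maps["stat"].sig_mask, outdir / f"exp1_{gname}_sig.nii.gz")
            write_volume(maps["bf"].bfmap, outdir / f"exp1_{gname}_bf.nii.gz")
            write_volume(maps["bf"].bins, outdir / f"exp1_{gname}_bfbins.nii.gz")
    if "exp2" in cfg.experiments:
        res2 = run_experiment2(cfg, inputs)
        reports["experiment2"] = res2["report"]
        matrix = res2["matrix"]
        pd.DataFrame(matrix.matrix, index=matrix.patient_ids,
                     columns=[f"s{j}" for j in matrix.streamline_index]).to_csv(
            outdir / "disconnection_matrix.csv.gz")
        sset = inputs.streamlines
        for gname, res in res2["results"].items():
            idx = np.asarray(res["significant"], dtype=int)
            if len(idx):
                subset = type(sset)(
                    streamlines=[sset.streamlines[i] for i in idx],
                    tract_labels=([sset.tract_labels[i] for i in idx]
                                  if sset.tract_labels else None))
                write_streamlines(subset, outdir / f"exp2_{gname}_significant.trk")
    if "exp3" in cfg.experiments:
        res3 = run_experiment3(cfg, inputs)
        reports["experiment3"] = res3["report"]
        for mode, table in res3["tables"].items():
            table.load.assign(total=table.total).to_csv(outdir / f"lesion_load_{mode}.csv")
    for name, rep in reports.items():
        rep["provenance"] = prov
        with open(outdir / f"{name}.json", "w") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return reports
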