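"""Random-forest prediction of neglect from tract-wise lesion load.

Out-of-sample performance is the mean ROC AUC over repeated stratified
train/test splits (80/20 by default), with a shallow forest (100 trees,
depth <= 3, min 5 samples to split) to limit over-fitting at clinical
sample sizes.  Significance is assessed by a permutation test: the
labels are shuffled and the entire repeated-CV procedure re-run,
yielding a null distribution of mean AUCs and the add-one p-value
p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = ["ClassifierConfig", "ClassifierResult", "repeated_cv_auc", "permutation_test_auc"]

_SEED_MAX = 2**31 - 1


@dataclass
class ClassifierConfig:
    n_trees: int = 100
    max_depth: int = 3
    min_samples_split: int = 5
    n_splits: int = 100
    test_fraction: float = 0.2
    n_perm: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "max_depth", "min_samples_split", "n_splits", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0,1)")


@dataclass
class ClassifierResult:
    mean_auc: float
    per_split_auc: np.ndarray
    perm_aucs: np.ndarray | None = None
    p_value: float | None = None
    config: dict = field(default_factory=dict)


def _cv_mean_auc(features: np.ndarray, labels: np.ndarray, cfg: ClassifierConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-split test AUCs of fresh forests over stratified shuffle splits."""
    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_splits, test_size=cfg.test_fraction,
        random_state=int(rng.integers(_SEED_MAX)),
    )
    aucs = np.empty(cfg.n_splits)
    for i, (train, test) in enumerate(splitter.split(features, labels)):
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_depth=cfg.max_depth,
            min_samples_split=cfg.min_samples_split,
            random_state=int(rng.integers(_SEED_MAX)), n_jobs=1,
        )
        clf.fit(features[train], labels[train])
        scores = clf.predict_proba(features[test])[:, 1]
        aucs[i] = roc_auc_score(labels[test], scores)
    return aucs


def repeated_cv_auc(features: np.ndarray, labels: np.ndarray,
                    cfg: ClassifierConfig | None = None) -> ClassifierResult:
    """Mean test AUC over repeated stratified 80/20 splits.

    Stratification keeps the class ratio in every fold; because both
    classes must be present, labels with a single class are rejected.
    """
    cfg = cfg or ClassifierConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes in labels")
    n_minority = min(np.sum(labels == c) for c in classes)
    if n_minority * cfg.test_fraction < 1:
        raise ValueError("minority class too small for the test fraction")
    rng = np.random.default_rng(cfg.seed)
    aucs = _cv_mean_auc(features, labels, cfg, rng)
    return ClassifierResult(mean_auc=float(aucs.mean()), per_split_auc=aucs,
                            config=asdict(cfg))


def permutation_test_auc(features: np.ndarray, labels: np.ndarray,
                         cfg: ClassifierConfig | None = None) -> ClassifierResult:
    """Permutation test of the mean cross-validated AUC.

    Each permutation shuffles the labels and repeats the identical
    repeated-CV procedure (stratified on the shuffled labels, which
    preserves the class counts); fresh forests are grown every time.
    """
    cfg = cfg or ClassifierConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(cfg.seed)
    observed = _cv_mean_auc(features, labels, cfg, rng)
    mean_obs = float(observed.mean())
    perm_means = np.empty(cfg.n_perm)
    for b in range(cfg.n_perm):
        shuffled = rng.permutation(labels)
        perm_means[b] = _cv_mean_auc(features, shuffled, cfg, rng).mean()
    p = (1 + np.sum(perm_means >= mean_obs)) / (1 + cfg.n_perm)
    return ClassifierResult(mean_auc=mean_obs, per_split_auc=observed,
                            perm_aucs=perm_means, p_value=float(p),
                            config=asdict(cfg))
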