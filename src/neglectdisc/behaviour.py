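"""Centre-of-Cancellation (CoC) scoring of cancellation tests.

In a cancellation test the patient crosses out targets scattered over a
sheet whose centre is aligned with their sagittal midline.  The CoC is
the mean horizontal position of the successfully cancelled targets,
normalised so the extreme targets map to +/-1: a patient who only finds
targets on the right of the sheet (left neglect) scores towards +1, a
symmetric performance scores 0.

Two tests are supported by name: ``letters`` (60 targets) and ``bells``
(35 targets).  Severity is the mean CoC over available tests; the binary
neglect label is positive when the CoC of at least one test strictly
exceeds its empirically established cutoff.  Cutoffs are configuration,
never constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CancellationRecord",
    "BehaviouralRecord",
    "compute_coc",
    "mean_coc",
    "classify_neglect",
    "read_behaviour_table",
    "write_behaviour_table",
]

VALID_TESTS = ("letters", "bells")


class UndefinedScoreError(ValueError):
    """Raised when a CoC is undefined (no target was cancelled)."""


@dataclass
class CancellationRecord:
    """One administered cancellation sheet.

    target_x: horizontal target positions in cm, sheet midline = 0.
    hit_flags: per-target indicator that the target was cancelled.
    """

    test_name: str
    target_x: np.ndarray
    hit_flags: np.ndarray

    def __post_init__(self) -> None:
        self.target_x = np.asarray(self.target_x, dtype=float)
        self.hit_flags = np.asarray(self.hit_flags, dtype=bool)
        if self.target_x.size == 0:
            raise ValueError("no targets")
        if self.hit_flags.shape != self.target_x.shape:
            raise ValueError("hit_flags must match target_x in length")
        if not (np.any(self.target_x < 0) and np.any(self.target_x > 0)):
            raise ValueError("targets must flank the midline on both sides")


@dataclass
class BehaviouralRecord:
    patient_id: str
    coc_per_test: dict[str, float] = field(default_factory=dict)
    group: str = ""

    @property
    def mean_coc(self) -> float:
        return mean_coc(self.coc_per_test)

    def neglect(self, cutoffs: dict[str, float]) -> bool:
        return classify_neglect(self.coc_per_test, cutoffs)


def compute_coc(rec: CancellationRecord) -> float:
    """Mean normalised horizontal position of the cancelled targets.

    Positions are normalised by the largest absolute target position on
    the sheet, so the extreme targets score exactly +/-1 and the score is
    invariant to uniform rescaling of the coordinates.
    """
    if not np.any(rec.hit_flags):
        raise UndefinedScoreError("no target cancelled; CoC undefined")
    denom = np.max(np.abs(rec.target_x))
    return float(np.mean(rec.target_x[rec.hit_flags]) / denom)


def mean_coc(scores: dict[str, float]) -> float:
    """Arithmetic mean of the available per-test CoC scores."""
    vals = [v for v in scores.values() if v is not None and np.isfinite(v)]
    if not vals:
        raise ValueError("no CoC score available")
    return float(np.mean(vals))


def classify_neglect(scores: dict[str, float], cutoffs: dict[str, float]) -> bool:
    """Neglect iff CoC in at least one available test strictly exceeds its cutoff."""
    present = {k: v for k, v in scores.items() if v is not None and np.isfinite(v)}
    if not present:
        raise ValueError("no CoC score available")
    missing = set(present) - set(cutoffs)
    if missing:
        raise KeyError(f"no cutoff supplied for test(s): {sorted(missing)}")
    return any(v > cutoffs[k] for k, v in present.items())


def read_behaviour_table(path: str | Path) -> list[BehaviouralRecord]:
    """Read the behavioural CSV: one row per patient-test.

    Rows carry either raw sheet data (``target_x`` and ``hit_flags`` as
    semicolon-joined values) or a precomputed ``coc`` column.  A ``group``
    column, when present, labels the lesion site (basal_ganglia/thalamus).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    records: dict[str, BehaviouralRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        rec = records.setdefault(
            pid, BehaviouralRecord(patient_id=pid, group=str(row.get("group", "") or ""))
        )
        test = str(row["test_name"])
        if "coc" in df.columns and pd.notna(row.get("coc")):
            score = float(row["coc"])
        else:
            xs = np.array([float(v) for v in str(row["target_x"]).split(";")])
            hits = np.array([int(v) for v in str(row["hit_flags"]).split(";")])
            score = compute_coc(CancellationRecord(test, xs, hits))
        rec.coc_per_test[test] = score
    return list(records.values())


def write_behaviour_table(records: list[tuple[str, str, CancellationRecord]],
                          path: str | Path,
                          groups: dict[str, str] | None = None) -> None:
    """Write raw cancellation sheets to the behavioural CSV format."""
    rows = []
    for pid, test, rec in records:
        rows.append({
            "patient_id": pid,
            "test_name": test,
            "group": (groups or {}).get(pid, ""),
            "target_x": ";".join(f"{v:.4f}" for v in rec.target_x),
            "hit_flags": ";".join(str(int(v)) for v in rec.hit_flags),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
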