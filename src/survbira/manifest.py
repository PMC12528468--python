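"""Cohort data model, manifest I/O, and patient-grouped fold construction.

A cohort is described by a flat manifest table with one row per slide:

    patient_id, slide_id, image_path, tissue_type, stage, survival_days, cohort

All patients are uncensored (their death time is observed), so
``survival_days`` is an ordinary positive regression target.  Stage is a
patient-level attribute that slides inherit.  Folds for cross-validation
are always patient-grouped: every slide of a patient lands in that
patient's fold, so no patient contributes to both train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed tissue-type labels for a slide.  Only primary tumor is expected
#: to carry survival signal; lymph node and normal/non-neoplastic slides are
#: kept so that "primary type only" versus "whole type" comparisons can be run.
TISSUE_TYPES = ("primary_tumor", "lymph_node", "normal_nonneoplastic")

VALID_STAGES = frozenset({1, 2, 3, 4})

REQUIRED_COLUMNS = (
    "patient_id", "slide_id", "image_path", "tissue_type",
    "stage", "survival_days", "cohort",
)


class ManifestError(ValueError):
    """Schema or validation failure while reading a cohort manifest."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identity, observed survival, stage, and slide count."""

    patient_id: str
    survival_days: int
    stage: int
    cohort: str = ""
    n_slides: int = 1

    def __post_init__(self) -> None:
        if self.survival_days <= 0:
            raise ManifestError(
                f"patient {self.patient_id!r}: survival_days must be positive, "
                f"got {self.survival_days}"
            )
        if self.stage not in VALID_STAGES:
            raise ManifestError(
                f"patient {self.patient_id!r}: stage must be in {sorted(VALID_STAGES)}, "
                f"got {self.stage}"
            )
        if self.n_slides < 1:
            raise ManifestError(
                f"patient {self.patient_id!r}: n_slides must be >= 1, got {self.n_slides}"
            )


@dataclass(frozen=True)
class SlideRecord:
    """One pathology image with its patient link and tissue type."""

    slide_id: str
    patient_id: str
    image_path: str
    tissue_type: str
    magnification: float = 20.0

    def __post_init__(self) -> None:
        if self.tissue_type not in TISSUE_TYPES:
            raise ManifestError(
                f"slide {self.slide_id!r}: tissue_type {self.tissue_type!r} "
                f"not in allowed values {TISSUE_TYPES}"
            )


@dataclass(frozen=True)
class FoldSplit:
    """A patient-level partition into ``k`` disjoint test folds."""

    k: int
    assignments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {p: f for p, f in self.assignments.items() if not 0 <= f < self.k}
        if bad:
            raise ValueError(f"fold indices outside [0, {self.k}): {bad}")

    def fold_patients(self, fold: int) -> list[str]:
        """Patient ids assigned to test fold ``fold``."""
        return [p for p, f in self.assignments.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignments), "fold": list(self.assignments.values())}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoldSplit":
        df = pd.read_csv(path, dtype={"patient_id": str, "fold": int})
        assignments = dict(zip(df["patient_id"], df["fold"]))
        return cls(k=int(df["fold"].max()) + 1, assignments=assignments)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype={"patient_id": str, "slide_id": str})


def load_manifest(path: str | Path) -> tuple[list[PatientRecord], list[SlideRecord]]:
    """Read a cohort manifest (CSV or TSV by extension).

    Returns one :class:`PatientRecord` per distinct patient (with
    ``n_slides`` set to its slide count) and one :class:`SlideRecord` per
    row, in file order.

    Raises
    ------
    ManifestError
        If a required column is missing, a survival time is non-positive,
        a tissue type is not one of the allowed labels, or a patient's
        rows disagree on survival_days / stage / cohort.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path}: missing required column(s) {missing}")

    slides: list[SlideRecord] = []
    for idx, row in df.iterrows():
        if int(row["survival_days"]) <= 0:
            raise ManifestError(
                f"manifest row {idx}: survival_days must be positive, "
                f"got {row['survival_days']} (patient {row['patient_id']!r})"
            )
        slides.append(
            SlideRecord(
                slide_id=str(row["slide_id"]),
                patient_id=str(row["patient_id"]),
                image_path=str(row["image_path"]),
                tissue_type=str(row["tissue_type"]),
            )
        )

    dup = df["slide_id"].astype(str).duplicated()
    if dup.any():
        raise ManifestError(f"manifest {path}: duplicate slide_id(s) {sorted(df['slide_id'][dup])}")

    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        for col in ("survival_days", "stage", "cohort"):
            if grp[col].nunique(dropna=False) != 1:
                raise ManifestError(
                    f"patient {pid!r}: conflicting values of {col!r}: "
                    f"{sorted(grp[col].unique().tolist())}"
                )
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                survival_days=int(grp["survival_days"].iloc[0]),
                stage=int(grp["stage"].iloc[0]),
                cohort=str(grp["cohort"].iloc[0]),
                n_slides=len(grp),
            )
        )
    return patients, slides


def filter_by_tissue_type(
    slides: list[SlideRecord], keep: set[str]
) -> list[SlideRecord]:
    """Keep slides whose ``tissue_type`` is in ``keep``; order preserved.

    An empty result is allowed (a cohort may have no slides of the
    requested types); an empty or invalid ``keep`` set is an error.
    """
    if not keep:
        raise ValueError("keep must be a non-empty set of tissue types")
    bad = set(keep) - set(TISSUE_TYPES)
    if bad:
        raise ValueError(f"unknown tissue type(s) {sorted(bad)}; allowed: {TISSUE_TYPES}")
    return [s for s in slides if s.tissue_type in keep]


def filter_by_stage(
    patients: list[PatientRecord], stages: set[int]
) -> list[PatientRecord]:
    """Keep patients whose stage is in ``stages`` (subset of {1,2,3,4})."""
    if not stages:
        raise ValueError("stages must be non-empty")
    bad = set(stages) - VALID_STAGES
    if bad:
        raise ValueError(f"invalid stage(s) {sorted(bad)}; allowed: {sorted(VALID_STAGES)}")
    return [p for p in patients if p.stage in stages]


def make_patient_folds(
    patients: list[PatientRecord], k: int, seed: int
) -> FoldSplit:
    """Randomly partition patients into ``k`` balanced test folds.

    Patient ids are shuffled with ``seed`` and dealt round-robin, so fold
    sizes differ by at most one and every patient appears in exactly one
    fold.  Deterministic given the same patients, ``k`` and ``seed``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[j]: i % k for i, j in enumerate(order)}
    return FoldSplit(k=k, assignments=assignments)
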