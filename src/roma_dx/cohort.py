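"""Typed data model for a pelvic-mass study cohort, with CSV I/O and validation.

A cohort is an ordered collection of :class:`PatientRecord`: one subject per
record, carrying demographics (age, menopausal status), the two serum tumour
markers (CA125 in U/ml, HE4 in pM), the surgical-pathology outcome
(benign/malignant with histology group, FIGO stage and grade), and optional
pre-analytic / history flags. Every downstream stage — ROMA scoring, ROC
analysis, group statistics — consumes this model.

The on-disk format is a plain UTF-8 comma-separated file with a mandatory
header (see :data:`CSV_COLUMNS`). Markers, age, menopausal status and
diagnosis are mandatory; the boolean covariates may be missing (``NA``).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

__all__ = [
    "MenopausalStatus",
    "DiagnosisClass",
    "HistologyGroup",
    "FigoStage",
    "Grade",
    "PathologyLabel",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "CohortSchemaError",
    "CSV_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "stratify",
]

SCHEMA_VERSION = "1"


class CohortSchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


class CohortValidationError(ValueError):
    """One or more records violate the cohort invariants."""


class MenopausalStatus(str, Enum):
    PRE = "pre"
    POST = "post"


class DiagnosisClass(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class HistologyGroup(str, Enum):
    CYSTADENOMA_FIBROMA = "cystadenoma_fibroma"
    ENDOMETRIOSIS = "endometriosis"
    MATURE_TERATOMA = "mature_teratoma"
    FIBROMA_THECOMA = "fibroma_thecoma"
    FUNCTIONAL_CYST = "functional_cyst"
    OTHER_BENIGN = "other_benign"
    EOC = "eoc"
    NEOC = "neoc"
    METASTATIC = "metastatic"


BENIGN_GROUPS = frozenset(
    {
        HistologyGroup.CYSTADENOMA_FIBROMA,
        HistologyGroup.ENDOMETRIOSIS,
        HistologyGroup.MATURE_TERATOMA,
        HistologyGroup.FIBROMA_THECOMA,
        HistologyGroup.FUNCTIONAL_CYST,
        HistologyGroup.OTHER_BENIGN,
    }
)
MALIGNANT_GROUPS = frozenset(
    {HistologyGroup.EOC, HistologyGroup.NEOC, HistologyGroup.METASTATIC}
)


class FigoStage(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    NOT_APPLICABLE = "NA"


class Grade(str, Enum):
    BORDERLINE = "borderline"
    G1 = "g1"
    G2 = "g2"
    G3 = "g3"
    NOT_APPLICABLE = "NA"


@dataclass(frozen=True)
class PathologyLabel:
    """Surgical-pathology outcome for one subject.

    FIGO stage and differentiation grade apply to epithelial ovarian cancer
    only; for every other histology group both must be ``NA``.
    """

    histology_group: HistologyGroup
    figo_stage: FigoStage = FigoStage.NOT_APPLICABLE
    grade: Grade = Grade.NOT_APPLICABLE
    subtype_tag: str = ""

    def __post_init__(self) -> None:
        if self.histology_group is not HistologyGroup.EOC:
            if self.figo_stage is not FigoStage.NOT_APPLICABLE:
                raise CohortValidationError(
                    f"figo_stage={self.figo_stage.value!r} is only valid for EOC, "
                    f"not {self.histology_group.value!r}"
                )
            if self.grade is not Grade.NOT_APPLICABLE:
                raise CohortValidationError(
                    f"grade={self.grade.value!r} is only valid for EOC, "
                    f"not {self.histology_group.value!r}"
                )


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, serum markers, pathology, optional flags.

    CA125 and HE4 must be strictly positive (the ROMA predictive index takes
    their natural logarithms). Boolean covariates may be ``None`` (missing)
    and are excluded pairwise from the relevant composition tests.
    """

    id: str
    age: float
    menopausal_status: MenopausalStatus
    ca125: float
    he4: float
    diagnosis: DiagnosisClass
    pathology: PathologyLabel
    haemolysis: bool | None = None
    freeze_delay_gt_4h: bool | None = None
    family_history_breast: bool | None = None
    family_history_ovarian: bool | None = None
    smoking: bool | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise CohortValidationError(f"record {self.id!r}: age must be finite and > 0")
        for name in ("ca125", "he4"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise CohortValidationError(
                    f"record {self.id!r}: {name} must be finite and > 0, got {v!r}"
                )
        benign = self.diagnosis is DiagnosisClass.BENIGN
        group = self.pathology.histology_group
        if benign and group not in BENIGN_GROUPS:
            raise CohortValidationError(
                f"record {self.id!r}: benign diagnosis with malignant histology "
                f"group {group.value!r}"
            )
        if not benign and group not in MALIGNANT_GROUPS:
            raise CohortValidationError(
                f"record {self.id!r}: malignant diagnosis with benign histology "
                f"group {group.value!r}"
            )


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise CohortValidationError(f"duplicate record id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> PatientRecord:
        return self.records[idx]

    def counts_by_diagnosis(self) -> dict[DiagnosisClass, int]:
        counts = {DiagnosisClass.BENIGN: 0, DiagnosisClass.MALIGNANT: 0}
        for r in self.records:
            counts[r.diagnosis] += 1
        return counts

    def filter(self, predicate) -> "Cohort":
        """New cohort containing the records for which ``predicate`` is true."""
        return Cohort([r for r in self.records if predicate(r)])

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with one row per record, columns as in the CSV schema."""
        rows = [_record_to_row(r) for r in self.records]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


# --------------------------------------------------------------------------
# CSV schema


CSV_COLUMNS = [
    "id",
    "age",
    "menopausal_status",
    "ca125_u_ml",
    "he4_pm",
    "diagnosis",
    "histology_group",
    "figo_stage",
    "grade",
    "subtype_tag",
    "haemolysis",
    "freeze_delay_gt_4h",
    "fh_breast",
    "fh_ovarian",
    "smoking",
]

_FLAG_FIELDS = {
    "haemolysis": "haemolysis",
    "freeze_delay_gt_4h": "freeze_delay_gt_4h",
    "fh_breast": "family_history_breast",
    "fh_ovarian": "family_history_ovarian",
    "smoking": "smoking",
}


def _format_float(x: float) -> str:
    # repr round-trips exactly under IEEE-754 double precision
    return repr(float(x))


def _format_flag(v: bool | None) -> str:
    if v is None:
        return "NA"
    return "1" if v else "0"


def _parse_flag(s: str, row: int, col: str) -> bool | None:
    if s in ("NA", ""):
        return None
    if s == "1":
        return True
    if s == "0":
        return False
    raise CohortValidationError(f"row {row}: column {col!r} must be 0, 1 or NA, got {s!r}")


def _record_to_row(r: PatientRecord) -> dict[str, str]:
    return {
        "id": r.id,
        "age": _format_float(r.age),
        "menopausal_status": r.menopausal_status.value,
        "ca125_u_ml": _format_float(r.ca125),
        "he4_pm": _format_float(r.he4),
        "diagnosis": r.diagnosis.value,
        "histology_group": r.pathology.histology_group.value,
        "figo_stage": r.pathology.figo_stage.value,
        "grade": r.pathology.grade.value,
        "subtype_tag": r.pathology.subtype_tag,
        "haemolysis": _format_flag(r.haemolysis),
        "freeze_delay_gt_4h": _format_flag(r.freeze_delay_gt_4h),
        "fh_breast": _format_flag(r.family_history_breast),
        "fh_ovarian": _format_flag(r.family_history_ovarian),
        "smoking": _format_flag(r.smoking),
    }


def _row_to_record(row: dict[str, str], rownum: int) -> PatientRecord:
    def _enum(cls, value: str, col: str):
        try:
            return cls(value)
        except ValueError:
            allowed = ", ".join(m.value for m in cls)
            raise CohortValidationError(
                f"row {rownum}: column {col!r} must be one of {{{allowed}}}, got {value!r}"
            ) from None

    def _float(value: str, col: str) -> float:
        try:
            return float(value)
        except ValueError:
            raise CohortValidationError(
                f"row {rownum}: column {col!r} must be numeric, got {value!r}"
            ) from None

    pathology = PathologyLabel(
        histology_group=_enum(HistologyGroup, row["histology_group"], "histology_group"),
        figo_stage=_enum(FigoStage, row["figo_stage"], "figo_stage"),
        grade=_enum(Grade, row["grade"], "grade"),
        subtype_tag=row["subtype_tag"],
    )
    try:
        return PatientRecord(
            id=row["id"],
            age=_float(row["age"], "age"),
            menopausal_status=_enum(
                MenopausalStatus, row["menopausal_status"], "menopausal_status"
            ),
            ca125=_float(row["ca125_u_ml"], "ca125_u_ml"),
            he4=_float(row["he4_pm"], "he4_pm"),
            diagnosis=_enum(DiagnosisClass, row["diagnosis"], "diagnosis"),
            pathology=pathology,
            haemolysis=_parse_flag(row["haemolysis"], rownum, "haemolysis"),
            freeze_delay_gt_4h=_parse_flag(
                row["freeze_delay_gt_4h"], rownum, "freeze_delay_gt_4h"
            ),
            family_history_breast=_parse_flag(row["fh_breast"], rownum, "fh_breast"),
            family_history_ovarian=_parse_flag(row["fh_ovarian"], rownum, "fh_ovarian"),
            smoking=_parse_flag(row["smoking"], rownum, "smoking"),
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {rownum}: {exc}") from None


def read_cohort_csv(path: str | Path, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Read and validate a cohort CSV; row order is preserved.

    Raises :class:`CohortSchemaError` if the header does not match
    :data:`CSV_COLUMNS`, and :class:`CohortValidationError` (citing the
    offending data row, 1-based) for malformed values.
    """
    if schema_version != SCHEMA_VERSION:
        raise CohortSchemaError(f"unsupported schema version {schema_version!r}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    records = [
        _row_to_record(row, i + 1)
        for i, row in enumerate(frame[CSV_COLUMNS].to_dict("records"))
    ]
    return Cohort(records)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV with deterministic column order and formatting.

    The output is losslessly re-readable: floats are rendered with ``repr``
    (shortest exact decimal), flags as ``0``/``1``/``NA``.
    """
    path = Path(path)
    frame = cohort.to_dataframe()
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


# --------------------------------------------------------------------------
# Stratification


_STRATIFY_KEYS = {
    "menopausal_status": lambda r: r.menopausal_status.value,
    "diagnosis": lambda r: r.diagnosis.value,
    "histology_group": lambda r: r.pathology.histology_group.value,
    "figo_stage": lambda r: r.pathology.figo_stage.value,
    "grade": lambda r: r.pathology.grade.value,
}


def stratify(cohort: Cohort, key: str) -> dict[str, Cohort]:
    """Partition a cohort by a categorical key.

    The sub-cohorts are disjoint and their union (in order) is the input;
    strata appear in order of first occurrence.
    """
    try:
        getter = _STRATIFY_KEYS[key]
    except KeyError:
        raise ValueError(
            f"unknown stratification key {key!r}; valid: {sorted(_STRATIFY_KEYS)}"
        ) from None
    buckets: dict[str, list[PatientRecord]] = {}
    for r in cohort:
        buckets.setdefault(getter(r), []).append(r)
    return {k: Cohort(v) for k, v in buckets.items()}


def concat(cohorts: Iterable[Cohort]) -> Cohort:
    """Concatenate cohorts (ids must remain unique)."""
    records: list[PatientRecord] = []
    for c in cohorts:
        records.extend(c.records)
    return Cohort(records)
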