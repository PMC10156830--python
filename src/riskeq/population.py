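"""Core data model for risk-equalization (RE) populations.

An RE model is a weighted individual-level regression of annual health
spending on a set of categorical *risk adjusters* (age interacted with
gender, pharmacy-based cost groups, diagnosis-based cost groups, ...).
This module defines the person-level record, the risk-adjuster scheme,
the numeric design matrix fed to the calibration stage, and delimited /
JSON readers and writers for both.

Conventions
-----------
* Spending is stored **annualized** (euros per person-year); the fraction
  of the year a person was enrolled is the regression weight.  The
  explicit :func:`annualize` step makes the conservation identity
  ``weight * annualized == raw`` testable.
* Dummy coding has no global intercept: the exhaustive age-gender block
  plays the intercept's role, and every other classification omits its
  reference class (``"none"`` for morbidity adjusters).
* Persons aged 0 are rejected at validation (the spending year cannot be
  linked to prior-year morbidity for newborns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ValidationError",
    "Classification",
    "RiskAdjusterScheme",
    "PersonRecord",
    "DesignMatrix",
    "annualize",
    "validate_records",
    "build_design",
    "dxgroup_indicator_matrix",
    "read_population",
    "write_population",
    "read_scheme",
    "write_scheme",
]

AGE_GENDER = "age_gender"
NONE_CLASS = "none"

_EMPTY: frozenset[str] = frozenset()


class ValidationError(ValueError):
    """Raised when a record, table or scheme violates an invariant."""


# ---------------------------------------------------------------------------
# Scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Classification:
    """One named risk-adjuster classification.

    Parameters
    ----------
    name:
        Classification identifier, e.g. ``"age_gender"`` or ``"pcg"``.
    labels:
        Class labels in design-matrix column order.  For exclusive
        morbidity classifications the reference label is *not* listed
        here; it is carried separately so it can be omitted from the
        design matrix.
    exclusive:
        Whether a person belongs to exactly one class (True for all
        classifications except count-valued DCG blocks, which are added
        to the design matrix separately).
    reference:
        The omitted reference label, or ``None`` for the exhaustive
        age-gender block, which keeps all its columns.
    """

    name: str
    labels: tuple[str, ...]
    exclusive: bool = True
    reference: str | None = NONE_CLASS

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(
                f"classification {self.name!r} has duplicate labels"
            )
        if self.reference is not None and self.reference in self.labels:
            raise ValidationError(
                f"classification {self.name!r}: reference class "
                f"{self.reference!r} must not be listed among labels"
            )


@dataclass(frozen=True)
class RiskAdjusterScheme:
    """Ordered set of classifications plus the registered dxgroup catalogue.

    The age-gender classification must be present, exhaustive and
    reference-free: its columns sum to one in every design-matrix row.
    """

    classifications: tuple[Classification, ...]
    dxgroup_catalogue: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [c.name for c in self.classifications]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate classification names in scheme")
        if AGE_GENDER not in names:
            raise ValidationError(f"scheme must contain an {AGE_GENDER!r} classification")
        if self.age_gender.reference is not None:
            raise ValidationError("age_gender block must not have a reference class")
        if len(set(self.dxgroup_catalogue)) != len(self.dxgroup_catalogue):
            raise ValidationError("duplicate dxgroup ids in catalogue")

    @property
    def age_gender(self) -> Classification:
        return next(c for c in self.classifications if c.name == AGE_GENDER)

    @property
    def morbidity(self) -> tuple[Classification, ...]:
        return tuple(c for c in self.classifications if c.name != AGE_GENDER)

    def classification(self, name: str) -> Classification:
        for c in self.classifications:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "RiskAdjusterScheme":
        """Scheme restricted to the given classifications (order kept)."""
        keep = [c for c in self.classifications if c.name in set(names)]
        return RiskAdjusterScheme(tuple(keep), self.dxgroup_catalogue)


# ---------------------------------------------------------------------------
# Person records
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class PersonRecord:
    """One insured individual.

    ``spending_annualized`` is euros per person-year; ``insured_fraction``
    is both the enrolled fraction of the year and the weight used in every
    regression and aggregation.  ``adjuster_flags`` maps each morbidity
    classification name to the person's class label (``"none"`` for the
    reference class).  ``dxgroups`` is the set of hospital diagnosis
    groups the person qualifies for, and ``conditions`` the optional set
    of GP-recorded chronic conditions (ICPC-style).
    """

    person_id: str
    insured_fraction: float
    spending_annualized: float
    age_band: str
    gender: str
    adjuster_flags: Mapping[str, str] = field(default_factory=dict)
    dxgroups: frozenset[str] = _EMPTY
    conditions: frozenset[str] = _EMPTY

    @property
    def age_gender_label(self) -> str:
        return f"{self.gender}|{self.age_band}"


def annualize(raw_spending: float, insured_fraction: float) -> tuple[float, float]:
    """Convert raw in-year spending to (euros per person-year, weight).

    A person enrolled for a fraction ``f`` of the year with raw spending
    ``s`` contributes annualized spending ``s / f`` with weight ``f``, so
    that ``weight * annualized == raw`` and population totals are
    conserved.
    """
    if not (0.0 < insured_fraction <= 1.0):
        raise ValidationError(
            f"insured_fraction must lie in (0, 1], got {insured_fraction}"
        )
    if raw_spending < 0:
        raise ValidationError(f"raw spending must be >= 0, got {raw_spending}")
    return raw_spending / insured_fraction, insured_fraction


def _validate_record(rec: PersonRecord, scheme: RiskAdjusterScheme,
                     catalogue: frozenset[str]) -> None:
    if not (0.0 < rec.insured_fraction <= 1.0):
        raise ValidationError(
            f"person {rec.person_id}: insured_fraction {rec.insured_fraction} "
            "outside (0, 1]"
        )
    if rec.spending_annualized < 0 or not np.isfinite(rec.spending_annualized):
        raise ValidationError(
            f"person {rec.person_id}: invalid spending {rec.spending_annualized}"
        )
    if rec.age_band.strip() in ("0", "0-0"):
        raise ValidationError(
            f"person {rec.person_id}: persons aged 0 are excluded from the model"
        )
    if rec.age_gender_label not in scheme.age_gender.labels:
        raise ValidationError(
            f"person {rec.person_id}: unknown age/gender class "
            f"{rec.age_gender_label!r}"
        )
    for cls in scheme.morbidity:
        label = rec.adjuster_flags.get(cls.name)
        if label is None:
            raise ValidationError(
                f"person {rec.person_id}: missing class for exclusive "
                f"classification {cls.name!r}"
            )
        if label != cls.reference and label not in cls.labels:
            raise ValidationError(
                f"person {rec.person_id}: unknown class label {label!r} for "
                f"classification {cls.name!r}"
            )
    unknown = set(rec.dxgroups) - catalogue
    if unknown:
        raise ValidationError(
            f"person {rec.person_id}: unregistered dxgroup id(s) "
            f"{sorted(unknown)}"
        )


def validate_records(records: Iterable[PersonRecord],
                     scheme: RiskAdjusterScheme) -> None:
    """Check every record against the scheme; raise on the first violation."""
    catalogue = frozenset(scheme.dxgroup_catalogue)
    for rec in records:
        _validate_record(rec, scheme, catalogue)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignMatrix:
    """Person-by-risk-class numeric matrix with aligned outcome and weight.

    Entries are 0/1 for exclusive classes and non-negative counts for
    multi-qualification DCG columns.  Column order is deterministic given
    the scheme: the age-gender block first, then each morbidity
    classification's non-reference labels in scheme order, then any extra
    (DCG or dxgroup) columns in the order supplied.
    """

    columns: tuple[str, ...]
    matrix: sparse.csr_matrix
    person_ids: tuple[str, ...]
    y: np.ndarray
    w: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column_index(self, label: str) -> int:
        return self.columns.index(label)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def _column_label(cls_name: str, label: str) -> str:
    return f"{cls_name}:{label}"


def build_design(
    records: Sequence[PersonRecord],
    scheme: RiskAdjusterScheme,
    extra: tuple[Sequence[str], sparse.spmatrix | np.ndarray] | None = None,
    validate: bool = True,
) -> DesignMatrix:
    """Build the regression design matrix for a validated population.

    ``extra`` optionally appends pre-computed columns (DCG dummies or
    counts, or per-dxgroup indicators) as ``(labels, matrix)`` with one
    row per record.
    """
    if validate:
        validate_records(records, scheme)
    n = len(records)

    columns: list[str] = []
    ag = scheme.age_gender
    ag_index = {lab: j for j, lab in enumerate(ag.labels)}
    columns.extend(_column_label(AGE_GENDER, lab) for lab in ag.labels)
    block_index: dict[str, dict[str, int]] = {}
    for cls in scheme.morbidity:
        block_index[cls.name] = {
            lab: len(columns) + j for j, lab in enumerate(cls.labels)
        }
        columns.extend(_column_label(cls.name, lab) for lab in cls.labels)

    rows: list[int] = []
    cols: list[int] = []
    for i, rec in enumerate(records):
        rows.append(i)
        cols.append(ag_index[rec.age_gender_label])
        for cls in scheme.morbidity:
            label = rec.adjuster_flags[cls.name]
            if label != cls.reference:
                rows.append(i)
                cols.append(block_index[cls.name][label])
    data = np.ones(len(rows))
    X = sparse.csr_matrix(
        (data, (rows, cols)), shape=(n, len(columns)), dtype=float
    )

    if extra is not None:
        extra_labels, extra_matrix = extra
        extra_matrix = sparse.csr_matrix(extra_matrix, dtype=float)
        if extra_matrix.shape != (n, len(extra_labels)):
            raise ValidationError(
                f"extra columns shape {extra_matrix.shape} does not match "
                f"({n}, {len(extra_labels)})"
            )
        if extra_matrix.nnz and extra_matrix.data.min() < 0:
            raise ValidationError("extra design columns must be non-negative")
        X = sparse.hstack([X, extra_matrix], format="csr")
        columns = columns + [str(lab) for lab in extra_labels]

    y = np.array([rec.spending_annualized for rec in records], dtype=float)
    w = np.array([rec.insured_fraction for rec in records], dtype=float)
    ids = tuple(rec.person_id for rec in records)
    return DesignMatrix(tuple(columns), X, ids, y, w)


def drop_empty_columns(
    labels: Sequence[str], matrix: sparse.spmatrix
) -> tuple[list[str], sparse.csr_matrix]:
    """Remove all-zero columns (classes with no qualifying person).

    A risk class nobody belongs to has no estimable payment weight and
    would make the design rank deficient; callers drop such columns and
    keep the label alignment through the returned list.
    """
    csc = sparse.csc_matrix(matrix)
    occupied = np.flatnonzero(np.diff(csc.indptr) > 0)
    return [labels[j] for j in occupied], csc[:, occupied].tocsr()


def dxgroup_indicator_matrix(
    records: Sequence[PersonRecord], catalogue: Sequence[str]
) -> tuple[list[str], sparse.csr_matrix]:
    """0/1 membership columns, one per dxgroup in catalogue order.

    A person's dxgroups form a set, so these indicator columns are the
    "full-dummy" regressors of the per-dxgroup model.
    """
    index = {g: j for j, g in enumerate(catalogue)}
    rows: list[int] = []
    cols: list[int] = []
    for i, rec in enumerate(records):
        for g in rec.dxgroups:
            rows.append(i)
            cols.append(index[g])
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(records), len(catalogue)),
        dtype=float,
    )
    labels = [f"dx:{g}" for g in catalogue]
    return labels, mat


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["person_id", "insured_fraction", "spending", "age_band", "gender"]


def write_population(records: Sequence[PersonRecord], path,
                     scheme: RiskAdjusterScheme) -> None:
    """Write records as a UTF-8 CSV table (spending stored annualized)."""
    morb = [c.name for c in scheme.morbidity]
    frame = pd.DataFrame(
        {
            "person_id": [r.person_id for r in records],
            "insured_fraction": [r.insured_fraction for r in records],
            "spending": [r.spending_annualized for r in records],
            "age_band": [r.age_band for r in records],
            "gender": [r.gender for r in records],
            **{
                name: [r.adjuster_flags[name] for r in records]
                for name in morb
            },
            "dxgroups": [";".join(sorted(r.dxgroups)) for r in records],
            "conditions": [";".join(sorted(r.conditions)) for r in records],
        }
    )
    frame.to_csv(path, index=False)


def _split_ids(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return _EMPTY
    return frozenset(str(cell).split(";"))


def read_population(path, scheme: RiskAdjusterScheme) -> list[PersonRecord]:
    """Read a population CSV/TSV, validating every row.

    Malformed rows are reported with their (1-based, header-exclusive)
    row numbers; duplicate person ids and unregistered dxgroups are
    errors.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype={"person_id": str}, keep_default_na=False)
    morb = [c.name for c in scheme.morbidity]
    missing = [c for c in _BASE_COLUMNS + morb if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")
    dup = frame["person_id"][frame["person_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate person_id(s): {sorted(set(dup))[:5]}"
        )
    has_cond = "conditions" in frame.columns
    catalogue = frozenset(scheme.dxgroup_catalogue)
    records: list[PersonRecord] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        rowd = row._asdict()
        try:
            rec = PersonRecord(
                person_id=str(rowd["person_id"]),
                insured_fraction=float(rowd["insured_fraction"]),
                spending_annualized=float(rowd["spending"]),
                age_band=str(rowd["age_band"]),
                gender=str(rowd["gender"]),
                adjuster_flags={name: str(rowd[name]) for name in morb},
                dxgroups=_split_ids(rowd["dxgroups"]),
                conditions=_split_ids(rowd["conditions"]) if has_cond else _EMPTY,
            )
            _validate_record(rec, scheme, catalogue)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        records.append(rec)
    return records


def write_scheme(scheme: RiskAdjusterScheme, path) -> None:
    payload = {
        "classifications": [
            {
                "name": c.name,
                "labels": list(c.labels),
                "exclusive": c.exclusive,
                "reference": c.reference,
            }
            for c in scheme.classifications
        ],
        "dxgroup_catalogue": list(scheme.dxgroup_catalogue),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_scheme(path) -> RiskAdjusterScheme:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        classifications = tuple(
            Classification(
                name=c["name"],
                labels=tuple(c["labels"]),
                exclusive=bool(c.get("exclusive", True)),
                reference=c.get("reference"),
            )
            for c in payload["classifications"]
        )
        return RiskAdjusterScheme(
            classifications, tuple(payload.get("dxgroup_catalogue", ()))
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed scheme file {path}: {exc}") from exc
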