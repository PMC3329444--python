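"""Patient-level domain types, marker categorisation rules and cohort I/O.

The clinical side of genomic-grade analysis for early-stage (pT1-2, pN0)
breast carcinoma: mitotic-index and Ki67 cut-offs, immunophenotype
assignment from ER/PR/HER2 status, tumor-cell-content filtering, and
round-trippable delimited-text cohort tables.

Categorisation conventions
--------------------------
* Mitotic index (mitoses per 10 high-power fields): MI1 < 10,
  MI2 = 10-19, MI3 >= 20; the dichotomy is low (< 20) vs high (>= 20).
* Ki67: ``high`` means strictly greater than the cut-off (default 20%),
  so a tumour at exactly 20% is low.
* Immunophenotype: HER2 positivity takes precedence over ER status, so
  ER+/HER2+ tumours are classed HER2-positive; triple negative requires
  all three markers negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import CohortIOError, ValidationError

__all__ = [
    "HistoType",
    "MitoticCategory",
    "MitoticDichotomy",
    "Ki67Category",
    "Immunophenotype",
    "PatientRecord",
    "Cohort",
    "categorize_mi",
    "dichotomize_mi",
    "categorize_ki67",
    "immunophenotype",
    "read_cohort",
    "write_cohort",
    "filter_tumor_content",
]

log = logging.getLogger(__name__)


class HistoType(str, Enum):
    IDC = "IDC"
    ILC = "ILC"
    MIXED = "mixed"
    OTHER = "other"


class MitoticCategory(str, Enum):
    MI1 = "MI1"
    MI2 = "MI2"
    MI3 = "MI3"


class MitoticDichotomy(str, Enum):
    LOW = "lowMI"
    HIGH = "highMI"


class Ki67Category(str, Enum):
    LOW = "low"
    HIGH = "high"


class Immunophenotype(str, Enum):
    ER_POS_HER2_NEG = "ER_pos_HER2_neg"
    HER2_POS = "HER2_pos"
    TRIPLE_NEG = "triple_neg"
    ER_NEG_HER2_NEG_PR_POS = "ER_neg_HER2_neg_PR_pos"


def _check_mitoses(mitoses) -> int:
    if mitoses is None or (isinstance(mitoses, float) and math.isnan(mitoses)):
        raise ValidationError("mitotic count is missing")
    if isinstance(mitoses, bool) or float(mitoses) != int(mitoses):
        raise ValidationError(f"mitotic count must be an integer, got {mitoses!r}")
    m = int(mitoses)
    if m < 0:
        raise ValidationError(f"mitotic count must be >= 0, got {m}")
    return m


def categorize_mi(mitoses) -> MitoticCategory:
    """Three-level mitotic index: < 10 -> MI1, 10-19 -> MI2, >= 20 -> MI3."""
    m = _check_mitoses(mitoses)
    if m < 10:
        return MitoticCategory.MI1
    if m < 20:
        return MitoticCategory.MI2
    return MitoticCategory.MI3


def dichotomize_mi(mitoses) -> MitoticDichotomy:
    """Low (< 20) vs high (>= 20) mitotic index."""
    m = _check_mitoses(mitoses)
    return MitoticDichotomy.HIGH if m >= 20 else MitoticDichotomy.LOW


def categorize_ki67(ki67: float, cutoff: float = 20.0) -> Ki67Category:
    """High Ki67 means strictly above *cutoff* percent (default > 20%)."""
    if ki67 is None or not math.isfinite(ki67):
        raise ValidationError("Ki67 score is missing or non-finite")
    if not 0.0 <= ki67 <= 100.0:
        raise ValidationError(f"Ki67 must be a percentage in [0, 100], got {ki67}")
    return Ki67Category.HIGH if ki67 > cutoff else Ki67Category.LOW


def immunophenotype(er, pr, her2) -> Immunophenotype:
    """Assign a marker-based subtype; HER2 positivity takes precedence.

    The precedence rule means ER+/HER2+ tumours fall in the HER2-positive
    class, so the ER-positive class is implicitly ER+/HER2-.
    """
    for name, v in (("er", er), ("pr", pr), ("her2", her2)):
        if v is None:
            raise ValidationError(f"marker {name!r} is missing")
    if her2:
        return Immunophenotype.HER2_POS
    if er:
        return Immunophenotype.ER_POS_HER2_NEG
    if not pr:
        return Immunophenotype.TRIPLE_NEG
    return Immunophenotype.ER_NEG_HER2_NEG_PR_POS


@dataclass
class PatientRecord:
    """One patient: clinical covariates, marker values and follow-up.

    Booleans follow pathology-report semantics (positive = True).
    ``follow_up`` is months from diagnosis to distant metastasis or censoring.
    """

    patient_id: str
    age: float
    tumor_size: float  # mm
    hg: int  # Elston-Ellis histological grade 1..3
    mitoses: int  # per 10 HPF
    ki67: float  # percent
    er: bool
    pr: bool
    her2: bool
    follow_up: float  # months
    metastasis: bool
    histo_type: Optional[HistoType] = None
    lvi: Optional[bool] = None
    tumor_cell_pct: Optional[float] = None
    received_aht: Optional[bool] = None
    received_act: Optional[bool] = None

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError("patient_id must be nonempty")
        if self.hg not in (1, 2, 3):
            raise ValidationError(
                f"patient {self.patient_id}: hg must be 1, 2 or 3, got {self.hg!r}"
            )
        self.mitoses = _check_mitoses(self.mitoses)
        if not 0.0 <= self.ki67 <= 100.0:
            raise ValidationError(
                f"patient {self.patient_id}: ki67 must be in [0, 100], got {self.ki67}"
            )
        if self.follow_up < 0:
            raise ValidationError(
                f"patient {self.patient_id}: follow_up must be >= 0, got {self.follow_up}"
            )
        if self.age <= 0:
            raise ValidationError(f"patient {self.patient_id}: age must be > 0")
        if self.tumor_size <= 0:
            raise ValidationError(f"patient {self.patient_id}: tumor_size must be > 0")
        if self.tumor_cell_pct is not None and not 0 <= self.tumor_cell_pct <= 100:
            raise ValidationError(
                f"patient {self.patient_id}: tumor_cell_pct must be in [0, 100]"
            )


MANDATORY_COLUMNS = (
    "patient_id",
    "age",
    "tumor_size",
    "hg",
    "mitoses",
    "ki67",
    "er",
    "pr",
    "her2",
    "follow_up",
    "metastasis",
)
OPTIONAL_COLUMNS = ("histo_type", "lvi", "tumor_cell_pct", "received_aht", "received_act")


@dataclass
class Cohort:
    """An ordered collection of patients with unique ids.

    ``annotations`` preserves any table columns outside the canonical schema
    so that read -> write round-trips losslessly.
    """

    records: tuple
    provenance: str = ""
    annotations: Optional[pd.DataFrame] = None  # indexed by patient_id

    def __post_init__(self):
        self.records = tuple(self.records)
        ids = [r.patient_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate patient ids: {sorted(dupes)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list:
        return [r.patient_id for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {f.name: getattr(r, f.name) for f in fields(r)}
            d["histo_type"] = None if r.histo_type is None else r.histo_type.value
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS))
        if self.annotations is not None and not self.annotations.empty:
            ann = self.annotations.reindex(df["patient_id"]).reset_index(drop=True)
            df = pd.concat([df, ann], axis=1)
        return df


_TRUE = {"1", "true", "yes", "pos", "positive", "t", "y"}
_FALSE = {"0", "false", "no", "neg", "negative", "f", "n"}


def _parse_bool(raw: str, row: int, col: str, required: bool):
    s = str(raw).strip().lower()
    if s in ("", "nan", "na", "none"):
        if required:
            raise CohortIOError(f"row {row}: missing value in column {col!r}")
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise CohortIOError(f"row {row}: cannot parse boolean {raw!r} in column {col!r}")


def _parse_float(raw: str, row: int, col: str, required: bool):
    s = str(raw).strip()
    if s.lower() in ("", "nan", "na", "none"):
        if required:
            raise CohortIOError(f"row {row}: missing value in column {col!r}")
        return None
    try:
        return float(s)
    except ValueError:
        raise CohortIOError(
            f"row {row}: cannot parse number {raw!r} in column {col!r}"
        ) from None


def read_cohort(path, provenance: Optional[str] = None) -> Cohort:
    """Read a cohort table (comma- or tab-delimited, auto-detected by header).

    Unknown columns are preserved as annotations; missing mandatory columns,
    unparseable values and duplicate ids raise :class:`CohortIOError` naming
    the offending row/column.
    """
    path = str(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"missing mandatory column(s): {missing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        pid = str(row["patient_id"]).strip()
        try:
            ht_raw = str(row.get("histo_type", "")).strip()
            kwargs = dict(
                patient_id=pid,
                age=_parse_float(row["age"], i, "age", True),
                tumor_size=_parse_float(row["tumor_size"], i, "tumor_size", True),
                hg=int(_parse_float(row["hg"], i, "hg", True)),
                mitoses=_parse_float(row["mitoses"], i, "mitoses", True),
                ki67=_parse_float(row["ki67"], i, "ki67", True),
                er=_parse_bool(row["er"], i, "er", True),
                pr=_parse_bool(row["pr"], i, "pr", True),
                her2=_parse_bool(row["her2"], i, "her2", True),
                follow_up=_parse_float(row["follow_up"], i, "follow_up", True),
                metastasis=_parse_bool(row["metastasis"], i, "metastasis", True),
                histo_type=HistoType(ht_raw) if ht_raw not in ("", "nan") else None,
                lvi=_parse_bool(row.get("lvi", ""), i, "lvi", False),
                tumor_cell_pct=_parse_float(
                    row.get("tumor_cell_pct", ""), i, "tumor_cell_pct", False
                ),
                received_aht=_parse_bool(row.get("received_aht", ""), i, "received_aht", False),
                received_act=_parse_bool(row.get("received_act", ""), i, "received_act", False),
            )
        except ValueError as exc:
            raise CohortIOError(f"row {i}: {exc}") from None
        try:
            records.append(PatientRecord(**kwargs))
        except ValidationError as exc:
            raise CohortIOError(f"row {i}: {exc}") from None

    extra_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    annotations = None
    if extra_cols:
        annotations = df[extra_cols].copy()
        annotations.index = pd.Index([r.patient_id for r in records], name="patient_id")
    try:
        return Cohort(
            records=tuple(records),
            provenance=provenance if provenance is not None else path,
            annotations=annotations,
        )
    except ValidationError as exc:
        raise CohortIOError(str(exc)) from None


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort table; tab-delimited for ``.tsv`` paths, comma otherwise."""
    path = str(path)
    sep = "\t" if path.endswith(".tsv") else ","
    df = cohort.to_dataframe()
    for col in ("er", "pr", "her2", "metastasis", "lvi", "received_aht", "received_act"):
        df[col] = df[col].map(lambda v: "" if v is None else str(int(v)))
    df.to_csv(path, sep=sep, index=False)


def filter_tumor_content(cohort: Cohort, threshold: float = 50.0):
    """Keep records with tumour-cell content strictly above *threshold* percent.

    Records with missing ``tumor_cell_pct`` fail the filter.  Returns
    ``(filtered_cohort, n_removed)``.
    """
    kept = [
        r for r in cohort.records
        if r.tumor_cell_pct is not None and r.tumor_cell_pct > threshold
    ]
    n_removed = len(cohort.records) - len(kept)
    if n_removed:
        log.info("filter_tumor_content: removed %d of %d records (threshold %g%%)",
                 n_removed, len(cohort.records), threshold)
    ann = None
    if cohort.annotations is not None:
        ann = cohort.annotations.loc[[r.patient_id for r in kept]]
    return Cohort(tuple(kept), cohort.provenance, ann), n_removed
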