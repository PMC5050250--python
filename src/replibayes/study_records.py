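"""Study-level data model for replication meta-analyses.

One :class:`StudyRecord` describes a single original effect together with its
independent-replication outcome and the covariates used as reproducibility
predictors (field of study, effect type, original p-value and effect size,
replication power, surprisingness, challenge, presence of a formal power
analysis).  A :class:`StudyTable` is an ordered collection of such records that
round-trips losslessly through CSV, including missing values (encoded as empty
fields, never as sentinel numbers).

Effects are grouped throughout the package by whether the original publication
contained at least one internal conceptual replication
(``internal_replication_count > 0``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "StudyTable",
    "SchemaError",
    "ValidationError",
    "read_study_table",
    "write_study_table",
    "validation_report",
    "replication_success_flag",
    "es_reduction_simple",
    "es_reduction_q",
    "log_sample_size",
    "COLUMNS",
    "DEFAULT_EXCLUSION_THRESHOLD",
]

#: canonical CSV column order
COLUMNS = (
    "study_id",
    "internal_replication_count",
    "discipline",
    "effect_type",
    "p_original",
    "r_original",
    "n_original",
    "p_replication",
    "r_replication",
    "replication_power",
    "surprisingness",
    "challenge",
    "power_analysis_present",
)

#: fields that may legitimately be missing (replication outcome and ratings)
OPTIONAL_FIELDS = frozenset(
    {"p_replication", "r_replication", "surprisingness", "challenge"}
)

DISCIPLINES = ("cognitive", "social")
EFFECT_TYPES = ("main", "interaction")

#: any study at least this large is flagged as an outlier for the
#: log-sample-size analysis; chosen so that exactly the single N = 230,025
#: study in the reference dataset is excluded.
DEFAULT_EXCLUSION_THRESHOLD = 200_000


class SchemaError(ValueError):
    """The CSV header does not contain a mandatory column."""


class ValidationError(ValueError):
    """One or more rows violate a field constraint.

    The offending rows are listed in :attr:`report` (also rendered in the
    message), each entry naming the row number, field and problem.
    """

    def __init__(self, report: list[dict]):
        self.report = report
        lines = [f"row {e['row']}: {e['field']}: {e['message']}" for e in report]
        super().__init__("invalid study table:\n" + "\n".join(lines))


@dataclass(frozen=True)
class StudyRecord:
    """One original effect with its independent-replication outcome."""

    study_id: str
    internal_replication_count: int
    discipline: str
    effect_type: str
    p_original: float
    r_original: float
    n_original: int
    p_replication: float | None
    r_replication: float | None
    replication_power: float
    surprisingness: float | None
    challenge: float | None
    power_analysis_present: bool

    @property
    def internally_replicated(self) -> bool:
        return self.internal_replication_count > 0


@dataclass
class StudyTable:
    """Ordered collection of :class:`StudyRecord` with unique ids."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                [{"row": -1, "field": "study_id", "message": f"duplicate id {d!r}"}
                 for d in dupes]
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {f.name: getattr(r, f.name) for f in fields(StudyRecord)}
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "StudyTable":
        report = validation_report(df)
        if report["errors"]:
            raise ValidationError(report["errors"])
        records = [_record_from_row(row) for _, row in df.iterrows()]
        return cls(records=records, provenance=provenance)

    # -- grouping ---------------------------------------------------------

    def split_by_internal_replication(self) -> tuple["StudyTable", "StudyTable"]:
        """Partition into (internally replicated, internally unreplicated)."""
        rep = [r for r in self.records if r.internally_replicated]
        unrep = [r for r in self.records if not r.internally_replicated]
        return (
            StudyTable(rep, provenance=self.provenance),
            StudyTable(unrep, provenance=self.provenance),
        )

    def subset(self, predicate) -> "StudyTable":
        return StudyTable([r for r in self.records if predicate(r)],
                          provenance=self.provenance)


# ---------------------------------------------------------------------------
# validation and I/O


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _parse_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no"}:
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def validation_report(df: pd.DataFrame) -> dict:
    """Validate a raw frame against the study-record schema.

    Returns a JSON-serialisable report ``{"n_rows": ..., "errors": [...]}``;
    each error names the (1-based, header excluded) row, the field and the
    problem.  Raises :class:`SchemaError` if a mandatory column is absent.
    """
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    errors: list[dict] = []

    def err(i, f, msg):
        errors.append({"row": int(i) + 1, "field": f, "message": msg})

    for i, (_, row) in enumerate(df.iterrows()):
        for name in COLUMNS:
            v = row[name]
            if _is_missing(v):
                if name not in OPTIONAL_FIELDS:
                    err(i, name, "missing value in mandatory field")
                continue
            try:
                if name == "internal_replication_count":
                    if int(v) < 0:
                        err(i, name, f"must be >= 0, got {v}")
                elif name == "discipline":
                    if str(v) not in DISCIPLINES:
                        err(i, name, f"must be one of {DISCIPLINES}, got {v!r}")
                elif name == "effect_type":
                    if str(v) not in EFFECT_TYPES:
                        err(i, name, f"must be one of {EFFECT_TYPES}, got {v!r}")
                elif name in ("p_original", "p_replication"):
                    if not 0.0 < float(v) <= 1.0:
                        err(i, name, f"probability must lie in (0, 1], got {v}")
                elif name in ("r_original", "r_replication"):
                    if not -1.0 <= float(v) <= 1.0:
                        err(i, name, f"effect size must lie in [-1, 1], got {v}")
                elif name == "n_original":
                    if int(v) < 1:
                        err(i, name, f"sample size must be >= 1, got {v}")
                elif name == "replication_power":
                    if not 0.0 <= float(v) <= 1.0:
                        err(i, name, f"power must lie in [0, 1], got {v}")
                elif name == "surprisingness":
                    if not 1.0 <= float(v) <= 6.0:
                        err(i, name, f"rating must lie in [1, 6], got {v}")
                elif name == "power_analysis_present":
                    _parse_bool(v)
            except (TypeError, ValueError) as exc:
                err(i, name, str(exc))

    return {"n_rows": int(len(df)), "errors": errors}


def _record_from_row(row: Mapping) -> StudyRecord:
    def opt(name):
        v = row[name]
        return None if _is_missing(v) else float(v)

    return StudyRecord(
        study_id=str(row["study_id"]),
        internal_replication_count=int(row["internal_replication_count"]),
        discipline=str(row["discipline"]),
        effect_type=str(row["effect_type"]),
        p_original=float(row["p_original"]),
        r_original=float(row["r_original"]),
        n_original=int(row["n_original"]),
        p_replication=opt("p_replication"),
        r_replication=opt("r_replication"),
        replication_power=float(row["replication_power"]),
        surprisingness=opt("surprisingness"),
        challenge=opt("challenge"),
        power_analysis_present=_parse_bool(row["power_analysis_present"]),
    )


def read_study_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> StudyTable:
    """Read a study table from a UTF-8, header-row CSV file.

    ``column_map`` maps canonical field names to the file's column names, so
    external exports of the reproducibility dataset can be adapted without
    code changes.  Malformed rows raise :class:`ValidationError` with row
    numbers; a missing mandatory column raises :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=False)
    if column_map:
        inverse = {src: canonical for canonical, src in column_map.items()}
        df = df.rename(columns=inverse)
    df = df.replace("", np.nan)
    return StudyTable.from_dataframe(
        df, provenance=provenance if provenance is not None else str(path)
    )


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table as CSV; missing values become empty fields."""
    df = table.to_dataframe()
    out = df.copy()
    # round-trip booleans as lowercase text
    out["power_analysis_present"] = out["power_analysis_present"].map(
        lambda b: "true" if b else "false"
    )
    out.to_csv(path, index=False, na_rep="")


def write_validation_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


# ---------------------------------------------------------------------------
# derived measures


def replication_success_flag(
    record: StudyRecord, alpha: float = 0.05
) -> bool | None:
    """Independent replication success: replication p strictly below ``alpha``.

    Missing replication p-values propagate as ``None``.
    """
    if record.p_replication is None:
        return None
    return record.p_replication < alpha


def es_reduction_simple(r_original: float, r_replication: float) -> float:
    """Effect-size reduction by simple subtraction, ``r_orig - r_rep``."""
    for r in (r_original, r_replication):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"effect size must lie in [-1, 1], got {r}")
    return r_original - r_replication


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform ``z = atanh(r)``."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return math.atanh(r)


def es_reduction_q(r_original: float, r_replication: float) -> float:
    """Cohen's q: difference between Fisher-z-transformed correlations."""
    return fisher_z(r_original) - fisher_z(r_replication)


def log_sample_size(
    table: StudyTable,
    exclusion_threshold: int = DEFAULT_EXCLUSION_THRESHOLD,
) -> pd.DataFrame:
    """Natural log of original sample sizes, flagging outliers for exclusion.

    Sample sizes are analysed on the log scale because their raw distribution
    is heavily right-skewed.  Records with ``n_original >=
    exclusion_threshold`` are flagged ``excluded=True`` rather than dropped,
    so the same table serves analyses with and without the exclusion.
    """
    rows = []
    for r in table:
        rows.append(
            {
                "study_id": r.study_id,
                "n_original": r.n_original,
                "log_n": math.log(r.n_original),
                "excluded": r.n_original >= exclusion_threshold,
            }
        )
    return pd.DataFrame(rows, columns=["study_id", "n_original", "log_n", "excluded"])
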