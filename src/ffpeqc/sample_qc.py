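"""Per-sample QC tables for FFPE RNA-Seq feasibility studies.

This module defines the record schema for a per-sample quality-control table
(one row per sequenced RNA sample: fragment distribution values, library
metrics, storage time, contamination, expression-cluster label), delimited-text
I/O with explicit missing-value handling, and descriptive statistics.

A packaged fixture, ``table2_seer_ffpe.tsv``, carries the QC table for a
67-sample cohort of archival high-grade ovarian serous adenocarcinoma FFPE
specimens from SEER Residual Tissue Repositories (storage times 7-32 years).
Biological replicates appear as ordinary, independent rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleQCRecord",
    "ColumnSummary",
    "Predicate",
    "QCTableError",
    "read_qc_table",
    "write_qc_table",
    "load_table2",
    "records_to_frame",
    "summarize_column",
    "count_where",
    "parse_predicate",
    "NUMERIC_COLUMNS",
]

#: numeric columns of the schema, in table order
NUMERIC_COLUMNS = (
    "input_for_libprep",
    "rin",
    "dv200",
    "dv100",
    "dv50",
    "lib_size",
    "lib_yield",
    "lib_molarity",
    "storage_time",
    "contamination_pct",
    "genes_detected",
)

_ALL_COLUMNS = ("sample_id",) + NUMERIC_COLUMNS + ("resequenced", "cluster_label", "site")
_REQUIRED_COLUMNS = ("sample_id",) + NUMERIC_COLUMNS + ("resequenced", "cluster_label")

#: default missing token, plus per-column aliases (the source table writes
#: "no info" for an unknown storage time)
DEFAULT_MISSING_TOKEN = "NA"
DEFAULT_MISSING_ALIASES = {"storage_time": ("no info",)}

_CLUSTER_LABELS = frozenset({"B", "C", "D"})


class QCTableError(ValueError):
    """Raised for malformed QC tables (unknown columns, bad values, duplicates)."""


@dataclass
class SampleQCRecord:
    """One row of the per-sample QC table.

    Percent-valued fields (``rin`` aside) are on the 0-100 scale. ``None``
    encodes a value that could not be measured and is distinct from zero:
    missing values never enter statistics or interval predicates.
    """

    sample_id: str
    input_for_libprep: float  # ng of total RNA into library prep
    rin: Optional[float]  # RNA Integrity Number, 1-10
    dv200: Optional[float]  # % RNA mass in fragments > 200 nt
    dv100: Optional[float]  # % > 100 nt
    dv50: Optional[float]  # % > 50 nt
    lib_size: float  # mean library fragment size, bp
    lib_yield: float  # library yield, ng
    lib_molarity: float  # library molarity, nM
    storage_time: Optional[int]  # specimen storage, whole years (>= 1)
    resequenced: bool
    contamination_pct: float  # % reads attributed to non-human genomes
    cluster_label: Optional[str] = None  # expression-concordance class B/C/D
    genes_detected: int = 0  # genes with > 5 mapped reads
    site: Optional[str] = None  # repository site (synthetic cohorts only)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.sample_id:
            problems.append("empty sample_id")
        for name, lo, hi in (
            ("rin", 1.0, 10.0),
            ("dv200", 0.0, 100.0),
            ("dv100", 0.0, 100.0),
            ("dv50", 0.0, 100.0),
            ("contamination_pct", 0.0, 100.0),
        ):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                problems.append(f"{name}={v} outside [{lo},{hi}]")
        for name in ("input_for_libprep", "lib_size", "lib_yield", "lib_molarity"):
            v = getattr(self, name)
            if v is None or v <= 0:
                problems.append(f"{name}={v} must be > 0")
        if self.storage_time is not None and self.storage_time < 1:
            problems.append(f"storage_time={self.storage_time} must be >= 1")
        if self.genes_detected is None or self.genes_detected < 0:
            problems.append(f"genes_detected={self.genes_detected} must be >= 0")
        if self.cluster_label is not None and self.cluster_label not in _CLUSTER_LABELS:
            problems.append(f"cluster_label={self.cluster_label!r} not in {{B,C,D}}")
        if self.dv50 is not None and self.dv100 is not None and self.dv200 is not None:
            if not (self.dv50 >= self.dv100 >= self.dv200):
                problems.append(
                    f"DV not monotone: dv50={self.dv50}, dv100={self.dv100}, dv200={self.dv200}"
                )
        return problems


@dataclass
class ColumnSummary:
    """Descriptive statistics of one numeric column over non-missing values.

    Quartiles use the linear-interpolation convention (the one whisker rules
    such as 1.5x IQR are usually stated against); ``sd`` is the sample
    standard deviation (0 for a single value).
    """

    metric_name: str
    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    sd: float
    quartile_method: str = "linear-interpolation"


def _parse_numeric(
    raw, column: str, row_label, missing_token: str, aliases: dict
) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s == missing_token or s in aliases.get(column, ()):
        return None
    try:
        return float(s)
    except ValueError:
        raise QCTableError(
            f"non-numeric value {s!r} in column {column!r}, row {row_label}"
        ) from None


def read_qc_table(
    path,
    *,
    sep: Optional[str] = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    missing_aliases: Optional[dict] = None,
) -> list[SampleQCRecord]:
    """Read a delimited QC table into validated records.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; auto-detected when ``sep`` is None)
        with a mandatory header row naming the schema columns.
    missing_token
        Token encoding a missing value (default ``"NA"``).
    missing_aliases
        Extra per-column missing tokens; defaults map ``"no info"`` to missing
        for ``storage_time``.

    Raises
    ------
    QCTableError
        On unknown columns, non-numeric values outside the missing tokens,
        duplicate sample ids, or records violating schema invariants (reported
        with their row numbers).
    """
    aliases = dict(DEFAULT_MISSING_ALIASES)
    if missing_aliases:
        aliases.update(missing_aliases)
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    unknown = [c for c in df.columns if c not in _ALL_COLUMNS]
    if unknown:
        raise QCTableError(f"unknown column(s): {', '.join(map(repr, unknown))}")
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise QCTableError(f"missing column(s): {', '.join(map(repr, missing_cols))}")

    records: list[SampleQCRecord] = []
    violations: list[str] = []
    for i, row in df.iterrows():
        row_no = int(i) + 2  # 1-based, header is line 1
        vals = {
            c: _parse_numeric(row[c], c, row_no, missing_token, aliases)
            for c in NUMERIC_COLUMNS
        }
        storage = vals.pop("storage_time")
        genes = vals.pop("genes_detected")
        cluster = str(row["cluster_label"]).strip() or None
        if cluster == missing_token:
            cluster = None
        site = str(row["site"]).strip() or None if "site" in df.columns else None
        rec = SampleQCRecord(
            sample_id=str(row["sample_id"]).strip(),
            storage_time=int(storage) if storage is not None else None,
            resequenced=str(row["resequenced"]).strip().upper() in ("Y", "YES", "TRUE", "1"),
            cluster_label=cluster,
            genes_detected=int(genes) if genes is not None else 0,
            site=site,
            **vals,
        )
        problems = rec.validate()
        if problems:
            violations.append(f"row {row_no} ({rec.sample_id}): " + "; ".join(problems))
        records.append(rec)
    if violations:
        raise QCTableError("invalid record(s):\n" + "\n".join(violations))
    ids = [r.sample_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise QCTableError(f"duplicate sample_id(s): {', '.join(sorted(dupes))}")
    return records


def write_qc_table(
    records: Sequence[SampleQCRecord],
    path,
    *,
    sep: str = "\t",
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write records back to delimited text; inverse of :func:`read_qc_table`."""
    cols = [f.name for f in dc_fields(SampleQCRecord)]
    include_site = any(r.site is not None for r in records)
    if not include_site:
        cols = [c for c in cols if c != "site"]

    def fmt(rec: SampleQCRecord, c: str) -> str:
        v = getattr(rec, c)
        if c == "resequenced":
            return "Y" if v else "N"
        if v is None:
            return missing_token if c in NUMERIC_COLUMNS else ""
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    lines = [sep.join(cols)]
    lines += [sep.join(fmt(r, c) for c in cols) for r in records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_table2() -> list[SampleQCRecord]:
    """Load the packaged 67-sample SEER FFPE ovarian carcinoma QC table."""
    ref = resources.files("ffpeqc").joinpath("data/table2_seer_ffpe.tsv")
    with resources.as_file(ref) as p:
        return read_qc_table(p)


def records_to_frame(records: Iterable[SampleQCRecord]) -> pd.DataFrame:
    """Records as a DataFrame; missing values become NaN (numeric) / None."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in dc_fields(SampleQCRecord)}
        rows.append(d)
    df = pd.DataFrame(rows)
    for c in NUMERIC_COLUMNS:
        df[c] = pd.to_numeric(df[c])
    return df


def summarize_column(records: Sequence[SampleQCRecord], metric: str) -> ColumnSummary:
    """Five-number summary plus mean/sd of a numeric column, missing excluded."""
    if metric not in NUMERIC_COLUMNS:
        raise ValueError(f"{metric!r} is not a numeric column")
    values = np.array(
        [getattr(r, metric) for r in records if getattr(r, metric) is not None],
        dtype=float,
    )
    if values.size == 0:
        raise ValueError(f"no data for metric {metric!r}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ColumnSummary(
        metric_name=metric,
        n=int(values.size),
        min=float(values.min()),
        q1=float(q1),
        median=float(med),
        mean=float(values.mean()),
        q3=float(q3),
        max=float(values.max()),
        sd=sd,
    )


@dataclass(frozen=True)
class Predicate:
    """Interval or missingness test on one numeric column.

    ``lower``/``upper`` of ``None`` mean unbounded; ``closed`` is one of
    ``both``, ``left``, ``right``, ``neither``. Missing values never satisfy
    an interval predicate; ``is_missing=True`` tests missingness instead.
    """

    metric: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    closed: str = "both"
    is_missing: bool = False

    def __post_init__(self):
        if self.metric not in NUMERIC_COLUMNS:
            raise ValueError(f"{self.metric!r} is not a numeric column")
        if self.closed not in ("both", "left", "right", "neither"):
            raise ValueError(f"bad closed={self.closed!r}")

    def __call__(self, record: SampleQCRecord) -> bool:
        v = getattr(record, self.metric)
        if self.is_missing:
            return v is None
        if v is None:
            return False
        if self.lower is not None:
            if self.closed in ("both", "left"):
                if v < self.lower:
                    return False
            elif v <= self.lower:
                return False
        if self.upper is not None:
            if self.closed in ("both", "right"):
                if v > self.upper:
                    return False
            elif v >= self.upper:
                return False
        return True


def count_where(records: Iterable[SampleQCRecord], predicate: Predicate) -> int:
    """Count records satisfying an interval or is-missing predicate."""
    return sum(1 for r in records if predicate(r))


def parse_predicate(expr: str) -> Predicate:
    """Parse a predicate string.

    Supported forms: ``"dv200 in [30,50]"`` (brackets/parens pick closed/open
    ends), ``"dv200 > 50"``, ``"dv200 <= 5"``, ``"dv200 missing"``.
    """
    tokens = expr.strip().split(None, 1)
    if len(tokens) != 2:
        raise ValueError(f"cannot parse predicate {expr!r}")
    metric, rest = tokens[0], tokens[1].strip()
    if rest == "missing":
        return Predicate(metric, is_missing=True)
    if rest.startswith("in"):
        body = rest[2:].strip()
        left_closed = body.startswith("[")
        right_closed = body.endswith("]")
        if not (body[0] in "[(" and body[-1] in "])"):
            raise ValueError(f"cannot parse interval in {expr!r}")
        lo_s, hi_s = body[1:-1].split(",")
        closed = {
            (True, True): "both",
            (True, False): "left",
            (False, True): "right",
            (False, False): "neither",
        }[(left_closed, right_closed)]
        return Predicate(metric, float(lo_s), float(hi_s), closed=closed)
    for op in ("<=", ">=", "<", ">"):
        if rest.startswith(op):
            val = float(rest[len(op):])
            if op == ">":
                return Predicate(metric, lower=val, closed="neither")
            if op == ">=":
                return Predicate(metric, lower=val, closed="left")
            if op == "<":
                return Predicate(metric, upper=val, closed="neither")
            return Predicate(metric, upper=val, closed="right")
    raise ValueError(f"cannot parse predicate {expr!r}")
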