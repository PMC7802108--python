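"""Readers/writers for HPA-style staining tables and query-list parsing.

The normal-tissue table is the tab-separated dialect of the Human Protein
Atlas ``normal_tissue.tsv`` download: one row per (gene, tissue, cell type)
with a pathologist staining call (``Level``) and an antibody-evidence label
(``Reliability``).  The cancer table is the ``pathology.tsv`` dialect: one
row per (gene, cancer) with patient counts at each staining level.

Tables are held in memory as :class:`pandas.DataFrame` objects with
canonical snake_case columns; parsing is *loss-counting* — every dropped
line is tallied in a :class:`ParseReport` that callers can assert on.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import EmptyInputError, EmptyQueryError, ParseError, SchemaError

#: Closed vocabulary of staining levels, strongest first.
LEVELS = ("High", "Medium", "Low", "Not detected")

#: Closed vocabulary of antibody-evidence labels, most certain first.
RELIABILITIES = ("Enhanced", "Supported", "Approved", "Uncertain")

#: Positive (detected) staining levels.
POSITIVE_LEVELS = frozenset({"High", "Medium", "Low"})

# header label (case-insensitive) -> canonical column
_NORMAL_COLUMNS = {
    "Gene": "gene_id",
    "Gene name": "gene_name",
    "Tissue": "tissue",
    "Cell type": "cell_type",
    "Level": "level",
    "Reliability": "reliability",
}
_CANCER_COLUMNS = {
    "Gene": "gene_id",
    "Gene name": "gene_name",
    "Cancer": "cancer",
    "High": "n_high",
    "Medium": "n_medium",
    "Low": "n_low",
    "Not detected": "n_not_detected",
}

_LEVEL_CANON = {lv.casefold(): lv for lv in LEVELS}
_RELIABILITY_CANON = {r.casefold(): r for r in RELIABILITIES}

NORMAL_TISSUE_COLUMNS = tuple(_NORMAL_COLUMNS.values())
CANCER_COLUMNS = tuple(_CANCER_COLUMNS.values())


@dataclasses.dataclass(frozen=True)
class ParseReport:
    """Loss accounting for one parsed table.

    Invariant: ``n_retained`` plus all drop counters equals ``n_lines``
    (data lines, excluding the header).
    """

    n_lines: int
    n_retained: int
    n_dropped_level: int = 0
    n_dropped_reliability: int = 0
    n_dropped_blank: int = 0

    def __post_init__(self) -> None:
        dropped = self.n_dropped_level + self.n_dropped_reliability + self.n_dropped_blank
        if self.n_retained + dropped != self.n_lines:
            raise ValueError(
                f"inconsistent parse report: {self.n_retained} retained + "
                f"{dropped} dropped != {self.n_lines} lines"
            )

    @property
    def n_dropped(self) -> int:
        return self.n_lines - self.n_retained


@dataclasses.dataclass(frozen=True)
class QueryList:
    """A parsed gene-symbol query: unique, upper-cased, order-preserving."""

    raw: Union[str, Sequence[str]]
    tokens: tuple[str, ...]

    @property
    def n_unique(self) -> int:
        return len(self.tokens)


def display_label(tissue: str, cell_type: str) -> str:
    """Canonical ``"TISSUE - cell type"`` label a result row is keyed by."""
    return f"{tissue.strip().upper()} - {cell_type.strip()}"


def _load_tsv(path, colmap: dict[str, str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    lower_to_actual = {c.strip().casefold(): c for c in df.columns}
    rename = {}
    missing = []
    for label, canon in colmap.items():
        actual = lower_to_actual.get(label.casefold())
        if actual is None:
            missing.append(label)
        else:
            rename[actual] = canon
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=rename)[list(colmap.values())]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    for col in df.columns:
        df[col] = df[col].str.strip()
    return df


def read_normal_tissue(path) -> tuple[pd.DataFrame, ParseReport]:
    """Read an HPA-style normal-tissue staining TSV.

    Returns the retained records and a :class:`ParseReport`.  Rows whose
    ``Level`` or ``Reliability`` falls outside the closed vocabularies
    (e.g. ``"N/A"``), or with a blank gene name, are dropped and counted —
    real HPA releases contain such rows, so this is not an error.
    """
    df = _load_tsv(path, _NORMAL_COLUMNS)
    n_lines = len(df)

    blank = df["gene_name"] == ""
    n_blank = int(blank.sum())
    df = df[~blank]

    level = df["level"].str.casefold().map(_LEVEL_CANON)
    bad_level = level.isna()
    n_level = int(bad_level.sum())
    df = df[~bad_level].assign(level=level[~bad_level])

    rel = df["reliability"].str.casefold().map(_RELIABILITY_CANON)
    bad_rel = rel.isna()
    n_rel = int(bad_rel.sum())
    df = df[~bad_rel].assign(reliability=rel[~bad_rel])

    df = df.reset_index(drop=True)
    report = ParseReport(
        n_lines=n_lines,
        n_retained=len(df),
        n_dropped_level=n_level,
        n_dropped_reliability=n_rel,
        n_dropped_blank=n_blank,
    )
    return df, report


_INT_RE = re.compile(r"^\d+$")
_COUNT_COLS = ("n_high", "n_medium", "n_low", "n_not_detected")


def read_cancer(path) -> tuple[pd.DataFrame, ParseReport]:
    """Read an HPA-style cancer/pathology TSV with per-level patient counts.

    Rows whose four counts are all blank (or all zero) are dropped and
    reported; a non-integer count raises :class:`ParseError` naming the
    offending line (1-based, header = line 1).
    """
    df = _load_tsv(path, _CANCER_COLUMNS)
    n_lines = len(df)

    counts = df[list(_COUNT_COLS)]
    all_blank = (counts == "").all(axis=1)
    bad = counts.apply(lambda s: ~(s.str.match(_INT_RE) | (s == "")))
    if bad.to_numpy().any():
        first = int(bad.any(axis=1).idxmax())
        value = counts.loc[first][bad.loc[first]].iloc[0]
        raise ParseError(f"{path}: line {first + 2}: non-integer count {value!r}")

    df = df.copy()
    for col in _COUNT_COLS:
        df[col] = pd.to_numeric(df[col].replace("", "0")).astype(int)
    all_zero = (df[list(_COUNT_COLS)].sum(axis=1) == 0) | all_blank
    n_blank = int(all_zero.sum())
    df = df[~all_zero].reset_index(drop=True)
    report = ParseReport(n_lines=n_lines, n_retained=len(df), n_dropped_blank=n_blank)
    return df, report


def write_normal_tissue(records: pd.DataFrame, path) -> None:
    """Write records back in the exact normal-tissue TSV dialect."""
    inv = {v: k for k, v in _NORMAL_COLUMNS.items()}
    records[list(_NORMAL_COLUMNS.values())].rename(columns=inv).to_csv(
        path, sep="\t", index=False
    )


def write_cancer(records: pd.DataFrame, path) -> None:
    """Write cancer records back in the pathology TSV dialect."""
    inv = {v: k for k, v in _CANCER_COLUMNS.items()}
    records[list(_CANCER_COLUMNS.values())].rename(columns=inv).to_csv(
        path, sep="\t", index=False
    )


_SPLIT_RE = re.compile(r"[\s,]+")


def parse_query(raw: Union[str, Iterable[str]]) -> QueryList:
    """Parse a free-text gene list into a :class:`QueryList`.

    Symbols may be separated by any run of spaces, commas, tabs or
    newlines; they are upper-cased and de-duplicated preserving first
    occurrence.  Token order never affects downstream scores.
    """
    if raw is None:
        raise EmptyQueryError("query is None")
    if isinstance(raw, str):
        parts = _SPLIT_RE.split(raw)
    else:
        parts = [p for tok in raw for p in _SPLIT_RE.split(str(tok))]
    tokens = tuple(dict.fromkeys(p.upper() for p in parts if p))
    if not tokens:
        raise EmptyQueryError("query contains no gene symbols")
    return QueryList(raw=raw, tokens=tokens)


#: float columns rendered with two decimals on export
_SCORE_COLUMNS = ("staining_score", "confidence_score", "pct_stained")


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table as RFC-4180-style CSV.

    Scores are rendered with two decimal places; p-values keep full
    precision.  Re-reading with :func:`read_results` reproduces the table
    (strings exactly, scores to two decimals).
    """
    if results is None or len(results) == 0:
        raise EmptyInputError("no results to write")
    out = results.copy()
    for col in _SCORE_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    if "detected_proteins" in out.columns:
        out["detected_proteins"] = out["detected_proteins"].map(_render_detected)
    out.to_csv(path, index=False)


def _render_detected(value) -> str:
    if isinstance(value, str) or value is None:
        return value or ""
    return ";".join(f"{gene}:{level}" for gene, level in value)


def read_results(path) -> pd.DataFrame:
    """Read a CSV previously written by :func:`write_results`."""
    return pd.read_csv(path)
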