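"""Staining score, confidence score, and the ranked query result table.

The staining score of a query list in one cell type is

    score = (100*h + 50*m + 25*l) / t

where t is the number of query proteins tested in the cell type and
h/m/l count those staining High/Medium/Low.  It ranges 0-100, hitting
100 only when every tested protein stains High; high staining is
over-weighted deliberately, as strong IHC calls are the more robust
cell-type evidence.

The confidence score down-weights results backed by few proteins:

    confidence = min(p, 50) * s / 50

with p the number of query proteins matched in the dataset and s the
staining score, so confidence equals the staining score once p >= 50.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .atlas_io import QueryList, display_label, parse_query
from .enriched import (
    Stringency,
    _best_level_per_gene_key,
    build_enriched_set,
    cancer_detection_fractions,
    detection_fractions,
    filter_by_stringency,
)
from .enrichment import ContingencyTable2x2, chi_square, fisher_exact, holm_adjust
from .errors import (
    EmptyAfterFilterError,
    NoGenesMatchedError,
    TooFewProteinsError,
    UndefinedScoreError,
)

LEVEL_WEIGHTS = {"High": 100.0, "Medium": 50.0, "Low": 25.0, "Not detected": 0.0}
_RANK_TO_LEVEL = {0: "Not detected", 1: "Low", 2: "Medium", 3: "High"}


@dataclasses.dataclass(frozen=True)
class ScoreComponents:
    """Level counts of a query within one cell type: h + m + l + nd = t."""

    t: int
    h: int
    m: int
    l: int  # noqa: E741 - field name mirrors the score equation
    nd: int

    def __post_init__(self):
        if min(self.t, self.h, self.m, self.l, self.nd) < 0:
            raise ValueError("counts must be non-negative")
        if self.h + self.m + self.l + self.nd != self.t:
            raise ValueError("h + m + l + nd must equal t")


@dataclasses.dataclass
class ScoreOptions:
    """Knobs for :func:`score_query`.

    stringency
        Reliability filter applied to the enriched-protein machinery
        (fractions, enriched set, contingency universe).  Staining scores
        themselves are computed on the unfiltered table.
    test
        ``"fisher"`` (default, one-sided by default) or ``"chisq"``.
    alternative
        ``"greater"`` (enrichment, default) or ``"two-sided"``; Fisher only.
    show_proteins
        Attach the list of detected query proteins per cell type.
    compute_pvalues
        Skip the enrichment test entirely when False (used by the
        permutation study, where only scores are needed).
    confidence
        Also compute the confidence score per row.
    per_key_universe
        Contingency universe = proteins evaluated in the key (default).
        When False, the universe is every protein in the filtered dataset.
    dilute_by_unmatched
        When True, t is the number of matched query proteins dataset-wide,
        so cell types where a protein was never evaluated are diluted.
        Default False: proteins absent from a cell type do not dilute it.
    """

    stringency: Stringency = Stringency.NORMAL
    test: str = "fisher"
    alternative: str = "greater"
    show_proteins: bool = True
    compute_pvalues: bool = True
    confidence: bool = False
    per_key_universe: bool = True
    dilute_by_unmatched: bool = False


def staining_score(components: ScoreComponents) -> float:
    """Evaluate (100h + 50m + 25l)/t for one cell type."""
    if components.t == 0:
        raise UndefinedScoreError("staining score undefined for t = 0")
    return (100.0 * components.h + 50.0 * components.m + 25.0 * components.l) / components.t


def confidence_score(p: int, s: float) -> float:
    """min(p, 50) * s / 50 — the sample-size-aware score, capped at p = 50."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if not 0.0 <= s <= 100.0:
        raise ValueError("staining score must lie in [0, 100]")
    return min(p, 50) * s / 50.0


def _as_query(query: Union[QueryList, str, Sequence[str]]) -> QueryList:
    return query if isinstance(query, QueryList) else parse_query(query)


RESULT_COLUMNS = [
    "display",
    "tissue",
    "cell_type",
    "staining_score",
    "n_tested",
    "n_high",
    "n_medium",
    "n_low",
    "n_not_detected",
    "n_enriched_detected",
    "p_value",
    "p_adjusted",
]


def score_query(
    records: pd.DataFrame,
    query: Union[QueryList, str, Sequence[str]],
    options: Optional[ScoreOptions] = None,
) -> pd.DataFrame:
    """Rank all cell types against a gene-list query.

    Returns one row per (tissue, cell type) key where at least one query
    protein was evaluated, sorted by staining score (desc), then by the
    number of tested proteins (desc), then by display label (asc) so the
    output is fully deterministic.  Duplicate records of a gene within a
    key resolve to the strongest level before counting.
    """
    options = options or ScoreOptions()
    query = _as_query(query)
    tokens = set(query.tokens)

    gene_upper = records["gene_name"].str.upper()
    matched_mask = gene_upper.isin(tokens)
    matched_genes = set(gene_upper[matched_mask])
    if not matched_genes:
        raise NoGenesMatchedError(sorted(tokens))
    unmatched = sorted(tokens - matched_genes)

    best = _best_level_per_gene_key(records[matched_mask])
    counts = (
        best.assign(
            high=best["rank"] == 3,
            medium=best["rank"] == 2,
            low=best["rank"] == 1,
        )
        .groupby(["tissue_key", "cell_key"], sort=False)
        .agg(
            tissue=("tissue", "first"),
            cell_type=("cell_type", "first"),
            n_eval=("rank", "size"),
            n_high=("high", "sum"),
            n_medium=("medium", "sum"),
            n_low=("low", "sum"),
        )
        .reset_index()
    )
    if options.dilute_by_unmatched:
        counts["n_tested"] = len(matched_genes)
    else:
        counts["n_tested"] = counts["n_eval"]
    counts["n_not_detected"] = (
        counts["n_tested"] - counts["n_high"] - counts["n_medium"] - counts["n_low"]
    )
    counts["staining_score"] = (
        100.0 * counts["n_high"] + 50.0 * counts["n_medium"] + 25.0 * counts["n_low"]
    ) / counts["n_tested"]
    counts["display"] = [
        display_label(t, c) for t, c in zip(counts["tissue"], counts["cell_type"])
    ]

    if options.show_proteins:
        pos = best[best["rank"] > 0].copy()
        pos["level"] = pos["rank"].map(_RANK_TO_LEVEL)
        detected = (
            pos.sort_values(["rank", "gene"], ascending=[False, True])
            .groupby(["tissue_key", "cell_key"])[["gene", "level"]]
            .apply(lambda g: list(map(tuple, g.to_numpy())))
        )
        counts["detected_proteins"] = [
            detected.get((tk, ck), []) for tk, ck in zip(counts["tissue_key"], counts["cell_key"])
        ]

    if options.compute_pvalues:
        ptab = _pvalue_table(records, tokens, options)
        counts = counts.merge(ptab, on=["tissue_key", "cell_key"], how="left")
    else:
        counts["n_enriched_detected"] = np.nan
        counts["p_value"] = np.nan
        counts["p_adjusted"] = np.nan

    if options.confidence:
        p = len(matched_genes)
        counts["confidence_score"] = [
            confidence_score(p, s) for s in counts["staining_score"]
        ]

    counts = counts.sort_values(
        ["staining_score", "n_tested", "display"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)

    cols = list(RESULT_COLUMNS)
    if options.show_proteins:
        cols.insert(cols.index("n_enriched_detected"), "detected_proteins")
    if options.confidence:
        cols.append("confidence_score")
    out = counts[cols]
    out.attrs["unmatched_tokens"] = unmatched
    out.attrs["n_matched"] = len(matched_genes)
    return out


def _test_pvalue(a: int, b: int, c: int, d: int, options: ScoreOptions) -> float:
    tbl = ContingencyTable2x2(a, b, c, d)
    if options.test == "chisq":
        return chi_square(tbl)
    return fisher_exact(tbl, alternative=options.alternative)


def _pvalue_table(records, tokens, options: ScoreOptions) -> pd.DataFrame:
    """Per-key enrichment p-values on the stringency-filtered table."""
    empty = pd.DataFrame(
        columns=["tissue_key", "cell_key", "n_enriched_detected", "p_value", "p_adjusted"]
    )
    try:
        fractions = detection_fractions(records, options.stringency)
        enriched = build_enriched_set(fractions, options.stringency)
    except (EmptyAfterFilterError, TooFewProteinsError) as exc:
        warnings.warn(f"enrichment test skipped: {exc}", stacklevel=3)
        return empty

    filtered = filter_by_stringency(records, options.stringency)
    best = _best_level_per_gene_key(filtered)
    best["success"] = (best["rank"] > 0) & best["gene"].isin(enriched.members)
    best["in_query"] = best["gene"].isin(tokens)
    best["a_flag"] = best["success"] & best["in_query"]
    grouped = (
        best.groupby(["tissue_key", "cell_key"], sort=False)
        .agg(
            n=("gene", "size"),
            n_success=("success", "sum"),
            n_query=("in_query", "sum"),
            a=("a_flag", "sum"),
        )
        .reset_index()
    )
    if options.per_key_universe:
        n_universe = grouped["n"]
        n_query = grouped["n_query"]
    else:
        all_genes = best["gene"].nunique()
        n_universe = pd.Series(all_genes, index=grouped.index)
        n_query = pd.Series(
            len(tokens & set(best["gene"])), index=grouped.index
        )
    a = grouped["a"].astype(int)
    b = (n_query - a).astype(int)
    c = (grouped["n_success"] - a).astype(int)
    d = (n_universe - grouped["n_success"] - b).astype(int)
    pvals = np.array(
        [_test_pvalue(ai, bi, ci, di, options) for ai, bi, ci, di in zip(a, b, c, d)]
    )
    return pd.DataFrame(
        {
            "tissue_key": grouped["tissue_key"],
            "cell_key": grouped["cell_key"],
            "n_enriched_detected": a,
            "p_value": pvals,
            "p_adjusted": holm_adjust(pvals),
        }
    )


def score_query_cancer(
    cancer_records: pd.DataFrame,
    query: Union[QueryList, str, Sequence[str]],
    options: Optional[ScoreOptions] = None,
) -> pd.DataFrame:
    """Rank cancers against a gene-list query from per-patient counts.

    Patient counts become fractional level weights: a gene contributes
    n_high/N to h, n_medium/N to m, n_low/N to l, with N its total
    patient count in the cancer, preserving within-cancer staining
    heterogeneity rather than collapsing it to a modal level.  Cancer
    data has no reliability labels, so stringency is not applied.
    """
    options = options or ScoreOptions()
    query = _as_query(query)
    tokens = set(query.tokens)

    gene_upper = cancer_records["gene_name"].str.upper()
    matched_mask = gene_upper.isin(tokens)
    matched_genes = set(gene_upper[matched_mask])
    if not matched_genes:
        raise NoGenesMatchedError(sorted(tokens))

    def _pairs(df: pd.DataFrame) -> pd.DataFrame:
        """Sum duplicate (gene, cancer) rows and attach fractional weights."""
        pairs = (
            df.assign(
                gene=df["gene_name"].str.upper(),
                cancer_key=df["cancer"].str.casefold(),
            )
            .groupby(["cancer_key", "gene"], sort=False)
            .agg(
                cancer=("cancer", "first"),
                n_high=("n_high", "sum"),
                n_medium=("n_medium", "sum"),
                n_low=("n_low", "sum"),
                n_not_detected=("n_not_detected", "sum"),
            )
            .reset_index()
        )
        total = pairs[["n_high", "n_medium", "n_low", "n_not_detected"]].sum(axis=1)
        pairs = pairs[total > 0].copy()
        total = total[total > 0]
        pairs["w_high"] = pairs["n_high"] / total
        pairs["w_medium"] = pairs["n_medium"] / total
        pairs["w_low"] = pairs["n_low"] / total
        return pairs

    pairs = _pairs(cancer_records[matched_mask])
    grouped = (
        pairs.groupby("cancer_key", sort=False)
        .agg(
            cancer=("cancer", "first"),
            n_tested=("gene", "size"),
            h=("w_high", "sum"),
            m=("w_medium", "sum"),
            l=("w_low", "sum"),
        )
        .reset_index()
    )
    grouped["staining_score"] = (
        100.0 * grouped["h"] + 50.0 * grouped["m"] + 25.0 * grouped["l"]
    ) / grouped["n_tested"]
    grouped["display"] = grouped["cancer"].str.strip().str.upper()

    if options.show_proteins:
        pos = pairs[pairs[["w_high", "w_medium", "w_low"]].sum(axis=1) > 0]
        detected = (
            pos.sort_values("gene")
            .groupby("cancer_key")
            .apply(
                lambda g: [
                    (gene, f"{frac:.2f}")
                    for gene, frac in zip(
                        g["gene"], g["w_high"] + g["w_medium"] + g["w_low"]
                    )
                ],
                include_groups=False,
            )
        )
        grouped["detected_proteins"] = [
            detected.get(ck, []) for ck in grouped["cancer_key"]
        ]

    if options.compute_pvalues:
        ptab = _cancer_pvalue_table(cancer_records, tokens, options)
        grouped = grouped.merge(ptab, on="cancer_key", how="left")
    else:
        grouped["n_enriched_detected"] = np.nan
        grouped["p_value"] = np.nan
        grouped["p_adjusted"] = np.nan

    if options.confidence:
        p = len(matched_genes)
        grouped["confidence_score"] = [
            confidence_score(p, s) for s in grouped["staining_score"]
        ]

    grouped = grouped.sort_values(
        ["staining_score", "n_tested", "display"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    cols = ["display", "cancer", "staining_score", "n_tested", "h", "m", "l"]
    if options.show_proteins:
        cols.append("detected_proteins")
    cols += ["n_enriched_detected", "p_value", "p_adjusted"]
    if options.confidence:
        cols.append("confidence_score")
    out = grouped[cols].rename(columns={"h": "w_high", "m": "w_medium", "l": "w_low"})
    out.attrs["unmatched_tokens"] = sorted(tokens - matched_genes)
    out.attrs["n_matched"] = len(matched_genes)
    return out


def _cancer_pvalue_table(cancer_records, tokens, options: ScoreOptions) -> pd.DataFrame:
    empty = pd.DataFrame(
        columns=["cancer_key", "n_enriched_detected", "p_value", "p_adjusted"]
    )
    try:
        fractions = cancer_detection_fractions(cancer_records)
        enriched = build_enriched_set(fractions, Stringency.LOW)
    except (EmptyAfterFilterError, TooFewProteinsError) as exc:
        warnings.warn(f"enrichment test skipped: {exc}", stacklevel=3)
        return empty

    df = pd.DataFrame(
        {
            "gene": cancer_records["gene_name"].str.upper(),
            "cancer_key": cancer_records["cancer"].str.casefold(),
            "positive": (
                cancer_records[["n_high", "n_medium", "n_low"]].sum(axis=1) > 0
            ),
            "evaluated": (
                cancer_records[
                    ["n_high", "n_medium", "n_low", "n_not_detected"]
                ].sum(axis=1)
                > 0
            ),
        }
    )
    df = df[df["evaluated"]]
    pair = df.groupby(["cancer_key", "gene"], sort=False)["positive"].any().reset_index()
    pair["success"] = pair["positive"] & pair["gene"].isin(enriched.members)
    pair["in_query"] = pair["gene"].isin(tokens)
    pair["a_flag"] = pair["success"] & pair["in_query"]
    grouped = (
        pair.groupby("cancer_key", sort=False)
        .agg(
            n=("gene", "size"),
            n_success=("success", "sum"),
            n_query=("in_query", "sum"),
            a=("a_flag", "sum"),
        )
        .reset_index()
    )
    a = grouped["a"].astype(int)
    b = (grouped["n_query"] - a).astype(int)
    c = (grouped["n_success"] - a).astype(int)
    d = (grouped["n"] - grouped["n_success"] - b).astype(int)
    pvals = np.array(
        [_test_pvalue(ai, bi, ci, di, options) for ai, bi, ci, di in zip(a, b, c, d)]
    )
    return pd.DataFrame(
        {
            "cancer_key": grouped["cancer_key"],
            "n_enriched_detected": a,
            "p_value": pvals,
            "p_adjusted": holm_adjust(pvals),
        }
    )
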