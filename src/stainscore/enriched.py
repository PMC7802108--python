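"""Stringency filtering and enriched (rare) protein sets.

A protein's *detection fraction* is the share of (tissue, cell type) keys
where it stains positive (Low/Medium/High) among the keys where it was
evaluated at all.  The *enriched set* at a given stringency is the set of
proteins whose fraction falls at or below the first quartile of the
observed fraction distribution — rarely-detected proteins, which carry the
cell-type-specificity signal the enrichment test looks for.  Proteins that
never stain positive anywhere are excluded from the distribution.

Stringency controls which antibody-evidence (``Reliability``) labels are
admitted before fractions are computed:

========  ========================================
low       Enhanced, Supported, Approved, Uncertain
normal    Enhanced, Supported, Approved
high      Enhanced, Supported
========  ========================================
"""

from __future__ import annotations

import dataclasses
import enum
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyAfterFilterError, TooFewProteinsError

_LEVEL_RANK = {"Not detected": 0, "Low": 1, "Medium": 2, "High": 3}


class Stringency(enum.Enum):
    """Data-quality stringency: which reliability labels are admitted."""

    LOW = ("Enhanced", "Supported", "Approved", "Uncertain")
    NORMAL = ("Enhanced", "Supported", "Approved")
    HIGH = ("Enhanced", "Supported")

    @property
    def admitted_reliabilities(self) -> frozenset:
        return frozenset(self.value)

    @classmethod
    def from_name(cls, name: str) -> "Stringency":
        return cls[str(name).strip().upper()]


@dataclasses.dataclass(frozen=True)
class EnrichedSet:
    """The stringency-specific rare-protein set.

    ``threshold`` is the 25th percentile (linear interpolation between
    order statistics) of the detection-fraction distribution; ``members``
    are the proteins with fraction <= threshold (boundary inclusive).
    """

    stringency: Stringency
    fractions: Mapping[str, float]
    threshold: float
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "fractions", MappingProxyType(dict(self.fractions)))


def filter_by_stringency(records: pd.DataFrame, stringency: Stringency) -> pd.DataFrame:
    """Keep records whose reliability is admitted at this stringency."""
    return records[records["reliability"].isin(stringency.admitted_reliabilities)]


def _best_level_per_gene_key(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (gene symbol, tissue, cell type) with the best level.

    Duplicate records (multiple antibodies/samples) resolve to the single
    strongest call — High > Medium > Low > Not detected — so no gene is
    double-counted within a key.  Gene symbols are upper-cased and key
    fields compared case-insensitively; first-seen spellings are kept for
    display.
    """
    df = pd.DataFrame(
        {
            "gene": records["gene_name"].str.upper(),
            "tissue": records["tissue"],
            "cell_type": records["cell_type"],
            "tissue_key": records["tissue"].str.casefold(),
            "cell_key": records["cell_type"].str.casefold(),
            "rank": records["level"].map(_LEVEL_RANK),
        }
    )
    return (
        df.groupby(["tissue_key", "cell_key", "gene"], sort=False)
        .agg(rank=("rank", "max"), tissue=("tissue", "first"), cell_type=("cell_type", "first"))
        .reset_index()
    )


def detection_fractions(records: pd.DataFrame, stringency: Stringency) -> pd.Series:
    """Per-protein detection fraction across cell-type keys.

    fraction = (# keys where the protein stains positive) /
    (# keys where it was evaluated), computed on stringency-admitted
    records with best-level-wins deduplication.  Proteins that never stain
    positive are omitted.
    """
    filtered = filter_by_stringency(records, stringency)
    if len(filtered) == 0:
        raise EmptyAfterFilterError(
            f"no records admitted at stringency {stringency.name.lower()}"
        )
    best = _best_level_per_gene_key(filtered)
    grouped = best.groupby("gene", sort=True)["rank"]
    n_eval = grouped.size()
    n_pos = grouped.agg(lambda r: int((r > 0).sum()))
    fractions = (n_pos / n_eval)[n_pos > 0]
    fractions.name = "detection_fraction"
    return fractions


def build_enriched_set(fractions, stringency: Stringency) -> EnrichedSet:
    """Derive the rare-protein set from a fraction distribution.

    Requires at least four proteins so the first quartile is meaningful.
    """
    fractions = dict(pd.Series(fractions).items())
    if len(fractions) < 4:
        raise TooFewProteinsError(
            f"need >= 4 proteins to define a quartile, got {len(fractions)}"
        )
    values = np.fromiter(fractions.values(), dtype=float)
    threshold = float(np.percentile(values, 25))
    members = frozenset(g for g, f in fractions.items() if f <= threshold)
    return EnrichedSet(
        stringency=stringency, fractions=fractions, threshold=threshold, members=members
    )


def enriched_set(records: pd.DataFrame, stringency: Stringency) -> EnrichedSet:
    """Convenience: fractions + set in one step from raw records."""
    return build_enriched_set(detection_fractions(records, stringency), stringency)


def cancer_detection_fractions(cancer_records: pd.DataFrame) -> pd.Series:
    """Detection fractions over cancers for the pathology table.

    "Positive" for a (gene, cancer) pair means any patient stained at
    High/Medium/Low.  Cancer data carries no reliability labels, so no
    stringency filter applies.
    """
    if len(cancer_records) == 0:
        raise EmptyAfterFilterError("no cancer records")
    df = pd.DataFrame(
        {
            "gene": cancer_records["gene_name"].str.upper(),
            "cancer": cancer_records["cancer"].str.casefold(),
            "positive": (
                cancer_records[["n_high", "n_medium", "n_low"]].sum(axis=1) > 0
            ),
        }
    )
    pair = df.groupby(["gene", "cancer"], sort=True)["positive"].any().reset_index()
    grouped = pair.groupby("gene", sort=True)["positive"]
    fractions = (grouped.sum() / grouped.size())[grouped.sum() > 0].astype(float)
    fractions.name = "detection_fraction"
    return fractions
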