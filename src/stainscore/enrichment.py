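"""Per-cell-type enrichment testing of rare proteins in a query.

For each cell-type key a 2x2 table splits the proteins evaluated in that
key by (in query?) x (enriched-and-detected?), where "enriched-and-
detected" means the protein belongs to the rare-protein set *and* stains
positive in this key.  A one-sided Fisher's exact test (default) or a
Pearson chi-squared test asks whether the query over-represents such
proteins; p-values are Holm-adjusted across all cell types of one run.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enriched import EnrichedSet, Stringency, _best_level_per_gene_key, filter_by_stringency


class LowExpectedCountWarning(UserWarning):
    """Chi-squared approximation invalid: an expected cell count is below 1."""


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one cell-type key.

    a: query proteins that are enriched-and-detected in the key;
    b: query proteins that are not; c/d: same split for background
    proteins.  Rows sum to the query/background proteins evaluated in
    the key.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def build_table(
    key: tuple[str, str],
    records: pd.DataFrame,
    query_tokens: Sequence[str],
    enriched: EnrichedSet,
    stringency: Stringency | None = None,
) -> ContingencyTable2x2:
    """Build the 2x2 table for one (tissue, cell type) key.

    The universe is the set of proteins evaluated in the key after
    stringency filtering (defaults to the enriched set's stringency);
    query proteins not evaluated in the key contribute to no cell.
    """
    stringency = stringency or enriched.stringency
    filtered = filter_by_stringency(records, stringency)
    best = _best_level_per_gene_key(filtered)
    tissue, cell_type = key
    sub = best[
        (best["tissue_key"] == tissue.casefold())
        & (best["cell_key"] == cell_type.casefold())
    ]
    tokens = {t.upper() for t in query_tokens}
    success = (sub["rank"] > 0) & sub["gene"].isin(enriched.members)
    in_query = sub["gene"].isin(tokens)
    a = int((success & in_query).sum())
    b = int((~success & in_query).sum())
    c = int((success & ~in_query).sum())
    d = int((~success & ~in_query).sum())
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_greater(tbl: ContingencyTable2x2) -> float:
    """One-sided (enrichment) Fisher exact p: hypergeometric tail P(X >= a)."""
    return float(stats.fisher_exact(tbl.as_array(), alternative="greater")[1])


def fisher_exact(tbl: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Fisher exact p-value with a selectable alternative."""
    return float(stats.fisher_exact(tbl.as_array(), alternative=alternative)[1])


def chi_square(tbl: ContingencyTable2x2) -> float:
    """Pearson chi-squared p (1 df, continuity-corrected).

    Returns 1.0 with a :class:`LowExpectedCountWarning` when any expected
    count is below 1 (including degenerate margins), where the chi-squared
    approximation is meaningless.
    """
    arr = tbl.as_array()
    n = arr.sum()
    if n == 0:
        warnings.warn("empty table", LowExpectedCountWarning, stacklevel=2)
        return 1.0
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    if (expected < 1).any():
        warnings.warn(
            "expected cell count below 1; chi-squared approximation invalid",
            LowExpectedCountWarning,
            stacklevel=2,
        )
        return 1.0
    _, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return float(p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    NaN entries (cell types where no test was possible) are passed
    through untouched and do not count toward the family size.
    """
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr.copy()
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="holm")[1]
    return out
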