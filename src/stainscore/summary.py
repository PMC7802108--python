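"""Atlas-wide summary: proteins evaluated vs positively stained per cell type."""

from __future__ import annotations

import pandas as pd

from .atlas_io import display_label
from .enriched import _best_level_per_gene_key
from .errors import EmptyInputError


def summarize_atlas(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (tissue, cell type) key with evaluation and staining depth.

    ``n_evaluated`` counts distinct proteins with any record in the key,
    ``n_stained`` those whose best level is Low/Medium/High, and
    ``pct_stained`` their ratio on a 0-100 scale.  No stringency filter is
    applied: the summary describes the raw table.  Duplicate records of a
    protein within a key are counted once (best level wins).
    """
    if records is None or len(records) == 0:
        raise EmptyInputError("cannot summarize an empty atlas")
    best = _best_level_per_gene_key(records)
    out = (
        best.assign(stained=best["rank"] > 0)
        .groupby(["tissue_key", "cell_key"], sort=False)
        .agg(
            tissue=("tissue", "first"),
            cell_type=("cell_type", "first"),
            n_evaluated=("gene", "size"),
            n_stained=("stained", "sum"),
        )
        .reset_index(drop=True)
    )
    out["pct_stained"] = 100.0 * out["n_stained"] / out["n_evaluated"]
    out["display"] = [
        display_label(t, c) for t, c in zip(out["tissue"], out["cell_type"])
    ]
    out = out[
        ["display", "tissue", "cell_type", "n_evaluated", "n_stained", "pct_stained"]
    ]
    return out.sort_values(
        ["pct_stained", "display"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
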