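"""Rank cell types for a gene-list query on the worked-example fixture.

The four-gene query (three pancreatic enzymes plus prolactin) should put
pancreatic exocrine glandular cells first with a staining score of 75:
three of the four tested proteins stain High there (3*100/4), prolactin
does not stain.  The pituitary scores 25 (one High of four) and the
small-intestine glandular cells 12.5 (one Medium of four).
"""

import stainscore as ss

records = ss.worked_example_fixture()
results = ss.score_query(
    records, "PRSS1, PNLIP, CELA3A, PRL", ss.ScoreOptions(confidence=True)
)
cols = ["display", "staining_score", "n_tested", "n_high", "n_medium",
        "p_value", "p_adjusted", "confidence_score"]
print(results[cols].head(5).to_string(index=False))
print(
    "\nstaining_score is (100h + 50m + 25l)/t per cell type; confidence_score "
    "down-weights it by min(p,50)/50 with p = 4 matched query proteins."
)
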