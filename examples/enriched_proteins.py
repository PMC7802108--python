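"""Derive the rare ("enriched") protein set at each stringency.

A protein is rare when its detection fraction — positive cell types over
evaluated cell types — sits at or below the first quartile of that
distribution.  Stringency controls which reliability labels enter the
computation, so the admitted record sets nest: high within normal within
low.
"""

import stainscore as ss

atlas = ss.generate_atlas(ss.heterogeneous_atlas_spec(seed=7))
for level in (ss.Stringency.LOW, ss.Stringency.NORMAL, ss.Stringency.HIGH):
    es = ss.enriched_set(atlas, level)
    print(
        f"{level.name.lower():>6}: {len(es.fractions)} proteins with a positive "
        f"stain, Q1 threshold = {es.threshold:.3f}, rare set = {len(es.members)}"
    )
print("\nThe rare set feeds the per-cell-type Fisher test: does a query "
      "over-represent rare proteins detected in that cell type?")
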