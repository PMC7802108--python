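# Methods

## Input model

A normal-tissue staining table has one record per (gene, tissue, cell
type) with a categorical staining call `Level ∈ {High, Medium, Low, Not
detected}` and an antibody-evidence label `Reliability ∈ {Enhanced,
Supported, Approved, Uncertain}`. Parsing is loss-counting: records with
a level or reliability outside those closed vocabularies (real releases
contain e.g. `"N/A"`), or a blank gene symbol, are dropped and tallied in
a `ParseReport` rather than raising — a pipeline can assert
`retained + dropped == total` on any input. Gene matching is by
upper-cased symbol (`Gene name`), because user queries are symbols; a
symbol mapping to several stable ids keeps all its records. Tissue and
cell-type comparisons are case-insensitive; the display key is
`"TISSUE - cell type"`.

Wherever one gene has several records in one key (multiple antibodies or
samples), the single strongest call wins (High > Medium > Low > Not
detected). This makes every score invariant to record duplication.

## Staining score

For a query list and one cell-type key, with t query proteins tested in
the key and h/m/l of them High/Medium/Low:

    score = (100·h + 50·m + 25·l) / t ∈ [0, 100]

Not-detected proteins count toward t (they dilute) but contribute no
weight; score = 100 iff every tested protein is High, 0 iff none is
positive. By default t counts only proteins *evaluated in that key* —
a protein never assayed in a cell type does not dilute that cell type.
The alternative reading (t = all matched query proteins, so missing
evaluations dilute) is available as `ScoreOptions(dilute_by_unmatched=
True)`; the two agree whenever every matched protein is evaluated
everywhere, as in the worked example. Ranking ties break by larger t,
then lexicographic display label, so output ordering is fully
deterministic. Scores are kept at full float precision and rendered to
two decimals only in CSV export.

## Confidence score

    confidence = min(p, 50) · s / 50

with s the staining score and p the number of query proteins matched in
the dataset (dataset-wide, not per key — the published spot checks fix
this reading: a 5-marker query with top score 57.75 yields 5.775).
Confidence ≤ score always, with equality once p ≥ 50 (the cap) or s = 0.
It exists to rank results across queries of very different sizes, where
a perfect score from one protein should not outrank a good score from
forty.

## Enriched (rare) proteins and the per-cell-type test

A protein's detection fraction is (# keys where its best level is
positive) / (# keys where it is evaluated); proteins that never stain
positive anywhere are excluded from the distribution. The rare set at a
given stringency is every protein with fraction ≤ Q1 of the observed
distribution, where Q1 is the 25th percentile with linear interpolation
between order statistics and the boundary is inclusive — both stated so
results are bit-reproducible. A distribution-relative cutoff (rather
than a fixed 0.25 fraction) is used deliberately: it adapts to how
saturated a given atlas release is. At least four proteins are required;
below that the quartile is refused (`TooFewProteinsError`) and, inside
`score_query`, the test is skipped with a warning and NaN p-values
rather than failing the whole query.

Stringency admits reliability labels — low: all four; normal (default):
Enhanced/Supported/Approved; high: Enhanced/Supported — and applies to
the enriched-set machinery and the contingency universe only. Staining
scores are computed on the unfiltered table: the score describes what
the pathologists saw; the stringency filter governs the evidence used
for the rarity claim.

Per cell type, a 2×2 table splits the proteins evaluated in that key
(post-stringency) by membership in the query versus "success" =
rare-set member *and* positively stained in that key. Query proteins
not evaluated in the key contribute to no cell. The universe choice
(per-key, the default, vs all proteins in the filtered dataset) is
exposed as `ScoreOptions(per_key_universe=False)` since the construction
is not uniquely determined by its verbal description. The default test
is the one-sided (greater) Fisher exact test — the direction matches the
enrichment claim; two-sided and Pearson χ² (with continuity correction,
returning p = 1 with a warning when any expected count is < 1) are
options. P-values are Holm step-down adjusted across all cell types of
one query run; NaN entries pass through without inflating the family
size. Fisher/χ²/Holm are computed by scipy and statsmodels; the test
suite checks them against independent oracles (exact integer-binomial
hypergeometric tails enumerated for every 2×2 table with total ≤ 40, a
closed-form Yates statistic, and a hand-stepped Holm procedure).

## Cancer mode

Pathology tables give per-(gene, cancer) patient counts at each level.
Rather than collapsing to a modal level, counts become fractional
weights — h += n_high/N etc., N the pair's patient total — preserving
within-cancer staining heterogeneity; t is the number of matched genes
with any patient in that cancer. Cancer data carries no reliability
column, so no stringency filter applies; "positive" for the rarity
computation means any High/Medium/Low patient.

## Permutation null

`run_permutations` samples gene lists uniformly without replacement from
the sorted distinct symbols of the atlas (optionally from the
stringency-filtered table), scores each list, and records the top-k
scores and the full score vector per run. The seed is split with
`SeedSequence.spawn` per (size, run), so results are reproducible and
adding sizes or runs never perturbs earlier ones. The full profile is
1000 runs at sizes 10/25/50/100 with top-k = 10; the acceptance suite
runs 500 per size and unit tests far fewer, purely to keep the default
suite fast. `summarize_null` reports moments and quantiles; skewness is
the Fisher–Pearson coefficient, defined as 0 for constant samples.

## Synthetic atlas

The generator emits tables in the exact TSV dialect of the readers
(lossless round trip) and emulates two structural features of real
staining atlases: a bimodal evaluation depth — a minority of cell types
scored for nearly every protein, a long tail scored for very few — and a
coupling between scoring depth and detection, with seldom-scored cell
types modelled as both sparsely evaluated and sparsely positive. The
default heterogeneous spec: 45 tissues × 3 cell types (135 keys), 1000
genes; a well-scored class (26% of keys, coverage 0.95, mean level
distribution 0.12/0.18/0.20/0.50 over High/Medium/Low/Not detected) and
a seldom-scored class (74%, coverage 0.02, levels 0.01/0.03/0.06/0.90);
each cell type draws its own level distribution from a Dirichlet around
its class mean (concentration 150); reliabilities 0.25/0.35/0.30/0.10.
Reliability is drawn independently of level, which real data need not
obey.

This coverage/staining coupling is what makes the null mean decrease
with list size: the per-key score is linear in gene contributions, so
under uniform sampling its expectation is size-invariant — the all-
results mean can only fall through *selection*, i.e. which keys reach
t ≥ 1. Seldom-scored, weakly staining keys enter the table more often as
the list grows, pulling the mean down. A uniform single-class spec is
provided for tests needing i.i.d. structure, and `MarkerBlock`s force
chosen (gene set, key, level) assignments verbatim for planted-signal
tests.

What passing tests on synthetic atlases do **not** show: the generator
has no biological co-expression, no real gene symbols, no antibody-level
error structure, and no correlation between reliability and staining;
conclusions about real atlas releases (set sizes, descriptive
distributions) require the real downloads, which nothing here depends
on.

## Numerical and degenerate-input choices

Quartiles via `numpy.percentile` (linear interpolation); Holm via
statsmodels with NaN passthrough; empty queries, empty files, missing
columns, non-integer counts, t = 0 scores, oversized permutation list
sizes and unknown marker-block keys each raise a typed error mapped to a
distinct CLI exit code. CSV export uses `.` decimals and comma
delimiters regardless of locale; scores are formatted to two decimals at
the I/O boundary only.

## Known limitations

- The worked-example fixture fills unstated cells with Not detected —
  the only completion consistent with all three published scores — so
  its Fisher p-values are uninformative (its background universe is only
  the four query genes).
- Detection fractions are computed over (tissue, cell type) pairs; an
  atlas that intends fractions over cell types pooled across tissues
  would need a pre-aggregation step.
- No antibody/image-level data, no XML API client, no reconciliation of
  column dialects across atlas releases: the parser targets the schema
  above and surfaces schema errors instead of guessing.
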