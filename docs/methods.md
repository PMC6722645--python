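# Methods

## Problem and scope

Knocking down a long non-coding RNA (lncRNA) and re-sequencing the
transcriptome changes which exons and introns are included in mature
mRNAs.  Tools such as rMATS summarize each knockdown-vs-control comparison
into per-event-type tables (skipped exon SE, retained intron RI,
alternative 5′/3′ splice sites, mutually exclusive exons), each row
carrying the event's six defining coordinates, a p-value, an FDR and an
inclusion-level difference.  This package starts *downstream* of rMATS: it
consumes those tables (and eCLIP-style RBP peak intervals) and asks three
questions — which genes are alternatively spliced under which knockdowns
and how cell-type-specific that is; which RNA-binding proteins (RBPs) bind
near the affected splice junctions more often than expected; and which
lncRNAs behave like broad "RBP sponges", i.e. their loss is associated
with enriched binding across many RBPs at once.  Alignment, rMATS's own
statistical model, and real GEO/ENCODE downloads are out of scope.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention).  rMATS
`*_0base` start columns are taken verbatim and end columns treated as
exclusive, so interval arithmetic needs no conversion anywhere.  The rMATS
dialect is pinned to the v3.2.5 column names; a column-mapping argument
accommodates other dialects, and both count flavors of the tables
(junction-count-only and reads-on-target) are accepted, with the flavor
logged.  Chromosome names pass through untouched; a strict mode rejects
mixed `chr1`/`1` inputs rather than silently harmonizing them.  For
A5SS/A3SS the variable ("long") exon maps to the target region and the
short/flanking exons to the upstream/downstream roles; for MXE the first
alternative exon is the target.  Because those mappings are a convention
rather than a published rule, proximal-region extraction enables only SE
and RI by default and the other three sit behind an explicit opt-in.

## Significance filter and frequency matrices

An event is significant when `fdr < fdr_max` AND `pvalue < pvalue_max`,
with strict inequalities; defaults are 0.1 and 0.05.  Filtering is
idempotent and monotone in both thresholds.  Events are deduplicated on
(type, chromosome, strand, six coordinates) — first occurrence wins, so a
recurring event's statistics come from the first comparison reporting it.
The frequency matrix counts unique significant events per gene symbol
(gene id as fallback) per knockdown; all-zero gene rows are dropped.  The
specificity summary reports per-cell-line gene sets, pairwise and
higher-order Venn intersection counts, and the fraction of matrix genes
spliced in ≥ 2 cell lines (numerator and denominator are also reported
separately, so alternative denominators can be derived).

## Proximal regions

Each event contributes six regions, one per junction coordinate c:
`[max(0, c − w), c + w)` with `w = 500` bp by default.  Windows are
symmetric and strand-agnostic.  Nearby anchors can produce overlapping
windows; these are deliberately *not* merged, because the downstream
contingency counting is per region and merging would silently change its
denominators.  Clipping happens only at coordinate 0 (chromosome lengths
are not an input).

## Interval engine

Region × peak overlap uses a per-chromosome sort-and-sweep: both sides
sorted by start, a pointer admits peaks whose start precedes the current
region's end, and peaks ending at or before the current region's start are
retired (safe because regions are processed in start order).  Semantics
match `bedtools intersect`: half-open abutment is not an overlap, minimum
overlap defaults to 1 bp, and an optional stranded mode requires equal
strands.  Cell-line pairing is structural: regions are only tested against
peaks of their own cell line, and a cell line without peaks produces no
flag table at all (the U87 situation).  An RBP with no peaks in a cell
line has no column — distinguishable from an all-false column.  The
engine's correctness contract is exact set-equivalence with an all-pairs
brute-force oracle on random fixtures, which the test suite enforces.

## Enrichment model

For each (cell line, lncRNA, RBP), the 2×2 table counts the lncRNA's
proximal regions bound (x) and unbound (y) by that RBP versus the bound
(a) and unbound (b) regions of all other lncRNAs in the same cell line —
the only margin-consistent reading of the bound/unbound design, with
x + y + a + b equal to the cell line's total region count for every test.
The p-value is the exact hypergeometric tail conditional on the margins,
computed with log-gamma (log-factorial) arithmetic; the default
alternative is one-sided "greater" (binding over-representation), with
two-sided and "less" exposed.  The implementation is validated against
exhaustive PMF enumeration for all tables with margins ≤ 30 (≈ 2×10⁵
tables, agreement within 1e−12) and against an independent library
implementation on random tables.  The odds ratio is xb/ya, infinite when
ya = 0 with xb > 0 and undefined (NaN) when both vanish.

P-values are pooled within each cell line (matching the per-cell-line
heatmap panels) and adjusted with Benjamini–Hochberg by default
(Bonferroni and Benjamini–Yekutieli are config options); adjustment is
delegated to statsmodels, with the textbook step-up formula as the
independent test oracle.  A region-level counting unit is the default; a
per-gene mode first collapses each (lncRNA, gene) to a single unit that is
bound if any of its regions is.

**Null-row contract.**  An RBP bound in 100% of a cell line's regions has
no unbound margin anywhere, so no informative contrast exists for any
lncRNA; all of its cells are NULL — not zero, and excluded from the number
of adjusted tests.  NULL serializes as `NA` and renders grey.  The same
convention covers tests that were never performed.

## Sponge breadth and clustering

The sponge score is this package's operationalization (the model itself is
qualitative): breadth = n_rbps_significant / n_rbps_tested at adjusted
p < α (default 0.05), with NULL cells excluded from both numerator and
denominator; profiles are ranked within each cell line by breadth, ties
broken by significant count then name, and an all-NULL lncRNA gets a
flagged, undefined profile ranked last.  Breadth uses adjusted, not raw,
p-values, consistent with the −log₁₀(adjusted p) heatmap cells.

Matrices are clustered with distance d(u, v) = 1 − Spearman rank
correlation and average linkage (the linkage is a config key; the
published workflow's heatmap tool does not state its default).  Ranks use
midrank ties; a zero-variance vector has undefined rank correlation and is
assigned the maximum distance 2.0 with a warning.  Rows/columns are
pre-sorted by label before clustering so tied merges resolve
deterministically; leaf orders and a Newick rendering of each dendrogram
are returned.  For heatmaps containing NULLs, NaNs are treated as 0 for
distance computation only.

The binding-vs-splicing correlation compares, per cell line, each
knockdown's total significant SE event count with its significant-RBP
count, reporting Spearman and Pearson coefficients with p-values and n.
n < 3 yields an explicit `insufficient_data` status and constant input a
`degenerate` status rather than a coefficient.

## Gene-set over-representation

A generic hypergeometric upper-tail test replaces the original workflow's
interactive annotation tool: for a query gene set against each GMT term
(intersected with the universe), p = P(overlap ≥ k), BH-adjusted across
terms, filtered at raw p < 0.05 by default.  The universe defaults to the
genes observed in the analysis, not the genome — conservative and
download-free.  Ontology hierarchies, term grouping and bundled databases
are out of scope.

## Synthetic data: what it emulates, and what it does not

The generator emulates rMATS *output* and eCLIP *peaks*, not reads: the
analysis under test begins downstream of rMATS, so simulating alignment
would add cost without exercising any additional code path.  Defaults
mirror the emulated study's shape: 3 cell lines × 13 knockdowns
(39 comparisons), SE and RI tables with 100 events per comparison, 40%
planted significant (p ~ U(0, p_max/2), fdr ~ U(0, fdr_max/2); the rest
planted clearly above both thresholds), ~7% of AS genes assigned to two
cell lines, 20 RBPs, eCLIP peaks in two of the three cell lines (the third
exercises the no-eCLIP path), and one designated sponge lncRNA per eCLIP
cell line whose windows are bound at density 0.8 per RBP versus 0.1 for
the background.  Geometry makes bookkeeping exact: every event occupies a
private genomic slot whose six anchors sit more than two windows apart, so
proximal windows are pairwise disjoint and unclipped, and each planted
peak lies strictly inside exactly one window — a window is bound iff a
peak was planted there.  `verify_ground_truth` re-reads everything from
disk and re-derives the planted facts through the pipeline's own readers.

Consequently the synthetic data do **not** reproduce several features of
real data: overlapping windows from adjacent anchors of the same event,
events recurring across comparisons (deduplication is exercised by
dedicated unit fixtures instead), peaks straddling window boundaries,
correlated binding across RBPs, or variation in per-comparison significant
counts (which makes the SE-count correlation degenerate on defaults — the
correct, explicitly reported behavior).  Passing tests therefore
demonstrate the pipeline's correctness on its contracts, not biological
effect sizes.

## Numerical and calibration notes

Exact conditional tests are discrete and conservative: under a uniform
binding density the attained rate of raw p < 0.05 sits slightly below
0.05.  The calibration check therefore uses problem sizes with wide
hypergeometric support (≈ 190 focal regions per lncRNA at density 0.5) so
the attained level is close to nominal, and evaluates the pooled rate over
10 seeds against a three-binomial-SE band.  Sub-seeds for replicate
simulations are derived deterministically from a single user seed and kept
below 2³¹.  Problem sizes in the test suite and acceptance script (e.g.
25 recovery seeds at 10 events per comparison, calibration at 40) were
chosen as the smallest scales at which the planted contrasts are
statistically unambiguous.

## Known limitations

* Only SE and RI events flow through the proximal/enrichment stages by
  default; A5SS/A3SS/MXE mappings are provided but opt-in.
* rMATS FDR values are trusted as given; no cross-comparison recomputation.
* Peak strength (score column) is carried but not used as a weight.
* The breadth score treats RBPs as exchangeable; no RBP-specific binding
  propensity model is fit.
* Chromosome ends are not known to the region extractor, so windows are
  clipped only at zero.
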