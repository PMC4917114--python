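# Methods

This note documents the models and numerical choices behind `coexseed`,
module by module, in the order the pipeline runs them.

## Synthetic studies: the latent-factor module model

The generator emulates a small multi-platform SMA expression compendium:
2–3 platforms measuring the same genes, two severity contrasts (type I
SMA vs control on the merged platforms; type I vs type III on a separate
one), planted co-expression modules, duplicate probes and unannotated
probes.

Each module *m* has a per-sample latent factor
`f_m ~ N(severity · e_m, 1)`, with severity coded 1 for type I SMA and 0
for control/type III samples (this fixes the sign convention of
module–trait correlations). A member gene is

    x = baseline + λ f_m + ε,   ε ~ N(0, σ²),   λ = σ √(ρ / (1 − ρ)),

so the pairwise within-module correlation equals `ρ = within_module_cor`
exactly in expectation when `e_m = 0`. A nonzero trait effect adds
between-group factor variance `e²/4` (balanced groups), raising the
pooled within-module correlation to `λ²(1+e²/4) / (λ²(1+e²/4)+σ²)` —
trait modules are tighter than null modules, which is precisely why they
survive the stringent membership thresholds downstream.

Platform distortions are strictly monotone maps (identity, affine,
centered cubic), chosen so that rank-based cross-platform normalization
can undo them exactly in the no-ties limit. Duplicate probes re-measure
their gene's profile with a small probe noise (sd 0.05 log2 units);
unannotated probes lack an entrez id and are dropped by the annotation
filter, with the surviving gene list recorded in the truth sidecar.

Default study conditions (3 platforms, 10 samples/group, 300 genes,
modules of 50/40/30, ρ = 0.7, σ = 0.5, 10% duplicates, 5% unannotated)
are of the order of a small public-compendium re-analysis. The
*benchmark* bundle used for end-to-end recovery is larger — 25
samples/group, 400 genes, ρ = 0.8, trait effects ±2 — because the
published membership threshold `P < 10⁻¹³` is only attainable when the
pooled degrees of freedom support it: a single-platform contrast with
n = 50 samples (df = 48) needs a membership correlation of about 0.81,
which tight trait modules reach; at n ≈ 18 (df = 16) the same threshold
would require r > 0.97 and essentially nothing could ever be assigned.
The benchmark sizes are therefore a deliberate choice of regime in which
the method's own thresholds are meaningful.

What the generator does **not** emulate: probe-level (CEL) data, scanner
artifacts, batch effects beyond monotone distortions, heavy-tailed
expression noise, correlated background genes, and annotation bias.
Passing the planted-truth benchmarks therefore demonstrates internal
correctness of the pipeline under its own model assumptions, not
performance on real arrays.

The benchmark bundle wires the planted target genes as interaction-network
hubs (degree 30 vs background ≤ ~5) with two degree-1 leaf neighbours
each — making every planted hub an articulation point, i.e. a "critical
connection" by construction — and guarantees trait-module genes an
ontology annotation (`must_cover`), so the annotation-filter stage
exercises counting rather than silently deleting the planted signal.

## Preprocessing

`quantile_normalize` maps every column onto the row-wise mean of the
column-sorted matrix; ties receive the mean of the reference values at
their occupied positions; a single-sample matrix is returned unchanged
with a warning. The transform is idempotent.

`median_rank_transform` (median rank scores, MRS) restricts the datasets
to shared genes, forms the reference vector of per-rank medians of the
reference platform's column-sorted values, and replaces **every**
sample's rank-*r* value with the reference vector's *r*-th entry — the
reference platform's own samples included. Mapping all samples (rather
than passing the reference platform through untouched) makes the output
exactly rank-equivalent across platforms: all sorted sample vectors are
identical, and any strictly monotone platform distortion is removed
exactly when there are no ties. Rank ties are broken by the stable order
of row ids, making the transform deterministic. The reference defaults
to the platform with the most samples.

Duplicate probes are collapsed by the arithmetic mean per gene symbol.
Fold-change DEG selection uses `FC = 2^(Δ mean)` on log2 data with the
±1.2 rule; the filter is applied after cross-platform merging (the
natural place once a single merged matrix exists), and can be bypassed
for small targeted arrays where every gene is carried forward.

## Network construction and tree cutting

The network is unsigned: `a_ij = |r_ij|^β`, β = 6. The unsigned TOM is
computed vectorized (`L = A·A` with a zeroed diagonal excludes the
endpoint terms automatically) and clipped to [0, 1]; genes are clustered
by average linkage on `1 − TOM`.

Module extraction cuts the dendrogram at a single height and discards
clusters below `min_module_size = 20`. The cut height is chosen
adaptively at the midpoint of the largest gap between sorted merge
heights, considering only gaps whose upper edge lies in the top half of
the height range: within-module merges populate the low heights,
background and between-module merges concentrate near `1 − TOM ≈ 1`, and
the widest high gap separates the two regimes. Gaps among the earliest
merges are sampling noise and are ignored. A fixed numeric `cut_height`
override is exposed for manual control. Degenerate input (all
dissimilarities equal) yields a single cluster, never a spurious split.
Surviving clusters are labelled 1..K by decreasing size with
lexicographic tie-breaks, so labels are invariant to gene input order.

## Module membership and the meta P

The default MM statistic correlates a gene with the `top_n = 5` genes of
highest within-module connectivity kin (excluding the scored gene
itself — "another five"); with `top_n → module size − 1` it converges to
the gene's mean correlation with the whole module. The exact
gene–eigengene correlation is available via `mode="eigengene"`; the
eigengene is the first principal component of the standardized module
submatrix, sign-oriented so its mean correlation with the module's genes
is non-negative.

Per-dataset correlations are t-transformed
(`t = r√(n−2)/√(1−r²)`, |r| clamped at 1−10⁻¹² with a warning),
averaged, scaled by √D where D is the number of datasets covering the
gene, and converted to a two-sided P on Student's t with pooled
`df = Σ_d (n_d − 2)` — the conservative df choice for an average of
per-dataset t-scores. Final assignment requires `R > 0.2` (mean r,
positive membership) and `P < 10⁻¹³`, the gene going to the module
maximizing R.

Two calibration caveats, both checked by the test suite:

* The averaged-t statistic is only *approximately* t-distributed: each
  per-dataset t has variance `(n−2)/(n−4) > 1`, so the scaled average is
  slightly over-dispersed relative to the pooled-t reference.
  Calibration is asymptotic in the per-dataset sample size; the null
  benchmark uses n = 40 per dataset, where the Kolmogorov–Smirnov test
  against Uniform(0, 1) on > 2000 null genes is comfortably passed.
* The top-5-kin MM is a **mean of five correlations**, whose t-transform
  has null variance near 1/5 — conservative, not uniform. The null
  calibration benchmark therefore scores genes with the exact eigengene
  correlation (each gene against a module it does not belong to), for
  which the t-transform has its nominal null distribution. The top-5
  proxy is kept as the default for assignment because it is what the
  workflow prescribes; its conservatism only makes the `P < 10⁻¹³`
  threshold stricter.

Module–trait association is the Pearson correlation of each eigengene
with the 0/1 severity coding; modules at `|r| ≥ 0.2` (or a top-m rule)
are carried forward.

## Ontology filtering and the kappa term network

Genes in no term are dropped (order-preserving). Enrichment is the
hypergeometric upper tail `P(X ≥ k)` with the universe set to all genes
on the merged platform after preprocessing; Benjamini–Hochberg q-values
are pooled across the whole collection (a per-source family is a
one-line change). The weighted-KS enrichment statistic of GSEA is
deliberately **not** reimplemented: in this workflow the enrichment step
functions as an annotation filter plus term grouping, and hypergeometric
over-representation is the transparent, exactly testable equivalent.

Term–term similarity is Cohen's kappa between membership indicator
vectors over the universe, computed directly from the 2×2 table so the
degenerate case (both terms covering the whole universe, `p_e = 1`) can
be defined as 1 for identical terms and rejected otherwise. Terms are
retained when `p < 0.05` and the query holds at least 4% of the term's
genes (`k/K`, the term-centric reading; a query-centric alternative is a
config flag); edges require `κ ≥ 0.4`.

## Seed network and candidate roles

Seeds are expanded over the interactome by undirected breadth-first
search to radius 1 (induced subgraph); hubs are the top-k nodes by total
degree with lexicographic tie-breaks. Candidate roles codify
"initiation, critical connection and termination" as: pure source / pure
sink on the activation/inhibition edges (co-expression edges are
undirected and excluded from the source/sink test), and critical =
betweenness at or above the 0.9 quantile among hubs **and positive**, or
an articulation point of the undirected skeleton. The positivity guard
prevents a degenerate quantile (e.g. a single hub with zero betweenness)
from tagging every hub as critical. These rules are a documented
heuristic codification of a qualitative published description, with the
quantile exposed in config. Candidates of the two contrasts merge by
deduplicated union (the operation that reproduces the published
eight-gene outcome); an intersection mode exists.

## qPCR validation

Per animal, `ΔCt = Ct(target) − Ct(reference)`; per case animal,
`FC = 2^−(ΔCt − mean control ΔCt)`; the reported mean ± SD is over the
per-animal fold changes (SD on the linear fold-change scale, ddof = 1),
and the group test is Welch's unequal-variance two-sided t-test on the
ΔCt values — the robust default at n = 3–5 animals per group. Noise-free
data make the t statistic undefined; an exact-equality guard then
reports p = 1 for equal means and p = 0 otherwise. Regulation calls:
p < 0.05 → significant arrow, 0.05 ≤ p < 0.1 → trend arrow, p ≥ 0.1 →
unchanged; the boundaries p = 0.05 and p = 0.1 fall to the weaker
category by convention (measure-zero in practice), and FC exactly 1 is
always "unchanged". Symbols are emitted as UTF-8 arrows or ASCII codes.

## Pipeline, determinism, benchmark sizes

The two contrasts run independently from a single config whose defaults
are the published parameter values (β = 6, FC 1.2, R > 0.2, P < 10⁻¹³,
κ ≥ 0.4, 4% term fraction, q < 0.05); the run manifest records
per-stage gene counts (monotone along the DEG → module → ontology-filtered
funnel), the full parameter snapshot and the seed. All randomness lives
in the generators; identical seed + config give byte-identical
manifests up to the timestamp.

Benchmark problem sizes (chosen once; see the rationale above): module
recovery uses 20 two-platform studies of 400 genes × 50 samples each;
the null calibration uses 3 × 40-sample datasets of 2100 genes;
end-to-end recovery uses 10 bundles of 400 genes across 3 platforms.
The full test suite runs in well under a minute on one CPU.

## Known limitations

* The adaptive gap cut is a single-height cut: nested or
  height-overlapping modules that the full adaptive-branch dynamic
  tree-cut algorithm would separate are not resolved.
* MRS assumes the platforms measure the same underlying distribution up
  to a monotone map; it cannot correct non-monotone probe effects.
* The meta P's pooled-df reference is slightly anti-conservative for
  very small per-dataset n (see the calibration caveats).
* The hypergeometric ORA ignores gene-gene correlation within terms, as
  over-representation tests generally do.
* Candidate-role rules are a codified heuristic; on real interactomes
  the initiation/termination labels are sensitive to database edge
  directionality conventions.
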