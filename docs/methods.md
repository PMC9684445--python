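# Methods

`mirloop` re-implements, as a tested and reusable pipeline, a common
serum-miRNA biomarker-discovery and regulatory-network workflow for
case/control cancer studies: differential expression of circulating
miRNAs, network-based biomarker scoring, diagnostic evaluation of single
markers and logistic panels, dense-module mining of the targets' PPI
network, and assembly of a TF–miRNA–gene feed-forward-loop (FFL)
co-regulatory network with hub ranking. This note records the models,
the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## Differential expression

Input matrices hold log2 intensities (features × samples). Quantile
normalization forces every sample to share one value distribution: the
reference is the vector of per-rank row means of the column-sorted
matrix, each column's values are replaced by the reference value at
their rank, and ties receive the mean of the reference values across the
tied rank span. Because the procedure depends only on within-column
ranks, any strictly increasing per-sample intensity distortion is
removed exactly.

Testing uses a moderated two-sample t: per-feature pooled variances
`s²` with `d = n₁ + n₀ − 2` degrees of freedom are shrunk toward a prior
`(d₀, s₀²)`,

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),    t on d₀ + d df,

with the prior estimated by moment matching on log sample variances
(digamma/trigamma equations; the trigamma inverse is solved by Newton
iteration). When the residual spread of log variances does not exceed
the sampling noise `trigamma(d/2)`, the fit is degenerate and the
estimator falls back to the ordinary pooled t (prior df 0). A Welch-t
option is provided for unequal variances. Features with zero variance
and zero mean difference get p = 1 by convention (avoids 0/0).
Two-sided p-values are adjusted by Benjamini–Hochberg across all
features. DEM selection keeps features with |log2FC| ≥ 1 and adjusted
p < 0.01 (defaults), ranks them by ascending adjusted p with ties broken
by descending |log2FC| and then id (so results are deterministic),
truncates to a top-k (default 500) per cohort, and intersects across
cohorts. Log2FC is the difference of group means of the normalized
matrix, which is assumed to be on the log2 scale already; an input on
the raw scale must be transformed before loading.

## NSR/TFP biomarker scoring

On the disease-specific bipartite miRNA→gene network (the selected DEMs
and their recorded targets), each miRNA is scored by

* **NSR** — the number of its targets with in-degree 1 (genes it
  regulates alone), and
* **TFP** — the fraction of its targets that are transcription factors.

Significance of TFP is the exact hypergeometric upper tail, drawing the
miRNA's target count from the network's gene universe with the
network's TF genes as successes. The gene universe is the disease
network itself, not the genome — self-contained and configurable.
Significance of NSR has no standard closed form, so it uses a
degree-preserving permutation null: checkerboard swaps of the bipartite
edge list (10 × |E| attempted swaps per replicate) preserve both the
per-miRNA out-degrees and the per-gene in-degrees while shuffling which
miRNA owns which exclusive targets; the p-value is the add-one upper
tail `(1 + #{null ≥ obs}) / (1 + permutations)`, which is never 0 and
shrinks as replicates grow. Candidates require p < 0.05 on both scores
and are ranked by descending NSR (ties: ascending p_NSR, then id).
miRNAs without targets score 0 with p = 1: they cannot be enriched.

## Diagnostics

AUC is the Mann–Whitney rank statistic with half credit for ties, which
equals trapezoidal integration of the empirical ROC curve. Orientation
is fixed so AUC ≥ 0.5 (recorded in the result). The standard error is
the Hanley–McNeil closed form with Q₁ = A/(2−A), Q₂ = 2A²/(1+A), and
the 95% CI is the normal interval clipped to [0, 1]; the CI method is
recorded in the output since tools differ here. The operating point
maximizes the Youden index J = sensitivity + specificity − 1 over
midpoints between adjacent distinct scores plus ±∞ (so J is exact on
the empirical distribution); ties keep the lower cutoff.

Multi-marker panels are binomial logistic regressions fit by IRLS
(convergence when the max coefficient change drops below `tol`,
default 1e-8, max 100 iterations). Rank-deficient designs (e.g.
duplicated members) raise a singular-design error. Perfect separation
is reported with a flag and the finite-iteration coefficients rather
than an exception, because the fitted probabilities — and hence the
panel ROC — are still well defined. Panel ROC is computed on in-sample
fitted probabilities by default, mirroring a fit-and-evaluate-per-dataset
validation design; evaluating transferred coefficients on a held-out
matrix is possible by scoring manually with the stored coefficients.

## Network topology and enrichment

Centralities are computed on the undirected simple graph after
iteratively removing nodes below a degree cutoff (equivalently, taking
the k-core at the cutoff; the operation is idempotent). Betweenness is
unnormalized shortest-path betweenness without endpoint counting — the
common network-tool default; other variants exist, so the choice is
stated here and verified against exhaustive path counting in the tests.
Candidate-panel grouping by "similar topology" has no canonical
algorithm; this package standardizes (degree, betweenness) to zero mean
and unit variance, runs single-linkage agglomeration, and cuts the
dendrogram where the merge distance exceeds τ (default 0.5). τ → 0
yields singletons, τ → ∞ one group. Over-representation analysis is
the hypergeometric upper tail of the query/set overlap within a stated
universe (default: all genes in the loaded target table), BH-adjusted
across sets.

## MCODE module detection

The PPI network keeps edges with confidence ≥ 0.4 (default, matching
common practice with STRING exports). The module detector follows the
original three-stage MCODE design with defaults degree = 2, node score
cutoff = 0.2, k-core = 2, max depth = 100:

1. each vertex is weighted by k × density of the highest k-core of its
   *closed* neighborhood (vertex plus neighbors) — inside an isolated
   k-clique every vertex weighs (k−1)·1; vertices under the degree
   cutoff weigh 0;
2. complexes grow breadth-first from the highest-weight unvisited seed,
   admitting neighbors with weight ≥ seed weight × (1 − cutoff), each
   vertex joining at most one complex;
3. complexes lacking a 2-core are discarded. Haircut and fluff exist
   but are off by default.

Implementations in the wild differ on open vs closed neighborhoods in
stage 1; the closed form is used because it reproduces the (k−1)
clique-weight identity. The module score is density × member count
(score k for an isolated k-clique). Results are deterministic: seeds
and neighbors are processed in sorted order, ties in the final ranking
break on the smallest member id. Module–miRNA association counts the
selected-module member genes each candidate miRNA targets; the
"model-2" panel rule keeps miRNAs above the median association — the
notion of "strongest association" is not standardized, so the rule is
an explicit knob rather than a claim.

## FFL co-regulatory network

The network joins TF→miRNA and TF→gene regulations with miRNA→gene
targeting, restricted to the candidate miRNAs, their shared target
genes, and every TF connected to either; miRNA→TF edges are derived
from miRNA targets that are TFs. Signs follow the standard assumption
— miRNAs repress their targets; TFs activate unless the source
annotates repression — and on conflicting duplicate records repression
wins (the conservative reading of a curated repression annotation).
Signs are carried on the output but do not enter classification, which
is purely topological:

* **composite** — t⇄m mutual regulation plus t→g and m→g (4 edges);
* **TF-FFL** — t→m, t→g, m→g and no m→t;
* **miRNA-FFL** — m→t, m→g, t→g and no t→m.

Composite takes precedence so the classes partition the qualifying
triples. A TF that is itself a regulation target may occupy the gene
role of other triples (dual-role nodes); triples with tf == gene are
degenerate and excluded. Hubs are ranked by total degree separately for
TF and gene nodes (ties by id); dual-role nodes are TFs with at least
one incoming edge.

## Synthetic data and what it shows

The expression generator emulates serum miRNA microarray profiles:
~2500 features, 100–200 samples per group, per-feature baseline means
Normal(8, 2) log2 units (typical log-intensity ranges), Gaussian cell
noise (default SD 0.5), and planted *up-regulated* case features with
log2 shifts drawn from [1, 3] by default (2.0 in the recovery
experiments) — circulating biomarkers in this setting are elevated in
cases. The optional per-sample distortion is an affine-plus-cube map
with random positive coefficients, the simplest strictly increasing
distortion that quantile normalization must undo. The regulatory
generator plants biomarker miRNAs whose exclusive ("single-line")
targets are reserved from all background wiring — their true NSR is
exact by construction, not approximate — and whose target sets are
TF-enriched (default fraction 0.4 vs ~0.15 TFs in the gene universe);
planted FFL triples occupy disjoint node sets wired with exactly their
class's edges, and background edges avoid the two pair types (m→t,
t→m) that could reclassify a planted triple. The PPI generator plants
disjoint near-cliques (p_within = 0.9) in a sparse background
(p_background = 0.01) with confidence scores uniform on [0.4, 0.99].
Defaults for background density (20 targets per background miRNA, 40
TF→miRNA and 80 TF→gene background edges on a 60-miRNA / 1000-gene
universe) were chosen to give the disease network a realistic long-tail
degree structure while keeping generation fast; setting them to 0
disables background wiring entirely for exact-recovery experiments.

What passing these experiments shows: the algorithms recover exactly
what was planted under the stated noise. What it does not show:
robustness to probe-level artifacts, batch effects, annotation drift
between miRBase versions, correlated features, or the heavy-tailed and
censored intensity distributions of real arrays — none of which the
generators emulate, and all of which real studies must handle upstream.

## Numerical choices and degenerate inputs

* BH adjustment delegates to `statsmodels`; tests verify it against a
  literal step-up implementation.
* Permutation p-values are never 0 (add-one rule); doubling the
  replicate count moves them by at most ~2 Monte-Carlo SEs.
* Quantile normalization uses stable mergesort ranking, so tied inputs
  are handled deterministically.
* The consensus target filter applies per-origin cutoff directions
  declared in config (≥ for target scores, ≤ for context++-style
  scores, case-insensitive trimmed membership for score classes);
  validated-strong pairs pass unconditionally; output size is monotone
  non-increasing in `min_sources` and in each cutoff's strictness.
* Identifier matching is case-sensitive and exact; alias resolution and
  miRBase version lifting are out of scope by design.
* Problem sizes in the test suite and the acceptance script (2500
  features for recovery runs, 400 features for null calibration, 400
  PPI nodes, 20 seeds for aggregate checks, 200 permutation replicates)
  were chosen to make Monte-Carlo noise small relative to the margins
  being asserted while keeping a full run in the tens of seconds.

## Known limitations

* NSR significance depends on the rewiring null; very dense bipartite
  networks mix slowly under checkerboard swaps, and the 10×|E| default
  may need raising there.
* In-sample panel ROC is optimistic relative to held-out evaluation;
  the package mirrors the per-dataset refit design and leaves
  cross-validation to the caller.
* MCODE's greedy, visited-once expansion can split a true module across
  two complexes when a bridge vertex is claimed early; recovery
  guarantees in the tests are therefore aggregate (mean membership),
  not per-module worst case.
* The hypergeometric ORA treats genes as exchangeable; correlated gene
  sets and annotation bias are not modeled.
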