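# Methods

## Synthetic kinetic model

The generator emulates multi-exposure capture on kinase-activity peptide
arrays. For a normal reporter peptide the fluorescence at exposure
`t` (ms) in one well is

    I(t) = s · t + c + ε,   ε ~ N(0, σ²),  clipped at 0,

with a per-peptide baseline slope `s ~ U(0.5, 3.0)` intensity/ms shared
by all wells, intercept `c = 5` intensity units, and exposures
(10, 20, 50, 100, 200) ms. Linearity in exposure is deliberate: the QC
step keeps only peptides whose signal grows linearly over time, so the
linear regime is the in-specification signal model and curvature is the
planted violation.

A planted kinase-family effect `e` (log2 units) multiplies the treatment
group's slope by `2^e` for every substrate of that family, so `e` equals
the expected log2 fold change of the slope-derived signal. Planted QC
failures come in two classes, selected by a seeded shuffle with
`floor(fraction × n_peptides)` of each: *dead* spots emit
`|N(0, σ/10)|` (indistinguishable from background) and *saturating*
spots follow `A·(1 − exp(−t/τ))` with `τ = 20 ms` and `A = 100·s`,
which is concave enough that its noise-free linear fit has R² ≈ 0.57,
safely below the 0.90 linearity threshold while keeping a clearly
detectable maximum intensity.

Defaults: two groups ("sedentary", "exercise") with two wells each,
three technical-replicate chips, noise σ = 2.0 intensity units (about
1–2 % of a mid-range 100-ms signal). All randomness flows from one
integer seed through `numpy.random.default_rng`; identical
configurations produce byte-identical read tables.

What the generator does **not** emulate: spot-level spatial artifacts,
washing chemistry, well-to-well loading differences, correlated noise
across exposures, and biological replicate variance (the emulated design
pools biological replicates before the chips, so wells differ only by
noise). Passing tests therefore demonstrate the correctness of the
analysis machinery under its stated model, not robustness to every
artifact of real arrays.

## Kinetic reduction and QC

Each (chip, sample, peptide) series is reduced by ordinary least squares
to slope, intercept and R²; the per-sample signal is `slope × 100 ms`
(the reference exposure, configurable). A constant series has R²
defined as 0. Fits with fewer than three distinct exposures cannot
support a linearity judgement and are marked failed.

QC classifies each fit: *undetectable* iff max intensity < `min_signal`
or slope ≤ 0 (numerically, slope ≤ 1e−12, so an exactly flat series is
undetectable rather than non-linear); otherwise *nonlinear* iff
R² < `min_r2`. Defaults `min_r2 = 0.90` and
`min_signal = 2 × noise floor`, where the noise floor is estimated as
the 5 % quantile of shortest-exposure intensities. A peptide enters the
comparison only if it passes in every well, matching the single
per-comparison pass count array workflows report.

## Differential phosphorylation

Fold changes are computed within each chip (the chip is the blocking
unit) as log2 of the ratio of group mean signals, then averaged across
chips. The |log2FC| > 0.2 flag uses a strict inequality; the 15 % hit
rule is applied on the linear fold-change scale, |2^log2FC − 1| ≥ 0.15,
evaluated with a 1e−12 tolerance so an exact 15 % ratio survives the
log/exp round-trip. The two flags are computed independently: the 15 %
rule admits log2FC ≥ log2 1.15 ≈ 0.2016 or ≤ log2 0.85 ≈ −0.2345, which
is neither implied by nor implies the ±0.2 flag.

The ternary kinase score assigns +1 (log2FC > 0.2), −1 (< −0.2), else 0
— boundary values score 0 — and averages over a kinase's mapped
substrates; the sign of the mean is the direction. Kinases with no
surviving substrate report `no_data` rather than a direction.

Heatmap export row-normalizes to (x − row mean)/row SD (constant rows
become zeros with a warning) and orders rows and columns by
average-linkage hierarchical clustering of Euclidean distances; the
metric and linkage are fixed and recorded, and the output is a table
plus leaf orders, never an image.

## Resampling enrichment

Family scores use random resampling: each of `n_iter = 2000` iterations
(default; 10,000 in the convergence check) draws |hits| peptides
uniformly without replacement from the QC-passing universe and counts
members per family; `z = (observed − mean)/sd` over iterations, with z
undefined (reported as NaN) when the permutation sd is 0. Because the
draw is a simple random sample, the moments converge to the
hypergeometric closed form — mean `nK/N`, variance
`n(K/N)(1−K/N)(N−n)/(N−1)` — which is the independent oracle in the
tests: at 10,000 iterations both moments sit within 0.05 of the closed
form on the worked 20-peptide instance. Families are scored on counts
only; direction comes from the ternary score.

## Rank harmonization

Each ranker is reduced to percentiles `rank/K` with average-rank ties
(best score → 1.0), after negating scores oriented lower-is-better.
This makes the harmonized table invariant under any strictly monotone
transform of a ranker's raw scores. Kinase names are mapped to HGNC
symbols via a packaged alias table covering the kinases this analysis
names plus the synthetic families; unknown aliases are carried through
and reported, and two aliases of one symbol within one ranker are an
error rather than a silent merge. Mean and median percentiles are taken
over the rankers where a kinase is present — absence is missing
evidence, shown as an empty circle in bubble tables, not zero evidence
(an `absent_as_zero` switch provides the alternative). Quartiles are
`⌈4p⌉` clipped to 1–4, so quartile 4 means percentile > 0.75.

## Prize-collecting Steiner forest

Node prizes are the percentile ranks of the mean harmonized percentile
over the merged serine/threonine and tyrosine tables (on a collision the
larger mean percentile wins); all other graph nodes have prize 0. Edge
costs are `1 − confidence` (bounded in [0,1), commensurate with
percentile prizes; `1/confidence` is available as an option). The
objective minimized is

    β · Σ_{v ∉ F} prize(v)  +  Σ_{e ∈ F} cost(e)  +  ω · (#trees in F),

the standard rooted formulation: a virtual root attached to every node
with edge weight ω makes each tree pay one root edge. Without the ω
term the optimum would degenerate to all-singletons, since including an
isolated prized node would be free. Defaults β = ω = 1; exact ties
between including and excluding a node go to inclusion.

The heuristic runs from two starts — the strong-pruned minimum spanning
tree of the rooted graph, and the empty forest — and polishes each with
a local search (cheapest-path attachment of excluded prized nodes,
tree-merging through non-forest paths, splitting of edges costing more
than ω, dropping of unprofitable trees) alternated with a node-set flip
search: for a fixed node set the optimal forest is exactly the rooted
MST of the induced subgraph, so toggling single nodes and re-treeing
evaluates each neighboring selection at its true optimum. Exact mode
enumerates all node subsets (≤ 12 nodes) with the same rooted-MST
evaluation; the subset MSTs use `scipy.sparse.csgraph` with a +1 weight
shift because that routine drops zero-weight edges and a spanning tree's
edge count is fixed, making the shift exact. On 50 random 10-node
instances the heuristic matches the enumerated optimum ≥ 96 % of the
time and, by construction of the comparison, can never beat it.

Hub nodes are ranked by degree within a focal subnetwork, ties broken by
prize then name; degree (rather than betweenness or solver internals) is
a documented choice.

## Pathway enrichment and meta-clustering

ORA uses the one-sided hypergeometric upper tail against the full graph
node set as universe, with gene sets intersected against it, and BH FDR
across tested terms (α = 0.05). The combined score is
`−ln(p) × z`, where z standardizes the deviation of the term's observed
p-value rank from its rank distribution under 100 random queries of the
same size (seeded); a pure `−ln(p)` mode keeps the result exact and
deterministic. Tests verify the p-values against exhaustive enumeration
of the hypergeometric pmf with integer binomial coefficients on all
universes ≤ 15.

Significant terms are clustered on their embedding vectors with
average-linkage agglomerative clustering on cosine distance; k is fixed
or chosen by the largest cosine silhouette over k ∈ [2, min(10, n−1)],
with all-identical directions collapsing to one cluster. The most
representative term is the member most cosine-similar to its cluster's
mean vector, ties to the lexicographically first term. Embeddings are
an input table; the synthetic fixture draws them from cluster prototypes
plus Gaussian noise, which preserves the within/between-cluster cosine
contrast real text-derived embeddings exhibit. 2-D coordinates are
presentation-only: provided ones are passed through, otherwise classical
MDS of cosine distances (a deterministic eigendecomposition) fills in;
no assertion depends on them. Cluster heatmap tables order clusters and
terms by descending mean log combined score, masking missing cells out
of the means.

## Validation statistics

The pooled (Student) two-sample t-test is implemented both from raw
values and from printed summaries (mean ± SE, n), converting
`SD = SE·√n` and pooling variances with `df = n_a + n_b − 2`. The
pooled rather than Welch form is used because it is what reproduces the
published group comparison from its printed summaries (p = 0.013).
Simple regression reports OLS slope/intercept, R² and the F(1, n−2)
p-value; sedentary animals enter distance regressions at distance 0.

## Synthetic companion fixtures

The demo's interaction graph, gene-set library, term embeddings and
external ranker tables are all generated in code (`kinopipe.simulate`),
clearly labelled synthetic. External rankers are noisy monotone
transforms of the internal z-scores (agreement 0.8), standing in for
tools whose internals are out of scope. The gene-set generator can
concentrate a few sets on chosen symbols so that enrichment and
clustering stages have genuine signal to find; the demo focuses them on
the top-quartile-prize kinases. The PPI generator includes a loosely
connected non-kinase background (30 proteins) so the enrichment universe
is realistically larger than the kinomic hit list.

## Problem sizes and reproducibility

The bundled experiments use: full-size chips (144/196 peptides, 3 chips,
4 wells) for simulation studies; 50 seeded runs for the planted-recovery
and Steiner-forest oracle studies; 10,000 iterations for the resampling
convergence check; 2000 iterations for routine enrichment. The demo
pipeline completes in about a second and the whole self-check battery in
under a minute on one CPU. Every stochastic step takes an explicit seed,
outputs embed no timestamps, and a pipeline rerun under an identical
configuration is byte-identical (verified by SHA-256 digests in the run
manifest).

## Known limitations

- The kinetic model omits saturation of *normal* peptides at long
  exposures; real arrays drift from linearity at high signal.
- The alias table is a small curated fixture, not a full HGNC dump;
  unmapped names pass through as-is (upper-cased) and are reported.
- The Steiner-forest heuristic is exact only in its oracle regime
  (≤ 12 nodes); on larger graphs it provides no optimality certificate,
  only the never-beats-exact guarantee where enumeration is feasible.
- The β-monotonicity of collected terminals is guaranteed only in exact
  mode; the heuristic may be non-monotone on adversarial instances.
- UMAP-style nonlinear embedding of pathway coordinates is out of scope;
  the classical-MDS fallback preserves distances only linearly.
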