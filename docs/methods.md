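# Methods

This note documents the statistical procedures tssbind implements, the
defaults it ships, the design decisions taken where the underlying analysis
pattern is ambiguous, and what the synthetic-data generators do and do not
emulate.

## Coordinates and peak geometry

All coordinates are 0-based, half-open (BED convention). A peak's middle is
`floor((start + end) / 2)`. The signed distance from a peak to a gene is
strand-aware: `mid − tss` on the plus strand and `tss − mid` on the minus
strand, so negative always means upstream of the gene. The sign convention
is documented rather than universal; histograms can be recomputed on
absolute values by the caller if an unsigned profile is wanted.

Reproducible peaks are the intersection spans of every overlapping pair
between two replicate sets. Because the intervals are half-open, peaks that
merely touch (end of one = start of the other) share no base and do not
intersect. Nearest-TSS ties (two TSSs equidistant from a midpoint) break by
the lexicographically smaller gene id, which makes every downstream table
deterministic.

A gene is **bound** when some peak midpoint lies within `window` bp of its
TSS, boundary inclusive, with `window = 1000` by default — the same window
used to select genes for the methylation, knockdown and term-enrichment
analyses, so "bound" means the same thing everywhere.

Element annotation uses strand-aware upstream windows on the nearest gene:
promoter = 2 000 bp upstream (TSS included), enhancer = 30 000 bp upstream,
with precedence promoter > enhancer > gene body > intergenic. "Gene body"
is approximated as the 30 kb downstream of the TSS because the annotation
carries TSSs only, not transcript ends; on dense synthetic genomes (one
gene per ~2 kb) nearly every base falls in some window, so element
frequencies are informative only on sparse annotations.

Random control peaks draw a chromosome proportional to its length, a start
uniform along it, and a length resampled with replacement from the template
set ("uniform over genomic positions"); draws that would overrun the
chromosome are redrawn. Positions are reproducible from the seed.

## Expression stratification

Genes are ranked by expression (descending, ties by gene id) and chunked
into bins of 1 000; only the last bin may be smaller. The four expression
categories are frozen constants over CAGE-style tag counts: none = exactly
0, low = (0, 10], intermediate = (10, 100], high = (100, ∞). The published
ranges overlap at their endpoints (0–10, 10–100); they are resolved
half-open on the left so the categories partition the genes, and the
boundary cases 0, 10, 100 are pinned by explicit tests.

## Track similarity

A weight track is a nonnegative per-base signal stored as run-length
intervals (implicitly zero elsewhere). The raw association between two
tracks is the sum over all bases of the product of their weights, computed
by a boundary sweep over interval overlaps; dense per-base arrays are never
materialised, so whole-genome tracks cost O(intervals), not O(basepairs).
Two normalisations are provided:

* **cosine** (default): divide by the product of the tracks' Euclidean
  norms. This is the cosine of the angle between the per-base weight
  vectors: symmetric, scale-invariant, bounded in [0, 1], and maximal for
  self-comparison — the property that makes "a track ranks near itself and
  its replicates" hold by construction, which the ranking analyses rely on.
* **literal**: multiply the raw sum by the genome size and divide by the
  square of each track's total weight. This follows the published wording
  of the size correction ("the inverse square of the total weight of each
  track") at face value; it is not scale-invariant and is kept as an
  explicit mode because the original formula is not recoverable beyond its
  prose description.

Either track empty scores 0. An optional binning width re-expresses tracks
on a fixed grid (mass-preserving) for very large compendia; width 1 is
exact and the default is off.

Rankings sort by descending score with ties broken by experiment id. The
label-enrichment statistic is the mean rank of the labelled experiments; the
one-sided permutation p re-labels uniformly at random n_perm times (default
10⁵) with add-one smoothing, `p = (1 + #{perm ≤ obs}) / (1 + n_perm)`, and
the asymptotic one-sided Mann–Whitney p of labelled vs unlabelled ranks is
reported alongside as an analytic cross-check; the two agree within a small
factor at compendium sizes of ≥ 50. The median-label-rank profile ranks,
for every track used as query, all other tracks, extracts the ranks of the
labelled factor (lower median for even counts), and sorts queries by that
median; queries with no labelled counterpart get NaN and sort last.

## Methylation

The methylation grade of a gene is the arithmetic mean beta of its probes
(betas validated to [0, 1]; genes without probes are absent, not zero).
The comparison reports the empirical distributions of bound genes and of
all graded genes — the published comparison — plus the disjoint not-bound
complement, and runs the two-sample Kolmogorov–Smirnov test on bound vs
not-bound so the samples do not overlap.

## Knockdown regulation

Per construct, fold change is `mean(kd) − mean(ctrl)` on log2 scale and the
p-value comes from the two-sample equal-variance t-test across replicates
(triplicates in the motivating design; two suffice). Genes identical in
both arms get p = 1 by convention. The two constructs combine by the
arithmetic mean of their fold changes and by Fisher's method on their
p-values (χ² with 4 df; Stouffer optional); which method produced a table
is recorded in the run manifest. Classification takes the k = 1 000 genes
with the largest (smallest) average fold change as "up" ("down"); under the
p-value criterion the top k by combined p are taken separately among genes
whose fold changes agree in sign — the source analysis does not address
discordant constructs, and requiring concordance avoids calling a gene "up"
on the strength of one construct's downshift. Everything else is
"unaffected". Enrichment of a bound-gene set across the three categories is
tested by the chi-square contingency test plus one-sided two-proportion
z-tests of up-vs-unaffected and down-vs-unaffected; degenerate tables
(empty category, all genes bound) are reported as non-applicable rather
than raising.

## Co-expression network

Genes are standardized to mean 0, variance 1 (population variance), so no
intercept is needed and one penalty is comparable across genes. Each non-TF
target gene is regressed on all TF columns with an L1 penalty under the
objective `(1/2n)·‖y − Xβ‖² + λ‖β‖₁`, solved by coordinate descent
(scikit-learn's Lasso; tolerance 10⁻⁶, at most 10⁴ sweeps, non-convergence
raises). A nonzero coefficient is a directed TF → gene edge; TF–TF
regressions are excluded by default. Under this objective the all-zero
solution is optimal exactly when `λ ≥ max_j |x_jᵀy| / n`, which gives each
dataset a closed-form zero-edge threshold.

λ\* is calibrated by permutation: each of n_perm permutations shuffles
every gene's sample labels independently, preserving marginals while
destroying inter-gene correlation, and λ\* is the smallest value on a
50-point logarithmic grid over [0.01·λ_max, λ_max] at which every permuted
dataset yields zero edges (evaluated via the closed-form threshold; the
test suite additionally refits the permuted data at λ\* and asserts zero
edges). If the grid cannot silence all permutations, λ_max is returned with
a warning. Connection count is a TF's out-degree over unique targets; hubs
sort by descending count with ties by TF id. The cross-dataset comparison
reports a TF's rank in two independently fitted networks, its percentile
(rank / number of TFs) in the second, and which of the first network's
top-30 TFs has the most connections in the second.

## Term enrichment

Fold enrichment of a term is `(|set ∩ term| / |set|) / (|universe ∩ term| /
|universe|)`; significance is the hypergeometric upper tail of the overlap.
The universe defaults to all genes in the annotation unless overridden.
Filters drop terms larger than 5 000 genes or above p = 0.01, and among
term pairs whose gene sets have Jaccard ≥ 0.8 keep the smaller-p term (the
redundancy criterion is not specified by the source analysis; Jaccard 0.8
with keep-most-significant is this package's choice and is configurable).
A Benjamini–Hochberg column is available but no filter uses it.

## Synthetic data

The generators are pure functions of (config, seed); each input type draws
from its own child stream of the root seed, so regenerating one input never
perturbs another. The packaged default configuration ("paperlike-small")
is a desk-scale stand-in for a genome-wide study: two 5-Mb chromosomes,
5 000 genes at ≥ 1 500 bp spacing, log-normal expression (μ = 2.5, σ = 2.0
on the log scale, 25 % silent), binding probability logistic in
log10(1 + expression) (slope 2, intercept −3: ~5 % of silent and ~75 % of
very highly expressed genes bound), TSS-centred peaks with 300 bp
positional jitter, 400 ± 100 bp widths, 85 % per-replicate reproducibility
and 5 background peaks per Mb; a compendium of 10 polymerase-like and 5
open-chromatin-like expression-weighted tracks, 5 repressive tracks
covering silent genes, and 30 random tracks, all with per-gene lognormal
height noise (σ = 0.5) and 10 % gene dropout; methylation baseline
Beta(4, 2) with a −0.2 shift at bound genes and 0.1 probe noise over
Poisson(3) probes; a 15 000-gene knockdown universe whose bound subset
(1 500 genes, padded from the world's true bound set) has disjoint 30 %
fractions shifted ±1 log2 in both constructs, triplicate arms with 0.2
replicate noise; and a co-expression model Y = XB + E with 20 standard-
normal TFs, 200 targets, 300 samples, one hub TF driving 50 targets and
every other TF driving 5, coefficient magnitudes Uniform(0.5, 1.5) and
noise σ = 0.5. These values were chosen once as representative of the
signal strengths such studies report, and the whole pipeline runs on them
in well under a minute on one CPU.

What the generators deliberately do not emulate: read-level sequencing
noise (no FASTQ, no mappability structure), realistic gene architecture
(no transcript ends, isoforms or CpG islands), probe-level array artefacts,
batch effects in the expression compendium, and correlated TFs (the design
matrix is independent normal, which makes LASSO recovery easier than on
collinear real expression data). Passing recovery tests therefore shows the
statistics are implemented correctly and are calibrated under their own
assumptions — not that real data would yield effects this clean.

## Numerical choices and degenerate inputs

Seeds are mandatory wherever randomness enters (permutation tests, random
controls, generators); permutation p-values use add-one smoothing and are
never exactly zero. Similarity of anything with an empty track is 0 rather
than NaN. Histogram bins are half-open with the exact upper range endpoint
excluded. Zero-variance t-tests fall back to p = 1 (no change) or p = 0
(exact change), and chi-square tests on degenerate contingency tables are
reported as non-applicable. The lasso's univariate solutions match the
soft-threshold closed form to 10⁻⁸ when run at tight tolerance; the default
tolerance (10⁻⁶) is looser and can zero coefficients within ~10⁻³ of the
penalty boundary, which is irrelevant at the effect sizes the network
analysis targets but worth knowing when λ is chosen adversarially close to
λ_max.

## Known limitations

Element annotation approximates gene bodies from TSSs alone. The
median-label-rank profile is O(N²) in compendium size (all-versus-all
scores); at the ENCODE scale of several thousand tracks it needs the
precomputed similarity matrix and patience, or the optional binning. The
knockdown classifier assumes a common gene universe between constructs and
drops (with a warning) genes measured in only one. The network permutation
scheme destroys all inter-gene correlation including any TF–TF structure;
calibration against partial nulls (e.g. preserving TF covariance) is not
implemented.
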