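# Methods

This note records the statistical models implemented in `crisforge`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Discovery cascade

**Variable genes and normalization.** Genes with across-sample sd > 0.8
(n−1 denominator) are retained; each sample column is then standardized to
N(0,1). Per-*sample* standardization is used, not per-gene: the intent is to
remove sample-level scale differences before factorization while leaving the
gene-level contrasts that the clustering should see.

**Consensus NMF.** Z-scored data are made non-negative by row-splitting
(each gene contributes a positive-part row and a negated-negative-part row),
the standard device for factorizing centered data. For each K in 2…6 the
matrix is factorized `n_runs` times (default 50; 20 in the test suite and
acceptance script, which is ample for the cohort sizes used there) with
KL-divergence multiplicative updates (scikit-learn's `mu` solver, random
init, up to 2000 iterations, tol 1e-4). Each run assigns samples to their
dominant metagene; the consensus matrix is the mean co-clustering indicator.
Hard labels come from average-linkage clustering of 1 − consensus.

**Choosing K.** The cophenetic coefficient correlates the cophenetic
distances of the average-linkage tree with 1 − consensus. On well-separated
data it saturates at exactly 1 for several K at once: merging two true
clusters the same way in every run is as ultrametric-consistent as the true
partition, and so is a perfectly reproducible split of one cluster. Exact
ties are therefore broken by the dispersion coefficient
ρ = mean(4(c − ½)²) — how crisp the consensus is — and finally toward the
smaller K. The coefficient is clipped to [0, 1] to avoid floating-point
overshoot deciding ties.

**Core samples.** Silhouette width s(i) = (b − a)/max(a, b) on the distance
1 − consensus; samples with s(i) < 0 are dropped. An error is raised if a
cluster would lose all members.

**Multiclass differential statistic.** For gene i,
r_i = sqrt(Σ_k n_k (x̄_ik − x̄_i)² / (K − 1)) / (s_i + s0), with s_i the
pooled within-class sd and s0 the median of the s_i (a common fudge-factor
default; a grid search over s0 is deliberately out of scope). The null is
label permutation (default 100 permutations; fewer than 25 is refused as
unstable); the FDR at each observed cutoff is the median permuted count of
exceedances over the observed count, made monotone. The default selection
threshold is FDR ≤ 0.005.

**Shrunken centroids.** d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0)) with
m_k = sqrt(1/n_k − 1/n) (the standard error of a class mean around the
overall mean), soft-thresholded to d′_ik = sign(d_ik)(|d_ik| − Δ)₊. Δ is
chosen from a 30-point grid up to max|d| by leave-one-out cross-validation
with a uniform class prior; among error-minimizing thresholds the *smallest*
is taken, retaining the most genes — the selected genes feed the signature,
so parsimony in genes is not a virtue at this stage.

**Stromal filter.** Genes whose stromal signal fraction is strictly greater
than 0.5 are removed ("above 50%" read as strict, so exactly 0.5 is kept).
Genes missing from the stromal table are kept with a logged warning, since a
xenograft-derived table need not cover every measured gene.

**Non-redundant assignment.** A gene with a positive d′ for exactly one
class goes to that class; positive for several, to the best class only when
best − second ≥ 0.2; otherwise it is excluded, keeping the per-class lists
disjoint as NTP requires. The cascade ledger checks the arithmetic
candidates − no-positive-score − stromal = pool; pool − redundancy-excluded
= final size.

## Nearest template prediction

The template of class c is the binary indicator of its markers over the
union of all signature genes; the distance is (1 − Pearson r)/2, chosen from
the cosine/correlation family of the original method and pinned here (the
exact historical variant is implementation-defined). Distances lie in [0, 1]
and are invariant to per-sample affine rescaling. At least 50% of each
class's genes must be measured.

**Significance.** The observed statistic is the *minimum* distance over the
K class templates. The resampling null mirrors that selection: each of the
`n_resamples` draws takes a random gene layout of the union's size from all
measured genes, scores it against every class template (each retaining its
signature size), and keeps the minimum. A single-template null would make
null p-values sub-uniform (the minimum of K correlated distances is
stochastically small), inflating assignment on noise as K grows; with the
min-statistic null, nominal p-values are uniform on null data for any K
(verified by a Kolmogorov–Smirnov check in the suite). p-values use the
(1 + count)/(1 + B) convention. BH FDR is computed jointly across all
samples of a run, and samples at FDR ≥ 0.2 — or with an exact tie in the
best distance — are left UNASSIGNED.

**Class similarity tree.** Average-linkage clustering of classes on
1 − correlation between their per-sample distance profiles.

## Multiclass k-TSP

**ICOR.** Within each dataset, expression is rank-transformed across
samples and a gene × gene correlation matrix computed; for each gene and
each dataset pair, the pairwise index is the Pearson correlation between the
gene's two co-expression profiles (self excluded); the total ICOR averages
over dataset pairs. Pearson on the rank-correlation profiles is adopted
(whether the outer correlation should itself be rank-based is unstated in
the method lineage; this choice is pinned and tested).

**Dichotomization.** A two-component univariate Gaussian mixture (EM,
5 restarts, up to 500 iterations) is fitted to the total ICOR values; the
threshold is the equal-posterior crossing between the component means and
genes in the upper component are kept. The threshold is data-dependent by
design.

**Pairs.** Candidates per class are the top-50 genes by two-sided Wilcoxon
rank-sum p (class vs rest). For a comparison (X, Y), a pair (i, j) scores
delta = |P̂(X_i < X_j | X) − P̂(X_i < X_j | Y)| with within-sample ties
counting 0.5 (the unbiased convention); the secondary score gamma is the
absolute difference of the mean within-sample rank difference between the
classes (the standard k-TSP secondary score). Comparisons are processed in a
caller-supplied order (a helper reproduces the heuristic: priority classes
first, remaining comparisons by ascending candidate-pool size); within each
comparison the k best pairs by (delta, gamma, lexicographic ids) among
still-unused genes are taken and their genes are consumed globally, so all
pairs are disjoint. With k pairs per comparison and n classes this yields
k·C(n,2) pairs and each class receives k·(n−1) genes when reduced back to
per-class marker lists (the "NTP-80" construction at k = 4, n = 5).

**Voting.** Per sample: (i) pairs with unmeasured genes are discarded;
(ii) each comparison's evaluable pairs vote (a within-sample expression tie
splits the vote 0.5/0.5) and the per-class proportion averages the vote
fractions over the comparisons involving the class; (iii) a unique maximum
wins; (iv) a tie among ≥3 classes leaves the sample UNASSIGNED; (v) a
two-way tie is resolved by the head-to-head comparison, UNASSIGNED if still
tied. The rule depends only on within-sample orderings, so classification is
invariant under any strictly monotone per-sample transform (property-tested
with an exponential warp).

## Enrichment and scores

All scores are computed on per-gene median-centered log2 values of the input
cohort (the centering cohort is the analyzed matrix itself). The signature
score is mean(up) − mean(down), reducing to mean(up) when no down set is
given; the receptor activity score weights the receptor and the ligand
average equally, (Receptor + mean(Ligands))/2 — the literal reading of the
defining prose. Stromal C/E/L scores are plain signature means.

The preranked engine uses the weighted Kolmogorov–Smirnov running sum: hit
increments ∝ |rank value|^p (p = 1 by default; p = 0 gives the classical KS
statistic, verified against a brute-force running-sum oracle), miss
decrements 1/(N − N_hit); ES is the maximum deviation. The null permutes set
membership (random same-size sets, default 1000 permutations); the nominal p
compares |ES| with same-sign null values, NES = ES / mean(|null ES| of the
same sign), and FDR follows the standard pooled-NES procedure, with BH on
nominal p available as a simpler alternative. Sets of size < 2 or > N − 2
are skipped. SSEA ranks *samples* by a score and tests the per-class sample
memberships as sets, excluding UNASSIGNED samples.

## Genomic load

Mutational load is count / 30 Mb (the exome-size convention; configurable).
Copy-number load is Σ length(|seg mean| > 0.3) / Σ length over a sample's
segments, with strictly-greater alteration calls, 1-based inclusive SEG
coordinates and an error on overlapping segments (ambiguous nucleotide
count) or duplicate sample ids in mutation tables (aliquots must be
de-duplicated upstream).

## Synthetic data

The generator plants K latent classes: observed =
(1 − f_s)·cancer + f_s·stromal + N(0, noise_sd), with per-sample mixing
fraction f_s ~ U(lo, hi), class markers shifted by the effect size in their
own class, and a stromal program on a dedicated gene block. The defaults —
5 classes, 30 markers/class, 500 background genes, 40 stromal genes, effect
3 log2 units, noise sd 0.5, f_s ∈ [0, 0.3] — are the fixture used by the
test suite and acceptance script (40 samples per class there), sized so the
full pipeline runs in seconds. The emitted stromal-fraction table is the
expected share of signal of stromal origin:
f̄·a_g / (f̄·a_g + (1 − f̄)·b_g), with a_g the stromal amplitude and b_g the
gene's cancer-intrinsic amplitude.

Multi-platform replicates apply per-platform strictly increasing transforms
(gain + cubic term + offset) plus Gaussian noise, preserving within-sample
ranks in expectation. SEG fixtures tile a single synthetic chromosome with
an altered-nucleotide fraction matching the requested target up to
boundary discretization; mutation counts are Poisson(rate × 30 Mb).

**What this does not emulate** — and hence what passing tests do not show
about real data: count-level RNA-seq noise, batch effects beyond monotone
distortion, correlated background co-expression, intensity-scale (pre-log)
stromal mixing (the convex mixture is applied directly on the log2 scale as
a linear residual approximation), overlapping marker programs, and class
imbalance. Real cohorts are harder on every axis; the synthetic recovery
numbers are an internal-consistency check, not a field benchmark.

## Known limitations

- Consensus NMF cost grows as runs × K-values × factorization; the defaults
  target cohorts of a few hundred samples and ~1000 variable genes.
- The dispersion tie-break for K assumes ties reflect saturation on clean
  data; on real cohorts cophenetic values rarely tie and the plain argmax
  decides.
- Gene identifiers are opaque case-sensitive strings; probe collapsing and
  symbol aliasing must happen upstream.
- The SSEA FDR pools NES across the (often few) class sets; with < 3 sets
  the BH alternative is usually the more sensible choice.
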