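# Methods

## Model

A cell's differentiation potency is modeled through the statistics of an
expression-modulated random walk on a protein-protein interaction (PPI)
graph. Let A be the G×G symmetric binary adjacency of a connected PPI
network over named genes (A_ii = 0), k = A·1 its degree vector, and
x ∈ ℝ^G_{>0} a cell's strictly positive normalized expression over the same
genes. The walk moves from gene i to neighbor j with probability

    p_ij = A_ij x_j / Σ_k A_ik x_k .

Because the edge weights w_ij = x_i x_j are symmetric, the chain is
reversible, with closed-form invariant measure π_i = x_i (Ax)_i / xᵀAx
satisfying πP = π and detailed balance π_i p_ij = π_j p_ji. Its entropy rate

    SR = −Σ_ij π_i p_ij log p_ij = Σ_i π_i S_i ,   S_i = −Σ_j p_ij log p_ij,

measures how efficiently signaling flux spreads over the network; cells
that overexpress hubs distribute flux more promiscuously and attain higher
SR. SR is invariant to positive rescaling of x and bounded above by the log
of the largest adjacency eigenvalue (the graph's topological entropy; the
bound is attained when x realizes the Parry measure, e.g. uniform x on a
regular graph).

Two approximations follow. A mean-field step replaces (Ax)_i by k_i (up to
scale), giving the diagnostic three-way sum Σ_i x_i k_i S_i, exposed as
`sr_approximation` without any normalizing constant — only its ordering
across cells is meaningful. Observing further that the S_i have small
dynamic range yields CCAT = PCC(x, k), a per-cell Pearson correlation that
needs neither π nor S. CCAT is not equivalent to SR — graphs exist where
the two anti-correlate — but on hub-dominated (scale-free, PPI-like)
topologies it is a positively correlated, essentially free proxy; the test
suite asserts Spearman ρ > 0.5 between the two on simulated data.

Comparator measures implemented for benchmarking: detected-gene count;
GCS (geometric mean of log-normalized expression over the 200 genes most
correlated, per dataset, with detected-gene count); the transcriptome
Shannon entropy of read-count proportions; and its restriction to each
cell's 1000 most-expressed genes. The smoothing step some pipelines add on
top of GCS has no published closed form and is out of scope; GCS is the
implemented ceiling of that family. All entropies are reported in nats
(natural log); the log base only rescales entropy globally and cannot change
cross-cell rankings.

## Normalization

The diffusion matrix divides by sums of expression values, so x must be
strictly positive: counts are transformed as log₂(counts + 1.1), whose
minimum log₂(1.1) ≈ 0.1375 is above zero. The pseudocount is deliberately
not 1 (log1p leaves exact zeros). An expert override exists but warns when
it forfeits the positivity guarantee, and the diffusion operators reject
non-positive vectors with a pointer to the pseudocount. Base 2 is the field
convention; SR and CCAT are provably invariant to positive rescaling/affine
maps of x respectively, so the base is immaterial to results (tested to
1e−10). Optional counts-per-10k library scaling before the log is provided
but off by default; duplicate gene rows are aggregated by sum on counts
only (summing log-space values would be meaningless).

## Network handling

Edge lists (TSV or SIF) are deduplicated and stripped of self-loops. The
localization filter removes exactly the extracellular×intracellular
pairings; membrane proteins and unannotated genes keep all edges (the
conservative reading: only the stated implausible pairing is filtered).
The maximally connected component is then extracted, with size ties broken
by the lexicographically smallest sorted node list for determinism. Gene
matching against an expression matrix induces the subgraph on the shared
genes and re-extracts the component, so matrix rows and network nodes end
identically ordered. Adjacency is stored sparse (CSR); identifiers are
matched as exact case-sensitive strings, with no alias resolution.

Arithmetic sanity anchors: with the published node/edge counts of the
Pathway Commons v12 (12 649 / 464 091) and STRING v11 (12 921 / 3 594 088)
connectomes, E/(G(G−1)/2) evaluates to 0.580% and 4.31% — matching their
printed densities of 0.6% and 4% at printed precision.

## Evaluation statistics

Discrimination accuracy between known high- and low-potency groups uses the
AUC derived from the Mann-Whitney U statistic: AUC = U/(n₁n₂), the
probability a random high-potency cell outscores a random low-potency one,
ties counting ½. One-sided p-values use the exact U distribution when there
are no ties and n₁n₂ ≤ 400, otherwise the tie-corrected normal
approximation; a pooled sample with zero rank variance returns p = 0.5.

Dropout robustness: injection raises the matrix zero fraction by an
absolute delta (the "+5%" convention is percentage points, consistent with
describing datasets by their dropout *rate*), zeroing uniformly chosen
non-zero entries under an explicit seed; an expression-weighted variant
(probability ∝ 1/count) is available for sensitivity analysis, since the
physical dropout process favors low-abundance transcripts. The robustness
statistic is the Pearson correlation of per-cell scores before vs after,
with the measure fully recomputed (including re-normalization) on the
injected counts.

Degree-permutation significance: given two degree vectors k₁, k₂ over one
gene universe and a log-normalized matrix, the observed statistic is the
correlation across cells of the two per-cell CCAT vectors. Each Monte-Carlo
draw applies one shared permutation σ to both degree vectors — this leaves
PCC(k₁, k₂) exactly invariant (asserted every run) while destroying any
transcriptome–connectome association — and recomputes the statistic.
Empirical p-values use (1 + #{null ≥ observed})/(B + 1), which can never be
zero and is calibrated (uniform on its grid under the null, verified by a
200-repetition Kolmogorov–Smirnov check in the acceptance suite).

## Root-state identification

Given per-cell CCAT values: select the floor(0.05·N) highest-CCAT cells
(ties at the boundary broken by cell id; the count is clamped to ≥ 1 with a
warning below N = 20). Embed all cells with a diffusion map: a Gaussian
kernel with per-cell adaptive bandwidth (distance to the κ-th neighbor,
κ = min(30, N/3)), symmetrically normalized and eigendecomposed; the
diffusion components (DCs) are the non-trivial right eigenvectors scaled by
their eigenvalues, with signs fixed by making the largest-magnitude loading
positive so the embedding is deterministic. The selected cells are
clustered on *all* retained DCs (capped at min(N−1, 50) components for
numerical stability) via walktrap community detection — the Pons–Latapy
short-random-walk agglomeration as implemented in igraph, cut at maximum
modularity — on a symmetric Euclidean kNN graph (k = min(10, n_selected−1);
disconnected kNN graphs are clustered per component with a warning). The
walk length is floor(0.25 · n_selected), clamped to ≥ 1, reproducing the
22-cells → length-5 worked example. The root state is the largest cluster
(size ties broken by higher mean CCAT — the most plausible potent root —
then label order) and the root cell its medoid in DC space: "median cell"
is not defined for multivariate coordinates, and the medoid is the standard
analogue that is always an actual cell. Diffusion pseudotime from the root
is the spectral diffusion distance dpt(c)² = Σ_l (λ_l/(1−λ_l))²
(ψ_lc − ψ_l,root)²; a non-trivial eigenvalue of 1 (disconnected kernel
graph) is an error. The embedding is computed on all cells and only the
selected subset is clustered within it; clustering the selected cells in
their own embedding is a documented alternative the API permits by passing
a subset matrix.

## Synthetic data generator

The generator reproduces the two structural features the method relies on,
with known ground truth. (i) Connectomes: Barabási–Albert preferential
attachment (default 200 nodes, 3 edges/node) for the heavy-tailed,
hub-dominated degree structure of real PPI networks; Erdős–Rényi at matched
density as a homogeneous control, bridged to connectivity.
`perturb_network` rewires a fraction of edges (default 0.5) to emulate a
second release of the same resource: degree vectors stay positively but
imperfectly correlated (≈0.8 at the default), which is the regime in which
cross-connectome CCAT agreement is a meaningful, testable claim — two
*independent* random graphs would share no connectome signal and make the
permutation null degenerate. (ii) Expression: per cell c and gene i,
weights w_ic = exp(base_i + β·potency_c·log(1+k_i) + ε_ic) with
base_i ~ N(0, 1.5), noise ε ~ N(0, 0.5), potency ~ Uniform(0, 1) unless
supplied; counts are Poisson draws at library depth 100 over each cell's
weight distribution (negative binomial behind a dispersion flag, since
Poisson under-disperses relative to real data). The log(1+k) coupling
keeps hub overexpression within a realistic dynamic range. β = 2 is the
default hub-coupling strength: strong enough that potency is recoverable
(CCAT AUC ≳ 0.99 between potency quartiles), while β = 0 is an exact null.
The default depth yields 75–80% zeros, inside the 70–90% sparsity band
typical of droplet data while staying below the >95% extremes that make any
measure unstable. The bifurcation variant places a root population
(potency 0.95–1, 20% of cells) and two balanced branches whose potency
falls from 0.8 to 0.05 along a position coordinate, each overexpressing its
own random 20-gene program proportionally to position so that DCs separate
branches. All outputs are bit-reproducible from (parameters, seed) via a
single numpy Generator stream per dataset.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, gene-length or capture biases, and realistic gene-gene correlation
beyond the hub/program structure. Passing tests therefore demonstrate the
internal consistency and statistical behavior of the measures under the
assumed generative mechanism, not performance on any real dataset.

## Problem sizes and numerical choices

Default verification scales: 500 cells × 200 genes for potency-recovery and
dropout analyses (5 and 10 seeds), 200 cells × 50 seeds for root-state
recovery, B = 1000 permutations (B = 99 × 200 repetitions for calibration),
chosen so the full suite runs in seconds while keeping Monte-Carlo error
well inside the asserted margins. Tolerances: row sums and detailed balance
to 1e−10, stationarity to 1e−8 (one matrix-vector product of accumulated
rounding), closed-form entropy rates to 1e−10. Degenerate inputs yield NaN
sentinels with warnings (constant expression profiles, all-zero cells)
rather than silent zeros; batch scoring propagates sentinels without
aborting. Top-n selections (GCS, top-1000 entropy) break ties by input gene
order via stable argsort, a documented dialect choice.

## Known limitations

- CCAT's validity as an SR proxy is topology-dependent; on non-PPI-like
  graphs the correlation can vanish or invert, and the package makes no
  attempt to detect such topologies.
- The GCS smoothing refinement used by some published pipelines is not
  implemented (no published formula); comparisons involving it should treat
  the package's GCS as its unsmoothed base measure.
- The Wilcoxon exact path requires tie-free data; heavily tied small
  samples fall back to the normal approximation.
- `score_all` densifies matrices internally; it is sized for desk-scale
  analyses and synthetic benchmarking, not for millions of cells, although
  CCAT itself is a single pass of vectorized correlations.
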