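# Methods

## Data model

The root input is a binary gene × drug incidence matrix: entry (i, j) is 1
iff gene i participates in the absorption, distribution, metabolism,
elimination or toxicity of drug j.  Each link optionally carries a count of
pharmacogenomic labels (FDA / CPIC / DPWG) backing it; links without labels
default to weight 1 in weighted analyses.  Validation rejects duplicate
identifiers, non-binary entries, label counts on absent links, and isolated
items; after sub-setting operations, items left without links are dropped
with a warning instead, so filtering workflows compose.  When the same
gene-drug pair appears under several label sources the counts are summed
(capping them is equally defensible; summing preserves the total weight of
evidence).  The canonical file format is a long (edge-list) TSV, because
real ADME tables are sparse.

## Posterior-probability (ΔP) analysis

With N drugs total, w_i drugs linked to gene i and c_ij drugs shared by
genes i and j, the marginal is P(X_i) = w_i/N, the conditional
P(X_i|X_j) = c_ij/w_j, and ΔP_ij = P(X_i|X_j) − P(X_i).  Rows index the
responding gene and columns the conditioning gene; the accessor
`delta_p(responding=..., conditioning=...)` names both roles to prevent
transposition mistakes.  Probabilities are raw maximum-likelihood
proportions — no pseudocounts, shrinkage or significance machinery — so
worked examples on printed counts reproduce exactly, at the price of noisy
estimates for low-degree genes (a conditional on a one-drug gene is 0 or
1).  Useful identities, all enforced as invariants: the diagonal of the
conditional matrix is 1, ΔP_ii = 1 − P(X_i), −P(X_i) ≤ ΔP_ij ≤ 1 − P(X_i),
and joint-probability symmetry P(X_i|X_j)P(X_j) = P(X_j|X_i)P(X_i) = c_ij/N.

Heatmap ordering uses Ward-linkage agglomerative clustering on the rows of
the symmetrized ΔP matrix (Euclidean distance, scipy implementation, fully
deterministic); nothing in ΔP itself prescribes an ordering, and Ward on
the symmetrized matrix is the choice that makes mutually-overlapping gene
families contiguous.

## Association-strength network

Genes and drugs form one item set.  Similarity is the association strength
s_ij = c_ij/(w_i·w_j).  Co-occurrence must be defined within type as well
as across types to make the unified matrix meaningful; we use:

* gene-drug: the link weight itself (label count, minimum 1, in weighted
  mode; 1 otherwise);
* gene-gene: Σ over shared drugs of min(link weights) — the plain count of
  shared drugs when weights are 1;
* drug-drug: symmetric, over shared genes.

w_i is the item's (weighted) bipartite degree: its total number of
occurrences in the gene-drug table, not the row sum of the full
co-occurrence matrix.  Multiplying all edge weights by a constant k scales
every c_ij by k and leaves assortativity unchanged (an invariant under
test).

**Assortativity.**  Degree assortativity is the Pearson correlation of the
degrees at the two ends of each edge, with each undirected edge
contributing both orientations; a zero-variance degree sequence raises an
error rather than returning NaN.  The default edge set is the unified item
graph (an edge wherever c_ij > 0) — the graph the map visualizes, in which
drugs sharing a pleiotropic gene form large mutually-connected groups.
This choice is deliberate: at realistic margins (one gene linked to two
thirds of all drugs alongside dozens of single-drug genes) the raw
bipartite edge set is intrinsically disassortative, because the hub
necessarily touches the specialist drugs; the item graph, by contrast,
reflects the core-periphery structure the assortativity claim is about.
The bipartite variant remains available via `graph="bipartite"` and is the
one cross-checked against networkx and a brute-force Pearson oracle.

## Constrained 2D layout

Coordinates minimize V = Σ_{i<j} s_ij‖x_i−x_j‖² subject to
(2/(n(n−1)))Σ_{i<j}‖x_i−x_j‖ = 1.  Without the similarity weight the
objective would be similarity-independent under the constraint and every
input would produce the same map, so the weighted form is the only
meaningful reading.  The constraint only fixes scale: V is homogeneous of
degree 2 and the constraint of degree 1, so the constrained problem is
equivalent up to scale to unconstrained minimization of
G(X) = V(X) − Σ_{i<j}‖x_i−x_j‖.  G is minimized by iterative majorization:
the concave −Σd term is bounded by its tangent at the current
configuration, giving a quadratic surrogate whose minimizer solves
2 L_s X = B(Z)Z (L_s the similarity Laplacian, B(Z) the Laplacian of
all-pairs 1/d_ij weights; the Cholesky factor of L_s + 11ᵀ/n is computed
once).  After each update the configuration is rescaled to the closed-form
scale optimum t* = m/(2V̂) of G, at which G = −m²/(4V̂) with m = n(n−1)/2
and V̂ the objective of the constraint-normalized iterate — so monotone
descent of G implies monotone descent of the reported objective, which the
tests assert iteration by iteration.  Final coordinates are normalized to
constraint value exactly 1.

Numerical choices: initialization uniform on [−0.5, 0.5]² from a
caller-supplied seed (default 42); 5 restarts by default, best objective
kept; convergence when the relative objective decrease drops below tol
(default 1e−8, giving coordinate accuracy around 1e−4 near the optimum —
tighten tol for tighter geometry) or after max_iter = 1000 iterations;
coincident points get zero weight in B(Z), the standard SMACOF convention.
The output gauge is canonical — centroid at the origin, principal axis on
x, reflections fixed by the first item with a nonzero coordinate — so
fixed seeds give bit-identical, comparable coordinates.  If the similarity
graph is disconnected the Laplacian system is solved by least squares
(components are placed independently and overlap near the origin) with a
warning; between-component distances are then not interpretable, but
descent and the constraint still hold.

Clustering of the embedding: k-means (Lloyd, max 300 iterations, tolerance
1e−4, 10 initializations, seeded — scikit-learn) and Ward agglomerative
clustering (scipy, deterministic).  When no k is given, the
silhouette-optimal k in [2, min(15, n−1)] is used; labels are renumbered
by order of first appearance so equivalent partitions compare equal.

## Variability overlay

Each gene node is annotated with its aggregated minor-allele-frequency
score of functional variants (an abstract nonnegative quantity supplied as
input; how it was aggregated upstream is outside this package's scope).
Hotspot score is MAF alone or MAF × degree, with degree the unweighted
drug count; both rankings are deterministic with lexicographic
tie-breaking.  Genes missing from the variability table score 0 (with a
warning) rather than being dropped, keeping layouts complete.  No spatial
density smoothing is applied — hotspots are gene sets, not kernel-density
values — and the hotspot report lists each top gene's nearest map
neighbors as candidate epistasis partners.

## Synthetic data

The generator emulates the structure real ADME surveys show, and its
defaults are the conditions the analysis is validated under: 50 genes ×
200 drugs, 2 planted blocks, p_in = 0.6, p_out = 0.02.  Genes are
partitioned into blocks, drugs into matching groups (standing in for
therapeutic areas); a block gene links its own drugs with p_in and foreign
drugs with p_out, giving within-block pairs an expected Jaccard substrate
overlap of p_in/(2−p_in) against a p_out background.  Optional hub genes
get an elevated link probability everywhere.  Label counts are
1 + Poisson(1) on a Bernoulli(label_rate) subset of links; MAF scores are
log-uniform on [1e−4, 0.5], spanning rare to common functional variation,
with an optional elevated block for hotspot tests.  Isolated items are
repaired with a single probability-proportional link.  Setting
p_in = p_out with one block yields iid Bernoulli links — the independence
control under which mean ΔP vanishes.

The realistic-scale preset (94 genes × 212 drugs) replaces p_in/p_out by
an expected-degree profile: the top four genes target 141/94/92/64 links
and the tail follows 141·rank^−1.25, chosen so that ≈55–70 genes end at
degree ≤ 3; 65% of each gene's expected degree is placed on its own
block's drugs, and an assortative coupling reweights links toward
popular drugs while preserving per-gene expected degrees.

What the generator does **not** emulate: real gene identities and label
provenance, drug chemistry, correlated assay batteries (real phase-2
enzymes are often tested in panels, inflating observed overlap), or the
variant-level structure behind the per-gene MAF score.  Passing tests
therefore demonstrate that the pipeline recovers planted co-metabolism
structure of realistic shape and sparsity, not that any particular real
gene pair interacts.

## Problem sizes in the test and acceptance runs

Oracle comparisons run at enumeration-friendly sizes (ΔP up to 8 genes ×
12 drugs, layout up to 6 items against a generic constrained minimizer,
assortativity up to 12 nodes against networkx).  Structure-recovery runs
use 24 genes × 100 drugs over 10 seeds (adjusted Rand index of k-means on
the gene embedding vs planted blocks); the acceptance script embeds 250
items.  These sizes were chosen so the full suite completes in well under
a minute while leaving each statistical check comfortable margins.

## Known limitations

* ΔP has no uncertainty quantification; a permutation null would be the
  natural extension.
* The layout objective is non-convex; multi-start mitigates but does not
  eliminate local minima (oracle tests show the global optimum is found
  reliably at small n).
* Conditionals on genes with very few drugs are coarse (multiples of
  1/w_j); interpret ΔP for low-degree genes qualitatively.
* Between-component geometry is meaningless when the similarity graph is
  disconnected (warned at fit time).
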