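# Methods

`cladenet` builds signed, weighted gene coexpression networks from a
gene × sample expression matrix, organizes the genes into modules on a
TOM-based dendrogram, and serves driver-gene queries (coexpression clades,
term enrichment, intramodular hubs). This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Network model

**Correlation and adjacency.** Coexpression similarity is the Pearson
correlation r_ij between gene expression profiles. The signed adjacency

    a_ij = ((1 + r_ij) / 2) ** beta

maps r = −1, 0, 1 to 0, 2^−β, 1: strong negative correlation is treated as
evidence *against* a connection rather than folded onto the positives. The
soft-threshold power β (default 14, a conventional choice for signed
networks) can be selected automatically as the smallest candidate power
whose connectivity distribution achieves a scale-free fit index R² ≥ 0.85.
The fit index bins connectivities k_i = Σ_{u≠i} a_iu into 10 equal-width
bins, regresses log10(frequency) on log10(mean k) over non-empty bins, and
signs R² by the negated slope sign so only decaying distributions score
positively. The 0.85 cut and the bin count are parameters, not claims; on
small synthetic matrices (hundreds of genes) no power may qualify, in which
case the best-R² power is returned with a flag.

**Topological overlap.** The TOM similarity

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj

rewards genes that share neighbors, denoising individual edges; 1 − TOM is
the clustering distance. Diagonals are stored as 1 (adjacency and TOM) but
excluded from connectivity sums, so 1 − TOM is a proper self-distance of 0.
Because signed adjacencies are non-negative, the signed and unsigned TOM
formulas coincide and a single formula serves both. TOM is computed in row
blocks (`block_size`, default 2048 rows) so large gene sets never need more
than the adjacency plus one block-by-n product in memory; blocked and dense
results agree to 1e-13 (exact bit-identity is not guaranteed because BLAS
products over different block shapes round differently in the last ulp).
The test suite checks TOM against a literal triple-loop evaluation of the
formula at 1e-10.

## Dendrogram

Average-linkage (UPGMA) hierarchical clustering of the TOM distance builds
a strictly binary, monotone merge tree. The linkage computation is
delegated to scipy's nearest-neighbor-chain implementation; exact distance
ties therefore follow its deterministic merge order (runs are
bit-reproducible, but the tie order is not the lexicographic-pair rule).
Trees serialize to Newick with branch lengths equal to *height
differences* (leaves at height 0), so the leaf-to-root path length equals
the root height and a scale bar reads directly in TOM distance; parsing
recovers node heights as the maximum downstream path length, which is exact
for ultrametric trees. Polytomies and negative branch lengths are rejected:
every tree this package handles is binary.

## Module detection

Detection follows the hybrid dynamic-cut idea with explicit, simple
criteria. Merge heights are normalized between their 5th percentile and the
cut height (0.99 × top merge height). A branch qualifies as a module when

- it has at least `min_cluster_size` leaves (default 15),
- its *core scatter* — the mean normalized height of the merges forming its
  first min(min_cluster_size, size) leaves — is at most
  maxCoreScatter = 0.64 + 0.10 · deep_split, and
- its *gap* — the normalized height at which it attaches to the rest of the
  tree minus its core scatter — is at least (1 − maxCoreScatter) · 3/4.

`deep_split` (0–4, default 2) thus trades sensitivity for robustness. The
tree is decomposed top-down: a branch is split into its two children only
when both qualify, and recursion continues inside each.

**PAM stage.** After the cut, unassigned genes may be adopted by the module
with the smallest mean TOM dissimilarity — but only when that dissimilarity
is within the module's own radius, defined as the largest mean intra-module
dissimilarity over current members. This guard is deliberate: unconditional
nearest-module assignment would empty the unassigned ("grey") set and
absorb pure-noise genes into modules; the radius rule keeps distant
background genes grey while rescuing borderline branch members. Disable
with `pam_stage=False` to keep the raw cut.

**Eigengenes and merging.** A module's eigengene is the first right
singular vector of its gene-standardized (z-scored, ddof=1) submatrix,
scaled to unit variance over samples and sign-oriented to correlate
positively with the module's mean standardized profile; `var_explained` is
the leading singular value's share of total variance. Modules whose
eigengenes are closer than `merge_height` (1 − correlation, default 0.25)
under average linkage are merged, eigengenes are recomputed, and the loop
repeats until no merge occurs — single-pass merging can leave newly-close
pairs, and convergence makes the operation idempotent. At convergence no
surviving pair of eigengenes correlates above 1 − merge_height. Modules are
named by the conventional color palette in descending size order (exact
size ties break on the lexicographically smallest member gene); "grey" is
reserved for unassigned genes and never merged.

## Trait association

Tissue labels are one-hot binarized per sample (multi-label samples are
allowed: each label contributes a 1). Each eigengene is Pearson-correlated
with each binary column — exactly the point-biserial correlation, no
special casing — and the two-sided p-value uses the exact t transform
t = r·sqrt((m−2)/(1−r²)) with m−2 degrees of freedom. Constant trait
columns yield undefined (NaN) associations rather than zeros. No multiple
testing correction is applied across the module × trait grid; the raw p is
always emitted (the `significant` flag uses a configurable α, default
0.05) so downstream users can adjust as they see fit.

## Clade queries

The default clade for a driver gene is the ancestor of its leaf whose
subtree size is closest to 25 genes; exact ties prefer the smaller clade,
which yields more specialized enrichment. Users resize by the count k of
internal nodes between the driver leaf and the clade root; expansion is
capped at ceil(25% of all genes) — an over-cap request returns the largest
in-cap ancestor, flagged truncated — and k = 1 (driver plus sibling
subtree) is the floor: a bare leaf is never returned. The default
selection ignores the cap (on trees under ~100 leaves "closest to 25" can
exceed 25% of the genes; a warning is emitted). The JSON payload carries
the clade Newick, the driver's module color, the per-gene module colors,
and — only when the requested category keyword matches a loaded term
database — the enrichment table sorted by adjusted p; an unknown keyword
skips enrichment silently by design.

## Enrichment

Overrepresentation p-values are upper-tail hypergeometric probabilities
P(X ≥ k), inclusive, via scipy's log-space survival function; the test
suite verifies them against exact rational enumeration for every
configuration with N ≤ 25 at 1e-12 relative. The universe defaults to all
network genes (so "hit percentage" is against the term's occurrence in the
whole dataset); `annotated_universe=True` restricts it to genes annotated
in the category. BH adjustment spans the terms actually tested — those
with ≥ 1 hit; zero-hit terms are untested, not penalized. The displayed
table keeps q ≤ 0.05 (configurable) sorted by (q, p); the unfiltered table
is always available. Hit percentage is 100·k/K and the overrepresentation
rate is (k/n)/(K/N).

## Hub genes (avgRank)

Within a module of n genes, each pair's TOM distance gets a rank among all
M = n(n−1)/2 intra-module pairs (1 = closest, midranks on ties), and

    avgRank_i = (n + 1) / [(n − 1)(M + 1)] · Σ_{j≠i} R_ij.

The normalization is chosen so the score lives on a 1..n scale: tie-free
scores total n(n+1)/2 and each gene expects (n+1)/2 under exchangeability.
The hub set is the minimizer plus every gene strictly within 1 of it.
Because only ranks enter, avgRank is invariant under any strictly monotone
transform of the distances. The formula is isolated in one function so an
alternative normalization is a one-line change.

## Synthetic benchmark

The generator plants a single-factor model per module: latent profile
E_m ~ N(0,1) per sample, shifted additively by `tissue_effect` in the
samples of the module's linked tissue, and gene g in module m expressing
loading_g·E_m + N(0, noise_sd). Background genes are pure noise. The
default configuration — 5 modules × 40 genes, 50 background genes, 60
samples over 5 tissues, loadings U(0.6, 0.95), noise_sd 1.0, seed 42 — is
the package's benchmark condition. `tissue_effect` defaults to 2.5 latent
SD units: a power calculation at 12 samples/tissue gives an expected
eigengene–trait correlation ≈ 0.7 (p ≈ 1e−9), the regime a tissue-specific
module in a curated compendium plausibly occupies. The generator records
the realized within-vs-between correlation separation so tests can assert
the planted structure is present (≥ 0.3 at the defaults).

Under this model the true eigengene, the true module–tissue link and the
true hub (max loading) are analytically known. What passing benchmarks
*show*: the pipeline recovers well-separated block structure, leaves noise
genes grey, orients eigengenes correctly, and ranks genuinely central genes
first. What they do *not* show: behaviour under correlated backgrounds,
batch effects, probe-level artifacts, overlapping modules, or compendium-
scale gene counts — none of which the generator emulates.

**A known statistical limit.** Identifying the single max-loading gene of
a module as a hub is not generally possible at benchmark scale: with 40
loadings drawn U(0.6, 0.95), the expected gap between the top two order
statistics (≈ 0.009) induces a correlation contrast far below the sampling
error of correlations at 60 samples (≈ 0.1). At population correlations
the avgRank minimizer *is* always the max-loading gene (verified), and the
designed-margin experiment in the test suite — one gene with clearly
smaller residual noise — recovers its hub in ≥ 90% of seeds. Treat hub
calls on small sample counts as a shortlist, not an identification.

## Problem sizes and numerical conventions

The shipped tests and the acceptance script run at desk scale by choice:
networks of 90–250 genes, 20 replicate seeds, 1000-tree clade audits,
exhaustive hypergeometric enumeration to N = 25. Matrix-equality checks
use 1e-10 against loop oracles, Newick round-trips 1e-9, closed-form
p-values 1e-12. Standardization uses ddof=1 throughout. Correlations are
clipped to [−1, 1] and symmetrized before use; TOM is clipped to [0, 1].
All randomness flows from explicit integer seeds; repeated runs are
reproducible to the byte.

## Known limitations

- Distance ties in average linkage follow scipy's deterministic merge
  order, not a documented lexicographic rule.
- The dynamic cut's branch statistics are recomputed by subtree traversal;
  on very deep (tens of thousands of leaves, heavily ladderized) trees this
  is quadratic in the worst case.
- Newick serialization recurses over the tree and is limited by the Python
  recursion limit (~1000 nested clades) for extremely ladderized trees.
- Static cut-height module detection is not offered; only the hybrid
  dynamic cut is implemented.
- Module membership is exclusive; overlapping or fuzzy membership is out of
  scope.
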