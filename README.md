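# cladenet

Signed, weighted gene coexpression networks with TOM dendrograms, module
detection, trait association, coexpression-clade queries, term enrichment
and intramodular hub ranking.

`cladenet` is for researchers who study condition-independent gene
coexpression — typically over a curated compendium of expression samples
spanning many tissues — and want to go from an expression matrix to
answerable questions: *which genes travel with my gene of interest, which
module do they form, which tissues express that module, which biological
terms are overrepresented in it, and which genes sit at its center?*

## The model

From a gene × sample matrix, Pearson correlations r_ij become a signed
weighted adjacency

    a_ij = ((1 + r_ij) / 2)^β        (β = 14 by default, or chosen so the
                                      connectivity distribution is
                                      approximately scale-free)

and the Topological Overlap Matrix blends direct edges with shared
neighbors:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,  k_i = Σ_{u≠i} a_iu.

Average-linkage clustering of 1 − TOM gives a binary dendrogram (exported
as Newick). Modules are cut from it with a hybrid dynamic tree cut
(minimum size 15, deepSplit 2), merged when their eigengenes — first
principal components of the module expression — correlate above 0.75
(dissimilarity < 0.25), and named by the conventional color palette.
Module eigengenes are correlated with one-hot tissue traits (point-biserial
PCC with exact t-based p-values). Queries return the dendrogram clade
around a driver gene closest to 25 genes (resizable by internal-node count
up to 25% of the genes), hypergeometric term enrichment with BH-FDR
(display cut q ≤ 0.05, hit percentage, overrepresentation rate), and hub
genes ranked by

    avgRank_i = (n + 1) / [(n − 1)(M + 1)] · Σ_{j≠i} R_ij,

the rescaled sum of each gene's intra-module TOM-distance ranks (hub set =
within 1 of the minimum on the 1..n scale).

See `docs/methods.md` for assumptions, parameter semantics and numerical
conventions.

## Worked example

Everything below is runnable offline: the `simulate` command generates a
benchmark with five planted modules (40 genes each plus 50 noise genes, 60
samples over 5 tissues) whose true structure is recorded alongside.

```sh
cladenet simulate --out demo/data
# simulated 250 genes x 60 samples (separation 0.619) -> demo/data

cladenet build --expr demo/data/expression.tsv \
               --traits demo/data/traits.tsv --out demo/bundle
# built bundle: beta=14, 5 modules -> demo/bundle
```

The bundle directory now holds the correlation/adjacency/TOM matrices with
JSON sidecars, the Newick tree, the gene → module-color table, eigengenes,
eigengene–trait correlations and a manifest. Query a driver gene:

```sh
cladenet query --bundle demo/bundle --driver AT1G00010 \
               --enrich bp --db demo/data/terms.gmt
```

```json
{
 "driver": {"id": "AT1G00010", "module": "turquoise"},
 "clade": {"k_internal": 1, "n_genes": 39, "truncated": false},
 "genes": [{"id": "AT1G00010", "module": "turquoise"}, "..."],
 "enrichment": [
  {"term_id": "MOD0000", "description": "planted module 0 process",
   "p": 5.93e-34, "q": 1.25e-32, "k_hit": 32, "K": 32, "n_set": 39,
   "N": 250, "hit_pct": 100.0, "overrep": 6.41}
 ]
}
```

Reading it: the driver's default clade (the ancestor subtree closest to 25
genes; here its first ancestor already holds 39) is almost entirely
turquoise-module genes, and the term annotating planted module 0 tops the
enrichment table — all 32 of its annotated genes fall inside the 39-gene
clade (hit 100%), a 6.4-fold overrepresentation against the 250-gene
universe. The module's central genes:

```sh
cladenet hubs --bundle demo/bundle --module turquoise
#      gene  avg_rank  is_hub
# AT3G00130  6.575561    True
# AT5G00300  7.027841    True
# AT3G00230 10.168226   False
# ...
```

Two genes sit within one avgRank unit of the top-ranking gene and are
flagged as the module's intramodular hubs. `cladenet module-page` combines
the trait correlations, the per-category enrichment, and this ranked table
into one JSON document; the same payloads are available from Python via
`cladenet.api_payload(...)` and friends, and the whole pipeline is a
scikit-learn-style estimator:

```python
from cladenet import CoexpressionNetwork, generate
expr, design, truth = generate()
model = CoexpressionNetwork(beta=14, min_cluster_size=15).fit(expr)
model.module_colors_   # ['turquoise', 'blue', 'brown', 'yellow', 'green']
model.eigengenes_      # module x sample DataFrame
```

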