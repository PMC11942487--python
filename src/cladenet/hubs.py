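"""Intramodular hub genes by average distance rank (avgRank).

Within a module of n genes, every pair (i, j) gets the rank R_ij of its TOM
distance among all M = n(n−1)/2 intra-module pair distances (1 = closest
pair; exact ties receive midranks). A gene's centrality is

    avgRank_i = (n + 1) / [(n − 1) (M + 1)] · Σ_{j≠i} R_ij,

a rescaled rank-sum living on the 1..n scale: with tie-free distances the
scores total n(n+1)/2 and under exchangeability each gene expects (n+1)/2.
Lower is more central. The hub set is the top-ranking gene together with
every gene whose avgRank lies strictly within 1 of it.

Because avgRank depends on distances only through their ranks, it is
invariant under any strictly monotone transform of the distance matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = ["distance_ranks", "avg_rank", "hub_genes", "hub_table", "module_page"]


def distance_ranks(dist: np.ndarray) -> np.ndarray:
    """Rank matrix of intra-module pair distances (midranks on ties).

    ``R[i, j]`` (i ≠ j) is the rank of d(i, j) among the n(n−1)/2 pair
    distances, smallest = 1; the diagonal is 0 and unused.
    """
    d = np.asarray(dist, dtype=np.float64)
    n = d.shape[0]
    if n < 2:
        raise ValueError("a module needs at least 2 genes")
    condensed = squareform(d, checks=True)
    ranks = rankdata(condensed, method="average")
    R = squareform(ranks, checks=False)
    return R


def avg_rank(R: np.ndarray) -> np.ndarray:
    """avgRank score per gene from a pair-distance rank matrix."""
    R = np.asarray(R, dtype=np.float64)
    n = R.shape[0]
    M = n * (n - 1) // 2
    return (n + 1) / ((n - 1) * (M + 1)) * R.sum(axis=1)


def hub_genes(scores: np.ndarray) -> np.ndarray:
    """Boolean hub mask: avgRank within (strictly) 1 of the minimum."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no scores")
    return scores - scores.min() < 1.0


def hub_table(dist: np.ndarray, genes: list[str]) -> pd.DataFrame:
    """Full hub table of a module: gene, avg_rank, is_hub, sorted ascending."""
    if len(genes) != dist.shape[0]:
        raise ValueError("gene list does not match distance matrix")
    scores = avg_rank(distance_ranks(dist))
    hubs = hub_genes(scores)
    tab = pd.DataFrame({"gene": genes, "avg_rank": scores, "is_hub": hubs})
    return tab.sort_values(["avg_rank", "gene"], kind="stable").reset_index(drop=True)


def module_page(bundle, module_color: str, fdr_cut: float = 0.05) -> dict:
    """Assemble the module-page document for one module.

    Contains the module's eigengene–trait associations, per-category term
    enrichment of its genes, and the full gene table ranked by avgRank with
    hub flags.
    """
    from .enrichment import enrich

    part = bundle.partition
    if module_color not in part.colors:
        raise KeyError(f"unknown module color {module_color!r}")
    members = part.members(module_color)
    idx = [bundle.gene_index[g] for g in members]
    sub = bundle.tom_dist[np.ix_(idx, idx)]
    table = hub_table(sub, members)

    doc: dict = {
        "schema_version": 1,
        "module": module_color,
        "n_genes": len(members),
        "var_explained": float(part.var_explained[module_color]),
        "genes": table.to_dict(orient="records"),
    }
    if bundle.trait_table is not None:
        tt = bundle.trait_table
        mine = tt[tt["module"] == module_color]
        doc["trait_associations"] = [
            {
                "trait": row["trait"],
                "r": None if pd.isna(row["r"]) else float(row["r"]),
                "p": None if pd.isna(row["p"]) else float(row["p"]),
                "significant": bool(row["significant"]),
            }
            for _, row in mine.iterrows()
        ]
    doc["enrichment"] = {
        cat: enrich(members, db, bundle.gene_ids, fdr_cut=fdr_cut).table.to_dict(
            orient="records"
        )
        for cat, db in bundle.term_dbs.items()
    }
    return doc
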