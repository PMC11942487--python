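"""Hypergeometric overrepresentation analysis with BH-FDR adjustment.

For a query gene set of size n drawn from an N-gene universe, a term
annotating K universe genes and hitting k of the query genes gets the
upper-tail probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

adjusted across all tested terms of the category by Benjamini–Hochberg.
Two descriptive ratios accompany each term: the hit percentage 100·k/K
(how much of the term's overall occurrence falls inside the query) and the
overrepresentation rate (k/n)/(K/N) (observed vs expected frequency).
Only terms with an adjusted p ≤ 0.05 are displayed by default; the
unfiltered table is always available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import TermDatabase

__all__ = ["hypergeom_upper", "bh_adjust", "enrich", "EnrichmentResult"]

TABLE_COLUMNS = [
    "term_id", "description", "p", "q", "k_hit", "K", "n_set", "N",
    "hit_pct", "overrep",
]


def hypergeom_upper(N: int, K: int, n_set: int, k_hit: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k_hit), inclusive.

    ``N`` universe genes of which ``K`` carry the term; ``n_set`` genes
    drawn; probability of observing at least ``k_hit`` annotated genes.
    """
    if not (0 <= K <= N):
        raise ValueError("need 0 <= K <= N")
    if not (0 <= n_set <= N):
        raise ValueError("need 0 <= n_set <= N")
    if not (0 <= k_hit <= min(K, n_set)):
        raise ValueError("need 0 <= k_hit <= min(K, n_set)")
    if k_hit == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_hit - 1, N, K, n_set))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Filtered display table plus the full tested table."""

    table: pd.DataFrame  # q <= fdr_cut, sorted by (q, p)
    full: pd.DataFrame  # all tested terms (k_hit >= 1)
    n_set: int
    N: int


def enrich(
    gene_set,
    db: TermDatabase,
    universe,
    fdr_cut: float = 0.05,
    annotated_universe: bool = False,
) -> EnrichmentResult:
    """Overrepresentation of ``gene_set`` against one term category.

    Parameters
    ----------
    gene_set
        Query gene identifiers (order-irrelevant; duplicates ignored).
    db
        Term database for one category.
    universe
        Background gene identifiers (typically all network genes). Query
        genes outside the universe are dropped before testing.
    fdr_cut
        Display threshold on the BH-adjusted p (default 0.05).
    annotated_universe
        Restrict the universe to genes annotated by at least one term of
        the category (off by default: the background is the full dataset).

    Notes
    -----
    BH adjustment spans the terms actually tested — those with at least one
    hit; zero-hit terms are untested, not penalized.
    """
    universe = list(dict.fromkeys(str(g) for g in universe))
    if annotated_universe:
        ann = db.genes()
        universe = [g for g in universe if g in ann]
    uni = set(universe)
    query = {str(g) for g in gene_set} & uni
    N, n_set = len(uni), len(query)
    if n_set == 0:
        warnings.warn("query gene set does not intersect the universe", stacklevel=2)
        empty = pd.DataFrame(columns=TABLE_COLUMNS)
        return EnrichmentResult(table=empty, full=empty.copy(), n_set=0, N=N)

    rows = []
    for term, (desc, genes) in db.terms.items():
        term_genes = genes & uni
        K = len(term_genes)
        k = len(term_genes & query)
        if k < 1:
            continue
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "p": hypergeom_upper(N, K, n_set, k),
                "k_hit": k,
                "K": K,
                "n_set": n_set,
                "N": N,
                "hit_pct": 100.0 * k / K,
                "overrep": (k / n_set) / (K / N),
            }
        )
    full = pd.DataFrame(rows)
    if full.empty:
        empty = pd.DataFrame(columns=TABLE_COLUMNS)
        return EnrichmentResult(table=empty, full=empty.copy(), n_set=n_set, N=N)
    full["q"] = bh_adjust(full["p"].to_numpy())
    full = full[TABLE_COLUMNS].sort_values(["q", "p", "term_id"]).reset_index(drop=True)
    table = full[full["q"] <= fdr_cut].reset_index(drop=True)
    return EnrichmentResult(table=table, full=full, n_set=n_set, N=N)
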