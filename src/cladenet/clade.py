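"""Driver-gene coexpression clades and the JSON query payload.

A query names a driver gene; the answer is the subtree (clade) of the TOM
dendrogram rooted at one of the driver leaf's ancestors. The default clade
is the ancestor whose leaf count is closest to 25 genes (ties prefer the
smaller clade — smaller subtrees yield more specialized enrichment). Users
may resize by choosing the number of internal nodes k between the driver
leaf and the clade root: expansion is capped at 25% of all genes (the
largest in-cap ancestor is returned, flagged, when the request exceeds it),
and k = 1 (driver plus its sibling subtree) is the smallest clade — a bare
leaf is never returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from pydantic import BaseModel

from .tree import Dendrogram

__all__ = [
    "Clade",
    "default_clade",
    "resize_clade",
    "api_payload",
    "ApiPayload",
]

DEFAULT_TARGET = 25
MAX_FRACTION = 0.25


@dataclass
class Clade:
    driver: str
    k_internal: int
    root_node: int
    genes: list[str]
    newick: str
    truncated: bool = False

    @property
    def size(self) -> int:
        return len(self.genes)


def _clade_at(tree: Dendrogram, driver: str, k: int, truncated: bool) -> Clade:
    node = tree.ancestors(driver)[k - 1]
    return Clade(
        driver=driver,
        k_internal=k,
        root_node=int(node),
        genes=tree.leaf_set(node),
        newick=tree.to_newick(node),
        truncated=truncated,
    )


def default_clade(tree: Dendrogram, driver: str, target: int = DEFAULT_TARGET) -> Clade:
    """Ancestor clade of the driver with leaf count closest to ``target``.

    Scans the driver's ancestor chain (parent to root) and picks the node
    minimizing |leaf count − target|; exact ties go to the smaller clade.
    """
    chain = tree.ancestors(driver)
    counts = [int(tree.leaf_count[a]) for a in chain]
    best_k = min(
        range(1, len(chain) + 1),
        key=lambda k: (abs(counts[k - 1] - target), counts[k - 1]),
    )
    if counts[best_k - 1] > math.ceil(MAX_FRACTION * tree.n_leaves):
        warnings.warn(
            "default clade exceeds the 25% expansion cap (small tree); "
            "cap waived for the default selection",
            stacklevel=2,
        )
    return _clade_at(tree, driver, best_k, truncated=False)


def resize_clade(
    tree: Dendrogram,
    driver: str,
    k_internal: int,
    max_fraction: float = MAX_FRACTION,
) -> Clade:
    """Clade at the ``k_internal``-th ancestor of the driver, cap-limited.

    If the requested ancestor holds more than ceil(max_fraction · n) leaves,
    the largest ancestor within the cap is returned instead (or the first
    ancestor when even it exceeds the cap) and the clade is flagged
    truncated. Requests beyond the driver's depth clamp to the deepest
    in-cap ancestor, also flagged.
    """
    if k_internal < 1:
        raise ValueError("k_internal must be >= 1")
    chain = tree.ancestors(driver)
    counts = [int(tree.leaf_count[a]) for a in chain]
    cap = math.ceil(max_fraction * tree.n_leaves)
    truncated = False
    k = k_internal
    if k > len(chain):
        k = len(chain)
        truncated = True
    if counts[k - 1] > cap:
        within = [kk for kk in range(1, k + 1) if counts[kk - 1] <= cap]
        k = within[-1] if within else 1
        truncated = True
    return _clade_at(tree, driver, k, truncated=truncated)


# ---------------------------------------------------------------------------
# JSON payload

class DriverInfo(BaseModel):
    id: str
    module: str
    description: str | None = None


class CladeInfo(BaseModel):
    newick: str
    k_internal: int
    n_genes: int
    truncated: bool


class GeneEntry(BaseModel):
    id: str
    module: str


class EnrichmentEntry(BaseModel):
    term_id: str
    description: str
    p: float
    q: float
    k_hit: int
    K: int
    n_set: int
    N: int
    hit_pct: float
    overrep: float


class ApiPayload(BaseModel):
    """Schema of the driver-query JSON document (version 1)."""

    schema_version: int = 1
    driver: DriverInfo
    clade: CladeInfo
    genes: list[GeneEntry]
    enrichment: list[EnrichmentEntry] | None = None


def api_payload(
    bundle,
    driver: str,
    k_internal: int | None = None,
    category: str | None = None,
    fdr_cut: float = 0.05,
) -> dict:
    """Answer a driver-gene query as a JSON-serializable document.

    ``k_internal=None`` selects the default (closest-to-25) clade. The
    enrichment block appears only when ``category`` names a loaded term
    database; an unknown or missing keyword silently skips enrichment.
    Unknown drivers yield a structured error document instead of raising.
    """
    from .enrichment import enrich

    tree = bundle.tree
    try:
        tree.leaf_index(driver)
    except KeyError as exc:
        return {"error": str(exc), "driver": driver}
    if k_internal is None:
        clade = default_clade(tree, driver)
    else:
        clade = resize_clade(tree, driver, k_internal)
    assignment = bundle.partition.assignment
    payload = ApiPayload(
        driver=DriverInfo(id=driver, module=str(assignment[driver])),
        clade=CladeInfo(
            newick=clade.newick,
            k_internal=clade.k_internal,
            n_genes=clade.size,
            truncated=clade.truncated,
        ),
        genes=[GeneEntry(id=g, module=str(assignment[g])) for g in clade.genes],
    )
    if category is not None and category in bundle.term_dbs:
        res = enrich(
            clade.genes, bundle.term_dbs[category], bundle.gene_ids, fdr_cut=fdr_cut
        )
        payload.enrichment = [
            EnrichmentEntry(**row) for row in res.table.to_dict(orient="records")
        ]
    return payload.model_dump(exclude_none=True)
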