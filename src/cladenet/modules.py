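"""Module detection on the TOM dendrogram and module eigengenes.

Detection follows the hybrid dynamic-cut idea: the dendrogram is decomposed
into candidate branches; a branch is accepted as a module when it is large
enough (``min_cluster_size``), internally tight (core scatter below a
``deep_split``-controlled ceiling) and clearly separated from its
surroundings (gap above a floor). An optional PAM-like stage then adopts
unassigned genes into the module they are closest to, but only when they lie
within that module's own radius — distant background genes stay "grey".

Each module is summarized by its eigengene, the first principal component of
the gene-standardized submatrix, sign-oriented to correlate positively with
the module's mean profile. Modules whose eigengenes are closer than
``merge_height`` (1 − correlation) are merged, iterating to convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._palette import GREY, PALETTE, color_name
from .tree import Dendrogram

log = logging.getLogger("cladenet")

__all__ = [
    "CutParams",
    "ModulePartition",
    "dynamic_tree_cut",
    "module_eigengene",
    "merge_close_modules",
    "assign_colors",
    "build_partition",
]

UNASSIGNED = -1


@dataclass
class CutParams:
    """Module detection and merging parameters.

    ``deep_split`` (0–4) trades module sensitivity against robustness via
    maxCoreScatter = 0.64 + 0.10·deep_split and
    minGap = (1 − maxCoreScatter)·3/4, on merge heights normalized between
    their 5th percentile and the cut height (0.99 × top merge height).
    """

    min_cluster_size: int = 15
    deep_split: int = 2
    pam_stage: bool = True
    merge_height: float = 0.25
    cut_height: float | None = None  # default 0.99 × max merge height

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be in {0,1,2,3,4}")
        if not (0.0 <= self.merge_height <= 1.0):
            raise ValueError("merge_height must lie in [0, 1]")

    @property
    def max_core_scatter(self) -> float:
        return 0.64 + 0.10 * self.deep_split

    @property
    def min_gap(self) -> float:
        return (1.0 - self.max_core_scatter) * 3.0 / 4.0


# ---------------------------------------------------------------------------
# dynamic tree cut

def dynamic_tree_cut(
    tree: Dendrogram,
    dist: np.ndarray,
    params: CutParams | None = None,
) -> np.ndarray:
    """Hybrid dynamic cut of a dendrogram into module labels.

    Parameters
    ----------
    tree
        Dendrogram whose leaves are the genes (in distance-matrix order).
    dist
        TOM distance matrix aligned to ``tree.leaf_names``.
    params
        Cut parameters; the benchmark defaults are min_cluster_size=15,
        deep_split=2, pam_stage on.

    Returns
    -------
    numpy.ndarray
        Integer label per leaf; ``-1`` marks unassigned ("grey") genes.
        Labels are numbered in branch-discovery order (renumber with
        :func:`assign_colors` for reporting).
    """
    params = params or CutParams()
    n = tree.n_leaves
    dist = np.asarray(dist, dtype=np.float64)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match tree leaves")

    merge_h = tree.heights[n:]
    top = float(merge_h.max())
    cut = params.cut_height if params.cut_height is not None else 0.99 * top
    lo = float(np.percentile(merge_h, 5.0))
    hi = cut
    span = hi - lo

    def norm(h: float) -> float:
        if span <= 0:
            return 0.0
        return float(np.clip((h - lo) / span, 0.0, 1.0))

    def core_scatter(v: int) -> float:
        """Mean normalized height of the merges forming the branch core."""
        size = int(tree.leaf_count[v])
        m = min(params.min_cluster_size, size)
        hs = tree.internal_heights(v)[: max(m - 1, 1)]
        return float(np.mean([norm(h) for h in hs]))

    def qualifies(v: int, attach_h: float) -> bool:
        if tree.is_leaf(v) or tree.leaf_count[v] < params.min_cluster_size:
            return False
        cs = core_scatter(v)
        gap = norm(attach_h) - cs
        return cs <= params.max_core_scatter and gap >= params.min_gap

    def split(v: int) -> list[int]:
        """Decompose a branch into units; children split only when both qualify."""
        units, stack = [], [v]
        while stack:
            u = stack.pop()
            if tree.is_leaf(u):
                units.append(u)
                continue
            l, r = (int(c) for c in tree.children[u])
            h = float(tree.heights[u])
            if qualifies(l, h) and qualifies(r, h):
                stack.extend((r, l))
            else:
                units.append(u)
        return units

    # components under the cut height
    components: list[int] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if not tree.is_leaf(v) and tree.heights[v] > cut:
            stack.extend(int(c) for c in tree.children[v])
        else:
            components.append(v)

    labels = np.full(n, UNASSIGNED, dtype=np.intp)
    next_label = 0
    for comp in components:
        attach = float(tree.heights[tree.parent[comp]]) if tree.parent[comp] != -1 else hi
        for unit in split(comp):
            if qualifies(unit, min(attach, hi) if unit == comp else float(tree.heights[tree.parent[unit]])):
                for leaf in tree._leaf_ids(unit):
                    labels[leaf] = next_label
                next_label += 1

    if params.pam_stage and next_label > 0:
        labels = _pam_assign(labels, dist)

    sizes = np.bincount(labels[labels >= 0], minlength=next_label)
    log.info(
        "dynamic cut: %d modules (sizes %s), %d grey",
        next_label, sizes.tolist(), int((labels == UNASSIGNED).sum()),
    )
    return labels


def _pam_assign(labels: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Adopt unassigned genes into nearby modules.

    A grey gene joins the module with the smallest mean dissimilarity, but
    only if that dissimilarity does not exceed the module's radius — the
    largest mean intra-module dissimilarity over current members. Genes
    outside every module's radius stay grey.
    """
    labels = labels.copy()
    mods = np.unique(labels[labels >= 0])
    radius = {}
    mean_to = {}
    for m in mods:
        members = labels == m
        sub = dist[np.ix_(members, members)]
        k = members.sum()
        within = sub.sum(axis=1) / max(k - 1, 1)
        radius[m] = float(within.max())
        mean_to[m] = dist[:, members].mean(axis=1)
    grey = np.flatnonzero(labels == UNASSIGNED)
    for g in grey:
        dists = {m: mean_to[m][g] for m in mods}
        best = min(dists, key=lambda m: (dists[m], m))
        if dists[best] <= radius[best]:
            labels[g] = best
    return labels


# ---------------------------------------------------------------------------
# eigengenes

def _standardize_rows(arr: np.ndarray) -> np.ndarray:
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant gene")
    return (arr - mu) / sd


def module_eigengene(
    expr: pd.DataFrame, member_genes: list[str]
) -> tuple[np.ndarray, float]:
    """Eigengene (first PC over samples) of a module's genes.

    The gene × sample submatrix is gene-standardized, its first right
    singular vector is scaled to unit variance over samples and sign-oriented
    to correlate positively with the module's mean standardized expression.

    Returns
    -------
    (eigengene, var_explained)
        ``eigengene`` has one value per sample; ``var_explained`` is the
        leading singular value's share of total variance, in [0, 1].
    """
    missing = [g for g in member_genes if g not in expr.index]
    if missing:
        raise KeyError(f"module genes absent from expression: {missing[:10]}")
    if len(member_genes) == 0:
        raise ValueError("module must have at least one gene")
    sub = _standardize_rows(expr.loc[member_genes].to_numpy(dtype=np.float64))
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    e = vt[0]
    mean_profile = sub.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    sd = e.std(ddof=1)
    if sd > 0:
        e = e / sd
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return e, var_explained


# ---------------------------------------------------------------------------
# merging and colors

@dataclass
class ModulePartition:
    """Final module assignment with eigengenes and merge history."""

    assignment: pd.Series  # gene id -> color name (GREY for unassigned)
    colors: list[str]  # descending module size, palette order
    eigengenes: pd.DataFrame  # color × sample
    var_explained: pd.Series  # per color
    merge_log: list[dict] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return len(self.colors)

    def members(self, color: str) -> list[str]:
        if color not in self.colors and color != GREY:
            raise KeyError(f"unknown module color {color!r}")
        return self.assignment.index[self.assignment == color].tolist()

    def sizes(self) -> pd.Series:
        return self.assignment[self.assignment != GREY].value_counts().reindex(self.colors)


def _eigengene_matrix(
    expr: pd.DataFrame, labels: np.ndarray, genes: list[str], mods: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    eig = np.empty((len(mods), expr.shape[1]))
    ve = np.empty(len(mods))
    for i, m in enumerate(mods):
        members = [g for g, lab in zip(genes, labels) if lab == m]
        eig[i], ve[i] = module_eigengene(expr, members)
    return eig, ve


def merge_close_modules(
    expr: pd.DataFrame,
    labels: np.ndarray,
    merge_height: float = 0.25,
) -> tuple[np.ndarray, list[dict]]:
    """Merge modules whose eigengenes are closer than ``merge_height``.

    Eigengene dissimilarity is 1 − Pearson correlation; modules are clustered
    by average linkage and every cluster joined below ``merge_height`` is
    merged. Eigengenes are recomputed between rounds and the loop runs until
    no merge occurs. Grey genes are untouched.
    """
    genes = [str(g) for g in expr.index]
    labels = np.asarray(labels, dtype=np.intp).copy()
    merge_log: list[dict] = []
    while True:
        mods = np.unique(labels[labels >= 0])
        if len(mods) < 2:
            break
        eig, _ = _eigengene_matrix(expr, labels, genes, mods)
        diss = 1.0 - np.corrcoef(eig)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        Z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(Z, t=merge_height, criterion="distance")
        if len(np.unique(groups)) == len(mods):
            break
        round_merges = []
        for gid in np.unique(groups):
            member_mods = mods[groups == gid]
            if len(member_mods) > 1:
                keep = int(member_mods[0])
                for m in member_mods[1:]:
                    labels[labels == m] = keep
                round_merges.append([int(m) for m in member_mods])
        merge_log.append({"merged": round_merges})
        log.info("merge round: %s", round_merges)
    return labels, merge_log


def assign_colors(labels: np.ndarray, genes: list[str]) -> dict[int, str]:
    """Map integer module labels to palette color names.

    Modules are ordered by descending size; exact size ties are broken by the
    lexicographically smallest member gene id, so coloring is deterministic.
    """
    labels = np.asarray(labels)
    mods = np.unique(labels[labels >= 0])
    def key(m: int):
        members = [g for g, lab in zip(genes, labels) if lab == m]
        return (-len(members), min(members))
    ordered = sorted((int(m) for m in mods), key=key)
    return {m: color_name(i) for i, m in enumerate(ordered)}


_PALETTE_RANK = {c: i for i, c in enumerate(PALETTE)}


def _color_rank(color: str) -> int:
    if color in _PALETTE_RANK:
        return _PALETTE_RANK[color]
    return 10**6 + int(color.removeprefix("module"))


def build_partition(
    expr: pd.DataFrame,
    labels: np.ndarray,
    merge_log: list[dict] | None = None,
) -> ModulePartition:
    """Assemble a :class:`ModulePartition` (colors, eigengenes) from labels."""
    genes = [str(g) for g in expr.index]
    color_of = assign_colors(labels, genes)
    assignment = pd.Series(
        [color_of.get(int(lab), GREY) for lab in labels], index=genes, name="module_color"
    )
    colors = sorted(color_of.values(), key=_color_rank)  # palette rank == size order
    eig_rows, ve_rows = [], []
    for c in colors:
        e, v = module_eigengene(expr, assignment.index[assignment == c].tolist())
        eig_rows.append(e)
        ve_rows.append(v)
    eigengenes = pd.DataFrame(eig_rows, index=colors, columns=expr.columns)
    var_explained = pd.Series(ve_rows, index=colors, name="var_explained")
    return ModulePartition(
        assignment=assignment,
        colors=colors,
        eigengenes=eigengenes,
        var_explained=var_explained,
        merge_log=merge_log or [],
    )
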