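"""Signed weighted network construction: correlation, soft threshold, TOM.

The network is built in three steps. Pearson correlations r_ij between gene
expression profiles are rescaled and raised to a soft-threshold power,

    a_ij = ((1 + r_ij) / 2) ** beta            (signed adjacency),

so that strong positive coexpression keeps high weight while negative
correlation decays toward zero instead of folding onto the positives. The
power ``beta`` is chosen so the connectivity distribution approximates
scale-free topology (signed R² of the log-log fit above a cut, conventionally
0.85). The Topological Overlap Matrix then blends direct adjacency with
shared-neighbor agreement,

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

and 1 − TOM is the clustering distance. Diagonals: adjacency and TOM are
stored with unit diagonal, but the diagonal is excluded from connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkParams",
    "GeneNetwork",
    "pearson_matrix",
    "signed_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
    "tom_distance",
    "build_network",
]

_SYM_TOL = 1e-8


@dataclass
class NetworkParams:
    """Construction parameters for a signed weighted network."""

    beta: int = 14
    r2_cut: float = 0.85
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    network_type: str = "signed"
    n_bins: int = 10
    block_size: int = 2048

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0.0 < self.r2_cut <= 1.0):
            raise ValueError("r2_cut must lie in (0, 1]")


@dataclass
class GeneNetwork:
    """Correlation, adjacency and TOM matrices over a fixed gene order."""

    gene_ids: list[str]
    beta: int
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    connectivity: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.connectivity is None:
            self.connectivity = connectivity(self.adjacency)

    @property
    def tom_dist(self) -> np.ndarray:
        return tom_distance(self.tom)


def _as_gene_matrix(expr) -> tuple[np.ndarray, list[str]]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=np.float64), [str(g) for g in expr.index]
    arr = np.asarray(expr, dtype=np.float64)
    return arr, [f"g{i}" for i in range(arr.shape[0])]


def pearson_matrix(expr) -> np.ndarray:
    """Pearson correlation between all gene rows.

    Raises if any gene has zero variance (its correlation is undefined).
    """
    arr, genes = _as_gene_matrix(expr)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = arr.std(axis=1)
    if np.any(sd == 0.0):
        bad = [genes[i] for i in np.flatnonzero(sd == 0.0)]
        raise ValueError(f"zero-variance genes: {bad[:10]}")
    r = np.corrcoef(arr)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def signed_adjacency(correlation: np.ndarray, beta: int) -> np.ndarray:
    """Signed adjacency a = ((1 + r)/2)^beta, elementwise in [0, 1]."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = np.asarray(correlation, dtype=np.float64)
    if np.any(r < -1.0 - 1e-12) or np.any(r > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + r) / 2.0) ** beta
    np.clip(a, 0.0, 1.0, out=a)
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Per-gene connectivity k_i = Σ_{u≠i} a_iu (diagonal excluded)."""
    a = np.asarray(adjacency, dtype=np.float64)
    return a.sum(axis=1) - np.diag(a)


@dataclass
class ScaleFreeFit:
    r2: float  # signed: −sign(slope)·R²
    slope: float
    intercept: float
    n_bins_used: int


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit index of a connectivity distribution.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity) over non-empty
    bins and the R² is signed by the negated slope sign, so a decaying
    (scale-free-like) distribution scores positively.
    """
    k = np.asarray(connectivity, dtype=np.float64)
    if np.any(k < 0):
        raise ValueError("connectivities must be non-negative")
    lo, hi = float(k.min()), float(k.max())
    if lo == hi:
        raise ValueError("degenerate histogram: all connectivities equal")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    keep = counts > 0
    mean_k = sums[keep] / counts[keep]
    freq = counts[keep] / k.size
    ok = mean_k > 0
    mean_k, freq = mean_k[ok], freq[ok]
    if mean_k.size < 2 or np.unique(np.log10(mean_k)).size < 2:
        raise ValueError("too few usable bins for the log-log fit")
    res = stats.linregress(np.log10(mean_k), np.log10(freq))
    return ScaleFreeFit(
        r2=float(-np.sign(res.slope) * res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_bins_used=int(mean_k.size),
    )


@dataclass
class PowerPick:
    """Result of the soft-threshold scan."""

    beta: int
    flagged: bool  # True when no power reached r2_cut (best-R² fallback)
    table: pd.DataFrame  # per power: r2, slope, mean_k, median_k, max_k


def pick_soft_threshold(
    expr,
    params: NetworkParams | None = None,
) -> PowerPick:
    """Scan candidate powers and choose the soft threshold.

    Returns the smallest candidate power whose signed scale-free R² reaches
    ``params.r2_cut``; if none qualifies, the power with maximum signed R²
    is returned with ``flagged=True``.
    """
    params = params or NetworkParams()
    arr, _ = _as_gene_matrix(expr)
    if arr.shape[0] < 10:
        raise ValueError("soft-threshold fit needs at least 10 genes")
    if not params.candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    corr = pearson_matrix(expr)
    rows = []
    for power in params.candidate_powers:
        adj = signed_adjacency(corr, power)
        k = connectivity(adj)
        try:
            fit = scale_free_fit(k, n_bins=params.n_bins)
            r2, slope = fit.r2, fit.slope
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append(
            {
                "power": power,
                "r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows).set_index("power")
    qualifying = table.index[table["r2"] >= params.r2_cut]
    if len(qualifying):
        return PowerPick(beta=int(qualifying[0]), flagged=False, table=table)
    best = int(table["r2"].idxmax())
    return PowerPick(beta=best, flagged=True, table=table)


def _check_adjacency(a: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max() > _SYM_TOL:
        raise ValueError("adjacency not symmetric within 1e-8")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")


def tom_similarity(adjacency: np.ndarray, block_size: int = 2048) -> np.ndarray:
    """Topological overlap of a signed adjacency matrix.

    Computed in row blocks so the peak footprint beyond the adjacency itself
    is one (block × n) product; a single block reproduces the dense formula.
    """
    a = np.ascontiguousarray(adjacency, dtype=np.float64)
    _check_adjacency(a)
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    tom = np.empty_like(a)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        rows = slice(start, stop)
        # l_ij = (A²)_ij − a_ii a_ij − a_ij a_jj = (A²)_ij − 2 a_ij (unit diag)
        numer = a[rows] @ a - a[rows]  # = l + a
        denom = np.minimum.outer(k[start:stop], k) + 1.0 - a[rows]
        # diagonal cells can be 0/0 (isolated gene); they are overwritten below
        denom[np.arange(stop - start), np.arange(start, stop)] = 1.0
        tom[rows] = numer / denom
    tom = (tom + tom.T) / 2.0
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_distance(tom: np.ndarray) -> np.ndarray:
    """Clustering distance 1 − TOM with an exactly zero diagonal."""
    d = 1.0 - np.asarray(tom, dtype=np.float64)
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    return d


def build_network(expr, params: NetworkParams | None = None) -> GeneNetwork:
    """Correlation → signed adjacency → TOM for an expression matrix.

    ``params.beta=None`` triggers the soft-threshold scan.
    """
    params = params or NetworkParams()
    _, genes = _as_gene_matrix(expr)
    corr = pearson_matrix(expr)
    beta = params.beta
    if beta is None:
        beta = pick_soft_threshold(expr, params).beta
    adj = signed_adjacency(corr, beta)
    tom = tom_similarity(adj, block_size=params.block_size)
    return GeneNetwork(
        gene_ids=genes, beta=int(beta), correlation=corr, adjacency=adj, tom=tom
    )
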