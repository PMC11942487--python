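"""Shared fixtures and independent oracles.

The oracle functions here deliberately reimplement operations by the most
naive route available (triple loops, explicit recurrences, exact rational
arithmetic) so the package code is checked against an independent path.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles

def naive_tom(adj: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 1.0)
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def naive_average_linkage(dist: np.ndarray) -> list[float]:
    """O(n^3) unweighted average-linkage; returns sorted merge heights."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    d = dist.copy().astype(float)
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dij < best[0]:
                    best = (dij, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def exact_hypergeom_upper(N: int, K: int, n: int, k: int) -> Fraction:
    """Upper tail P(X >= k) by exact rational enumeration of the PMF."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def random_binary_tree(n: int, rng: np.random.Generator):
    """Random binary dendrogram: uniform merge pairs, increasing heights."""
    from cladenet.tree import Dendrogram

    children = np.full((2 * n - 1, 2), -1, dtype=np.intp)
    heights = np.zeros(2 * n - 1)
    active = list(range(n))
    h = 0.0
    for t in range(n - 1):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        h += float(rng.uniform(0.001, 0.05))
        node = n + t
        children[node] = (active[i], active[j])
        heights[node] = h
        active[j] = node
        del active[i]
    return Dendrogram([f"AT1G{10 * (i + 1):05d}" for i in range(n)], children, heights)


@pytest.fixture(scope="session")
def oracles():
    """Bundle of independent reimplementations used as test oracles."""
    return {
        "tom": naive_tom,
        "average_linkage": naive_average_linkage,
        "hypergeom": exact_hypergeom_upper,
        "random_tree": random_binary_tree,
    }


# ---------------------------------------------------------------------------
# small shared datasets

@pytest.fixture(scope="session")
def benchmark():
    """The default planted-module benchmark dataset (seed 42)."""
    from cladenet import SynthConfig, generate

    expr, design, truth = generate(SynthConfig())
    return expr, design, truth


@pytest.fixture(scope="session")
def fitted_benchmark(benchmark):
    """Benchmark dataset with a fitted coexpression model."""
    from cladenet import CoexpressionNetwork

    expr, design, truth = benchmark
    model = CoexpressionNetwork().fit(expr)
    return expr, design, truth, model


@pytest.fixture(scope="session")
def benchmark_bundle(benchmark):
    """A full queryable bundle built from the benchmark dataset."""
    from cladenet import build_bundle, generate_term_db
    from cladenet.synth import SynthConfig, generate

    expr, design, truth = benchmark
    bundle = build_bundle(expr, trait_design=design)
    bundle.add_term_db(generate_term_db(truth, seed=42))
    return bundle, truth


@pytest.fixture()
def tiny_expr():
    """4 genes x 6 samples with two perfectly separated pairs."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=6)
    X = np.vstack([base, base + 0.01 * rng.normal(size=6),
                   -base, -base + 0.01 * rng.normal(size=6)])
    return pd.DataFrame(
        X, index=["g1", "g2", "g3", "g4"], columns=[f"s{j}" for j in range(6)]
    )
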