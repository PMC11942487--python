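"""Dynamic tree cut, eigengenes, module merging and coloring."""

import numpy as np
import pandas as pd
import pytest

from cladenet.modules import (
    CutParams,
    assign_colors,
    build_partition,
    dynamic_tree_cut,
    merge_close_modules,
    module_eigengene,
)
from cladenet.network import signed_adjacency, tom_distance, tom_similarity
from cladenet.tree import average_linkage


def block_distance(sizes, within=0.05, between=0.95, seed=0):
    """Distance matrix with tight planted blocks, plus tiny jitter."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    d += rng.uniform(0, 0.01, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d, labels


class TestDynamicTreeCut:
    def test_small_tree_stays_all_grey(self):
        d, _ = block_distance([5, 5])
        tree = average_linkage(d, [f"g{i}" for i in range(10)])
        labels = dynamic_tree_cut(tree, d, CutParams(min_cluster_size=15))
        assert np.all(labels == -1)

    def test_three_separated_blocks_recovered_pure(self):
        d, truth = block_distance([30, 30, 30])
        tree = average_linkage(d, [f"g{i}" for i in range(90)])
        labels = dynamic_tree_cut(tree, d, CutParams(min_cluster_size=15))
        assert len(set(labels)) == 3 and -1 not in labels
        for m in set(labels):
            assert len(set(truth[labels == m])) == 1  # purity

    def test_no_module_smaller_than_min_size(self, fitted_benchmark):
        _, _, _, model = fitted_benchmark
        raw = model.raw_labels_
        sizes = np.bincount(raw[raw >= 0])
        assert np.all(sizes >= 15)

    def test_planted_modules_recovered_on_benchmark(self, fitted_benchmark):
        from sklearn.metrics import adjusted_rand_score

        _, _, truth, model = fitted_benchmark
        assert adjusted_rand_score(truth.labels.values, model.labels_) >= 0.9

    def test_background_genes_stay_grey(self, fitted_benchmark):
        _, _, truth, model = fitted_benchmark
        grey = model.partition_.assignment == "grey"
        background = truth.labels == -1
        # most background genes must remain unassigned
        assert (grey & background).sum() >= 0.8 * background.sum()

    def test_mismatched_distance_rejected(self):
        d, _ = block_distance([10, 10])
        tree = average_linkage(d, [f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="match"):
            dynamic_tree_cut(tree, d[:10, :10], CutParams())


class TestEigengene:
    def test_single_gene_module_is_the_gene_standardized(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"])
        e, ve = module_eigengene(expr, ["b"])
        z = (expr.loc["b"] - expr.loc["b"].mean()) / expr.loc["b"].std(ddof=1)
        assert np.allclose(e, z, atol=1e-10)
        assert ve == pytest.approx(1.0)

    def test_rank_one_module_explains_everything(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=30)
        X = np.vstack([shared + 1e-4 * rng.normal(size=30) for _ in range(8)])
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(8)])
        e, ve = module_eigengene(expr, list(expr.index))
        assert ve > 0.99
        assert abs(np.corrcoef(e, shared)[0, 1]) > 0.999

    def test_var_explained_matches_full_svd(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(20, 40)), index=[f"g{i}" for i in range(20)])
        _, ve = module_eigengene(expr, list(expr.index))
        Z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        s = np.linalg.svd(Z, compute_uv=False)
        assert ve == pytest.approx(s[0] ** 2 / np.sum(s**2), abs=1e-10)

    def test_sign_oriented_toward_member_mean(self, fitted_benchmark):
        _, _, _, model = fitted_benchmark
        part = model.partition_
        expr = model.expression_
        for color in part.colors:
            members = part.members(color)
            sub = expr.loc[members]
            z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=1)).T
            mean_r = np.mean(
                [np.corrcoef(z.loc[g], part.eigengenes.loc[color])[0, 1] for g in members]
            )
            assert mean_r >= 0

    def test_absent_gene_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(3).normal(size=(2, 5)), index=["a", "b"])
        with pytest.raises(KeyError, match="nosuch"):
            module_eigengene(expr, ["a", "nosuch"])


def latent_modules(rhos, n_genes=20, m=200, seed=0):
    """Expression with one latent profile per module; rhos[i][j] is the
    correlation between latents i and j (via shared component mixing)."""
    rng = np.random.default_rng(seed)
    k = len(rhos)
    L = np.linalg.cholesky(np.array(rhos))
    latents = L @ rng.normal(size=(k, m))
    X, labels = [], []
    for i in range(k):
        for _ in range(n_genes):
            X.append(0.9 * latents[i] + 0.2 * rng.normal(size=m))
            labels.append(i)
    expr = pd.DataFrame(np.array(X), index=[f"g{j:03d}" for j in range(len(X))])
    return expr, np.array(labels)


class TestMergeCloseModules:
    def test_same_latent_modules_merged(self):
        expr, labels = latent_modules([[1.0, 0.995], [0.995, 1.0]])
        merged, log = merge_close_modules(expr, labels, 0.25)
        assert len(set(merged)) == 1 and log

    def test_merge_threshold_separates_close_from_distant_pairs(self):
        for rho, expect_merged in ((0.95, True), (0.50, False)):
            expr, labels = latent_modules([[1.0, rho], [rho, 1.0]], seed=4)
            merged, _ = merge_close_modules(expr, labels, 0.25)
            assert (len(set(merged)) == 1) == expect_merged

    def test_idempotent_and_no_close_pair_survives(self, fitted_benchmark):
        _, _, _, model = fitted_benchmark
        expr = model.expression_
        merged = np.array(
            [model.labels_[i] for i in range(len(model.labels_))]
        )
        again, log = merge_close_modules(expr, merged, 0.25)
        assert np.array_equal(again, merged) and not log
        eig = model.eigengenes_.to_numpy()
        if len(eig) > 1:
            r = np.corrcoef(eig)
            off = r[~np.eye(len(eig), dtype=bool)]
            assert np.all(off <= 1 - 0.25)


class TestColors:
    def test_single_module_gets_first_palette_color(self):
        labels = np.array([0, 0, 0, -1])
        colors = assign_colors(labels, ["a", "b", "c", "d"])
        assert colors == {0: "turquoise"}

    def test_size_ties_break_by_smallest_gene_deterministically(self):
        labels = np.array([1, 1, 0, 0])
        genes = ["zz", "zy", "aa", "ab"]
        for _ in range(3):
            colors = assign_colors(labels, genes)
            assert colors == {0: "turquoise", 1: "blue"}  # "aa" < "zy"

    def test_many_modules_unique_size_sorted_names(self):
        rng = np.random.default_rng(5)
        sizes = rng.integers(2, 30, size=42)
        labels = np.repeat(np.arange(42), sizes)
        genes = [f"g{i:04d}" for i in range(labels.size)]
        colors = assign_colors(labels, genes)
        assert len(set(colors.values())) == 42
        # palette order must follow descending module size
        from cladenet.modules import _color_rank

        order = sorted(colors, key=lambda mod: _color_rank(colors[mod]))
        assert sorted(sizes, reverse=True) == [int(sizes[m]) for m in order]

    def test_partition_eigengenes_have_unit_variance(self, fitted_benchmark):
        _, _, _, model = fitted_benchmark
        sd = model.eigengenes_.std(axis=1, ddof=1)
        assert np.allclose(sd, 1.0, atol=1e-8)
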