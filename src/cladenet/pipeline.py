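"""End-to-end pipeline: estimator, network bundle, build/load.

:class:`CoexpressionNetwork` is a scikit-learn style clusterer over genes:
``fit`` takes a gene × sample matrix (rows are the objects being clustered),
builds the signed adjacency and TOM, clusters the TOM distance, detects and
merges modules, and exposes the results as fitted attributes (``labels_``,
``module_colors_``, ``eigengenes_`` …). It composes with sklearn tooling via
``get_params``/``set_params``/``fit_predict``.

A :class:`NetworkBundle` is the persisted form: matrices (raw float64 +
JSON sidecars), the Newick tree, module table, eigengenes, trait
associations and a manifest. Queries (clades, enrichment, hubs, module
pages) read the bundle and never mutate it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from . import __version__
from .io import (
    TermDatabase,
    load_matrix,
    read_newick_file,
    save_matrix,
    write_newick_file,
)
from .modules import (
    CutParams,
    ModulePartition,
    build_partition,
    dynamic_tree_cut,
    merge_close_modules,
)
from .network import NetworkParams, build_network, pick_soft_threshold
from .traits import eigengene_trait_correlation
from .tree import Dendrogram, average_linkage

log = logging.getLogger("cladenet")

__all__ = ["CoexpressionNetwork", "NetworkBundle", "build_bundle"]


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Signed weighted coexpression network clustering of genes.

    Parameters
    ----------
    beta : int or "auto", default=14
        Soft-threshold power; ``"auto"`` scans ``candidate_powers`` for the
        smallest power whose signed scale-free R² reaches ``r2_cut``.
    r2_cut : float, default=0.85
        Scale-free fit threshold used when ``beta="auto"``.
    min_cluster_size : int, default=15
        Smallest branch accepted as a module by the dynamic cut.
    deep_split : int, default=2
        Split sensitivity (0–4) of the dynamic cut.
    pam_stage : bool, default=True
        Adopt unassigned genes into in-radius modules after the cut.
    merge_height : float, default=0.25
        Eigengene dissimilarity (1 − r) below which modules are merged.
    block_size : int, default=2048
        Row-block size of the TOM computation.

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,)
        Merged module label per gene; ``-1`` is grey/unassigned. Labels are
        indices into ``module_colors_``.
    module_colors_ : list of str
        Color name per module, descending size.
    beta_ : int
        The soft-threshold power actually used.
    network_ : GeneNetwork
        Correlation, adjacency and TOM matrices.
    tree_ : Dendrogram
        Average-linkage TOM-distance dendrogram.
    partition_ : ModulePartition
        Colors, eigengenes, variance explained and merge log.
    eigengenes_ : DataFrame
        Module color × sample eigengene matrix.
    """

    def __init__(
        self,
        beta: int | str = 14,
        r2_cut: float = 0.85,
        candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
        min_cluster_size: int = 15,
        deep_split: int = 2,
        pam_stage: bool = True,
        merge_height: float = 0.25,
        block_size: int = 2048,
    ) -> None:
        self.beta = beta
        self.r2_cut = r2_cut
        self.candidate_powers = candidate_powers
        self.min_cluster_size = min_cluster_size
        self.deep_split = deep_split
        self.pam_stage = pam_stage
        self.merge_height = merge_height
        self.block_size = block_size

    def _expr_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(np.float64)
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("X must be a 2-D gene × sample matrix")
        return pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )

    def fit(self, X, y=None) -> "CoexpressionNetwork":
        """Build the network and detect merged modules.

        ``X``: gene × sample expression (DataFrame with gene index, or
        array). Genes must have nonzero variance.
        """
        expr = self._expr_frame(X)
        if expr.shape[0] < 3:
            raise ValueError("need at least 3 genes")
        params = NetworkParams(
            beta=None if self.beta in (None, "auto") else int(self.beta),
            r2_cut=self.r2_cut,
            candidate_powers=tuple(self.candidate_powers),
            block_size=self.block_size,
        )
        if params.beta is None:
            pick = pick_soft_threshold(expr, params)
            if pick.flagged:
                log.warning(
                    "no candidate power reached r2_cut=%.2f; using best power %d",
                    self.r2_cut, pick.beta,
                )
            params.beta = pick.beta
            self.power_table_ = pick.table
        net = build_network(expr, params)
        dist = net.tom_dist
        tree = average_linkage(dist, net.gene_ids)
        cut = CutParams(
            min_cluster_size=self.min_cluster_size,
            deep_split=self.deep_split,
            pam_stage=self.pam_stage,
            merge_height=self.merge_height,
        )
        raw = dynamic_tree_cut(tree, dist, cut)
        merged, merge_log = merge_close_modules(expr, raw, self.merge_height)
        partition = build_partition(expr, merged, merge_log)

        self.expression_ = expr
        self.beta_ = net.beta
        self.network_ = net
        self.tree_ = tree
        self.raw_labels_ = raw
        self.partition_ = partition
        self.module_colors_ = partition.colors
        color_index = {c: i for i, c in enumerate(partition.colors)}
        self.labels_ = np.array(
            [color_index.get(partition.assignment[g], -1) for g in net.gene_ids],
            dtype=np.intp,
        )
        self.eigengenes_ = partition.eigengenes
        self.var_explained_ = partition.var_explained
        self.n_modules_ = partition.n_modules
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class NetworkBundle:
    """Everything a query needs, persisted as a versioned directory."""

    expression: pd.DataFrame
    network_params: dict
    gene_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    tree: Dendrogram
    partition: ModulePartition
    trait_design: pd.DataFrame | None = None
    trait_table: pd.DataFrame | None = None
    term_dbs: dict[str, TermDatabase] = field(default_factory=dict)

    FORMAT_VERSION = 1

    def __post_init__(self) -> None:
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def tom_dist(self) -> np.ndarray:
        from .network import tom_distance

        return tom_distance(self.tom)

    def add_term_db(self, db: TermDatabase) -> None:
        self.term_dbs[db.category] = db

    # -- persistence -------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sidecar = {"gene_ids": self.gene_ids, **self.network_params}
        save_matrix(self.correlation, out / "correlation.bin", sidecar)
        save_matrix(self.adjacency, out / "adjacency.bin", sidecar)
        save_matrix(self.tom, out / "tom.bin", sidecar)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
        write_newick_file(self.tree.to_newick(), out / "tree.nwk")
        self.partition.assignment.rename("module_color").to_csv(
            out / "modules.tsv", sep="\t", index_label="gene_id"
        )
        self.partition.eigengenes.to_csv(
            out / "eigengenes.tsv", sep="\t", index_label="module"
        )
        self.partition.var_explained.to_csv(
            out / "var_explained.tsv", sep="\t", index_label="module"
        )
        (out / "merge_log.json").write_text(json.dumps(self.partition.merge_log))
        if self.trait_design is not None:
            self.trait_design.to_csv(out / "trait_design.tsv", sep="\t")
        if self.trait_table is not None:
            self.trait_table.to_csv(out / "trait_associations.tsv", sep="\t", index=False)
        manifest = {
            "format_version": self.FORMAT_VERSION,
            "tool_version": __version__,
            "n_genes": len(self.gene_ids),
            "n_samples": int(self.expression.shape[1]),
            "params": self.network_params,
            "modules": self.partition.colors,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "NetworkBundle":
        out = Path(out_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        if manifest["format_version"] > cls.FORMAT_VERSION:
            raise ValueError("bundle format is newer than this tool")
        corr, meta = load_matrix(out / "correlation.bin")
        adj, _ = load_matrix(out / "adjacency.bin")
        tom, _ = load_matrix(out / "tom.bin")
        expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0)
        tree = Dendrogram.from_newick(read_newick_file(out / "tree.nwk"))
        assignment = pd.read_csv(out / "modules.tsv", sep="\t", index_col=0)[
            "module_color"
        ]
        eigengenes = pd.read_csv(out / "eigengenes.tsv", sep="\t", index_col=0)
        var_explained = pd.read_csv(out / "var_explained.tsv", sep="\t", index_col=0)[
            "var_explained"
        ]
        merge_log = json.loads((out / "merge_log.json").read_text())
        partition = ModulePartition(
            assignment=assignment,
            colors=list(manifest["modules"]),
            eigengenes=eigengenes,
            var_explained=var_explained,
            merge_log=merge_log,
        )
        trait_design = trait_table = None
        if (out / "trait_design.tsv").exists():
            trait_design = pd.read_csv(out / "trait_design.tsv", sep="\t", index_col=0)
        if (out / "trait_associations.tsv").exists():
            trait_table = pd.read_csv(out / "trait_associations.tsv", sep="\t")
        return cls(
            expression=expr,
            network_params=manifest["params"],
            gene_ids=list(meta["gene_ids"]),
            correlation=corr,
            adjacency=adj,
            tom=tom,
            tree=tree,
            partition=partition,
            trait_design=trait_design,
            trait_table=trait_table,
        )


def build_bundle(
    expr: pd.DataFrame,
    trait_design: pd.DataFrame | None = None,
    term_dbs: dict[str, TermDatabase] | None = None,
    alpha: float = 0.05,
    **estimator_params,
) -> NetworkBundle:
    """Run the whole pipeline and assemble a queryable bundle.

    A missing trait design only skips the trait-association table (with a
    log message); everything else is built.
    """
    model = CoexpressionNetwork(**estimator_params).fit(expr)
    trait_table = None
    if trait_design is not None:
        trait_table = eigengene_trait_correlation(
            model.eigengenes_, trait_design, alpha=alpha
        )
    else:
        log.warning("no trait design supplied; skipping trait associations")
    return NetworkBundle(
        expression=model.expression_,
        network_params={
            "beta": model.beta_,
            "network_type": "signed",
            "min_cluster_size": model.min_cluster_size,
            "deep_split": model.deep_split,
            "pam_stage": model.pam_stage,
            "merge_height": model.merge_height,
        },
        gene_ids=model.network_.gene_ids,
        correlation=model.network_.correlation,
        adjacency=model.network_.adjacency,
        tom=model.network_.tom,
        tree=model.tree_,
        partition=model.partition_,
        trait_design=trait_design,
        trait_table=trait_table,
        term_dbs=dict(term_dbs or {}),
    )
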