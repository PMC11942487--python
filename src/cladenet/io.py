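"""Readers and writers for on-disk artifacts.

Formats
-------
Expression
    TSV, UTF-8; first column ``gene_id``, remaining columns are samples,
    numeric body. Gene and sample order on disk is the in-memory order.
Traits
    TSV with columns ``sample_id`` and ``tissue``; a sample may appear on
    several rows (multi-label) and is one-hot binarized on load.
Term databases
    GMT (``term<TAB>description<TAB>gene...``) or two-column TSV
    (``gene<TAB>term``). Both load into the same :class:`TermDatabase`.
Matrices
    Raw float64, row-major, with a JSON sidecar recording shape, gene order
    and parameters (used by the network bundle; see :mod:`cladenet.pipeline`).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("cladenet")

__all__ = [
    "TermDatabase",
    "read_expression",
    "write_expression",
    "read_traits",
    "write_traits",
    "read_term_db",
    "write_gmt",
    "read_newick_file",
    "write_newick_file",
    "save_matrix",
    "load_matrix",
]


# ---------------------------------------------------------------------------
# expression

def read_expression(
    path: str | Path,
    drop_zero_variance: bool = False,
    na_policy: str = "error",
) -> pd.DataFrame:
    """Load a gene × sample expression matrix from TSV.

    Parameters
    ----------
    path
        TSV file with a header row of sample ids and first column of gene ids.
    drop_zero_variance
        Drop genes whose expression is constant across samples (their
        correlations are undefined). The dropped gene list is stored in
        ``df.attrs["dropped_zero_variance"]`` and logged.
    na_policy
        ``"error"`` (default) rejects missing cells; ``"drop-gene"`` removes
        genes with any missing value (list in ``df.attrs["dropped_na"]``).

    Returns
    -------
    pandas.DataFrame
        Genes in rows (index), samples in columns, float64 values.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    if pd.Index(raw.columns).duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise ValueError(
            f"non-numeric value {raw.at[g, s]!r} at gene {g!r}, sample {s!r}"
        )
    df = numeric.astype(np.float64)
    df.attrs["dropped_na"] = []
    df.attrs["dropped_zero_variance"] = []

    if df.isna().any().any():
        if na_policy == "drop-gene":
            dropped = df.index[df.isna().any(axis=1)].tolist()
            df = df.drop(index=dropped)
            df.attrs["dropped_na"] = dropped
            log.info("dropped %d genes with missing values", len(dropped))
        else:
            g = df.index[df.isna().any(axis=1)][0]
            raise ValueError(
                f"missing value for gene {g!r}; rerun with na_policy='drop-gene' "
                "to remove incomplete genes"
            )

    if drop_zero_variance:
        var = df.var(axis=1, ddof=0)
        dropped = df.index[var == 0.0].tolist()
        if dropped:
            df = df.drop(index=dropped)
            log.info("dropped %d zero-variance genes", len(dropped))
        df.attrs["dropped_zero_variance"] = dropped
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# traits

def read_traits(path: str | Path, samples: list[str]) -> pd.DataFrame:
    """Load a sample → tissue table and one-hot binarize it.

    The design is aligned to the given sample order; every sample must appear
    in the trait file at least once. Samples in the file but absent from
    ``samples`` are ignored.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.shape[1] < 2:
        raise ValueError(f"trait file {path} needs columns sample_id, tissue")
    tab = tab.iloc[:, :2]
    tab.columns = ["sample_id", "tissue"]
    missing = [s for s in samples if s not in set(tab["sample_id"])]
    if missing:
        raise ValueError(f"samples without tissue labels: {missing}")
    design = (
        pd.crosstab(tab["sample_id"], tab["tissue"])
        .clip(upper=1)
        .reindex(index=samples, columns=sorted(tab["tissue"].unique()))
        .fillna(0)
        .astype(np.int8)
    )
    design.index.name = "sample_id"
    return design


def write_traits(design: pd.DataFrame, path: str | Path) -> None:
    """Write a one-hot design back to the long sample/tissue TSV format."""
    rows = [
        (s, t)
        for s in design.index
        for t in design.columns
        if design.at[s, t]
    ]
    pd.DataFrame(rows, columns=["sample_id", "tissue"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# term databases

@dataclass
class TermDatabase:
    """A category of gene–term annotations.

    Attributes
    ----------
    category
        Short keyword naming the category (e.g. ``"bp"``).
    terms
        Map term id → ``(description, frozenset of gene ids)``.
    """

    category: str
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for _, gs in self.terms.values():
            out |= gs
        return frozenset(out)


def read_term_db(path: str | Path, category: str) -> TermDatabase:
    """Load a GMT or two-column (gene, term) TSV annotation file.

    ``.gmt`` extensions force GMT; otherwise a file where every row has
    exactly two fields is read as (gene, term) pairs. Terms with an empty
    gene set are dropped with a warning.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n").split("\t")
        for ln in path.read_text().splitlines()
        if ln.strip()
    ]
    is_gmt = path.suffix.lower() == ".gmt" or any(len(f) != 2 for f in lines)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    if is_gmt:
        for fields in lines:
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line in {path}: {fields!r}")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in terms:
                raise ValueError(f"duplicate term {term!r} in {path}")
            if not genes:
                warnings.warn(f"term {term!r} has no genes; dropped", stacklevel=2)
                continue
            terms[term] = (desc, frozenset(genes))
    else:
        by_term: dict[str, set[str]] = {}
        for gene, term in lines:
            by_term.setdefault(term, set()).add(gene)
        for term, genes in by_term.items():
            terms[term] = ("", frozenset(genes))
    return TermDatabase(category=category, terms=terms)


def write_gmt(db: TermDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in db.terms.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# newick + raw matrices

def read_newick_file(path: str | Path) -> str:
    return Path(path).read_text().strip()


def write_newick_file(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def save_matrix(
    arr: np.ndarray, path: str | Path, sidecar: dict | None = None
) -> None:
    """Write a float64 matrix as raw row-major binary plus a JSON sidecar."""
    path = Path(path)
    np.ascontiguousarray(arr, dtype=np.float64).tofile(path)
    meta = {"shape": list(arr.shape), "dtype": "float64", "order": "C"}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=np.float64).reshape(meta["shape"])
    return arr, meta
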