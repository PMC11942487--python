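"""Module eigengene ↔ tissue trait association.

Each module eigengene is correlated (Pearson) with every binary tissue
indicator; on a 0/1 column this is exactly the point-biserial correlation,
so no special-casing is needed. The two-sided p-value comes from the exact
t transformation t = r·sqrt((m−2)/(1−r²)) with m−2 degrees of freedom.
No multiple-testing correction is applied across the module × trait grid;
the raw p is always reported so users can adjust downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlation_pvalue", "eigengene_trait_correlation"]


def correlation_pvalue(r: np.ndarray, m: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation with ``m`` paired samples."""
    if m < 3:
        raise ValueError("need at least 3 samples")
    r = np.asarray(r, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.minimum(p, 1.0)


def eigengene_trait_correlation(
    eigengenes: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every module eigengene with every binary tissue trait.

    Parameters
    ----------
    eigengenes
        Module × sample matrix (rows indexed by module color).
    design
        Sample × trait one-hot matrix; sample order must match the
        eigengene columns.
    alpha
        Significance threshold applied to the raw p-value for the
        ``significant`` flag (display only; no adjustment).

    Returns
    -------
    pandas.DataFrame
        Long table with columns ``module, trait, r, p, significant``.
        Constant trait columns yield NaN r and p (undefined, not zero).
    """
    if list(eigengenes.columns) != list(design.index):
        if set(eigengenes.columns) != set(design.index):
            raise ValueError("eigengene samples and design samples differ")
        design = design.loc[eigengenes.columns]
    m = eigengenes.shape[1]
    if m < 3:
        raise ValueError("need at least 3 samples")
    E = eigengenes.to_numpy(dtype=np.float64)
    T = design.to_numpy(dtype=np.float64)
    const = T.std(axis=0) == 0.0

    Ez = (E - E.mean(axis=1, keepdims=True))
    Ez /= np.linalg.norm(Ez, axis=1, keepdims=True)
    Tz = T - T.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Tz, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        Tz = np.where(norms > 0, Tz / norms, np.nan)
    R = np.clip(Ez @ Tz, -1.0, 1.0)  # modules × traits
    P = correlation_pvalue(R, m)
    R[:, const] = np.nan
    P[:, const] = np.nan

    rows = []
    for i, mod in enumerate(eigengenes.index):
        for j, trait in enumerate(design.columns):
            r, p = R[i, j], P[i, j]
            rows.append(
                {
                    "module": mod,
                    "trait": trait,
                    "r": r,
                    "p": p,
                    "significant": bool(p <= alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)
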