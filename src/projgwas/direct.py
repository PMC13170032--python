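"""Covariate-residualized per-variant linear regression.

A per-variant association test of phenotype ``y`` on genotype dosage ``g``
with covariates ``Z`` (intercept included) is computed by first removing the
covariates from both sides with the residual projection
``P = I - Z (Z'Z)^-1 Z'`` and then running the univariate regression of the
residualized phenotype on the residualized genotype (the Frisch-Waugh-Lovell
decomposition).  On the residualized vectors,

    beta_hat = g~' y~ / g~' g~
    SE(beta_hat)^2 = (1/d) * (y~' y~ / g~' g~ - beta_hat^2)

with d = N - C_total - 1 residual degrees of freedom (C_total counts the
intercept; one further degree of freedom is spent on the genotype).  All
sums of squares share the single divisor d, which is what makes the
summary-statistics algebra in :mod:`projgwas.indirect` exact.

p-values use the two-sided t reference with d degrees of freedom; at biobank
sample sizes this coincides with the normal reference, and it keeps small-N
tests exact.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    GWAS_COLUMNS,
    FeatureGwasTable,
    PartialCovariance,
    ResidualizedMatrix,
)

logger = logging.getLogger(__name__)

# Relative tolerance below which a residualized sum of squares counts as zero
# (monomorphic-after-adjustment variant or perfectly fitted phenotype).
_ZERO_SS_RTOL = 1e-12


def _check_full_rank(Z: pd.DataFrame) -> None:
    """Raise naming the offending columns if Z is column-rank deficient."""
    Zv = np.asarray(Z, dtype=float)
    rank = np.linalg.matrix_rank(Zv)
    if rank == Z.shape[1]:
        return
    # Greedy scan: a column that fails to increase the running rank is
    # linearly dependent on its predecessors.
    offenders = []
    kept: list[int] = []
    for j in range(Z.shape[1]):
        cand = Zv[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
        else:
            offenders.append(str(Z.columns[j]))
    raise ValueError(
        "covariate matrix is rank deficient; dependent columns: "
        + ", ".join(offenders)
    )


def residualize(M: pd.DataFrame, Z: pd.DataFrame) -> ResidualizedMatrix:
    """Project the columns of ``M`` onto the orthogonal complement of the
    covariate column space.

    Computed via least-squares residuals, never materializing the N x N
    projector.  The returned degrees of freedom are d = N - C_total - 1.

    Parameters
    ----------
    M
        Matrix to residualize (samples x anything), sample ids on the index.
    Z
        Covariate matrix including an intercept column; must be full rank
        and share the sample index with ``M``.
    """
    if isinstance(M, pd.Series):
        M = M.to_frame()
    if not M.index.equals(Z.index):
        raise ValueError("sample ids of M and Z do not match")
    _check_full_rank(Z)
    Zv = np.asarray(Z, dtype=float)
    Mv = np.asarray(M, dtype=float)
    coef, *_ = np.linalg.lstsq(Zv, Mv, rcond=None)
    resid = Mv - Zv @ coef
    df = M.shape[0] - Z.shape[1] - 1
    return ResidualizedMatrix(
        values=pd.DataFrame(resid, index=M.index, columns=M.columns), df=df
    )


def _scan_arrays(
    G_res: np.ndarray, Y_res: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized residualized scan of every phenotype column in ``Y_res``
    against every genotype column in ``G_res``.

    Returns (beta, se) as (n_variants x n_phenotypes) arrays.  Variants whose
    residualized dosage has zero sum of squares get NaN statistics; exact
    fits (zero residual variance) get beta with NaN standard error.
    """
    ss_g = np.einsum("ij,ij->j", G_res, G_res)  # per-variant g~'g~
    ss_y = np.einsum("ij,ij->j", Y_res, Y_res)  # per-phenotype y~'y~
    scale = max(ss_g.max(initial=0.0), 1.0)
    degenerate = ss_g <= _ZERO_SS_RTOL * scale
    safe_ss_g = np.where(degenerate, 1.0, ss_g)

    beta = (G_res.T @ Y_res) / safe_ss_g[:, None]
    bracket = ss_y[None, :] / safe_ss_g[:, None] - beta**2
    # Exact fits can leave a tiny negative bracket from rounding.
    tol = _ZERO_SS_RTOL * np.maximum(ss_y[None, :] / safe_ss_g[:, None], 1.0)
    se2 = np.where(bracket > tol, bracket / df, np.nan)
    se = np.sqrt(se2)
    beta[degenerate, :] = np.nan
    se[degenerate, :] = np.nan
    if degenerate.any():
        logger.warning(
            "%d variant(s) have zero residualized variance; statistics flagged NA",
            int(degenerate.sum()),
        )
    return beta, se


def _rows_from_stats(
    variant_ids, beta: np.ndarray, se: np.ndarray, n: int, df: int
) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
        p = 2.0 * sps.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": p,
            "n": n,
            "df": df,
        }
    )
    return out[GWAS_COLUMNS]


def gwas_scan(
    G: pd.DataFrame,
    y: pd.Series,
    Z: pd.DataFrame,
    chunk_size: int | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Per-variant linear association scan of one phenotype.

    Returns a table with columns ``variant_id, beta, se, t_stat, p_value,
    n, df``.  Zero-variance residualized variants yield NA statistics with a
    logged warning rather than aborting the scan; results are independent of
    ``chunk_size`` and ``n_workers``.
    """
    res = feature_gwas(G, y.to_frame("__y__"), Z, chunk_size=chunk_size,
                       n_workers=n_workers)
    return _rows_from_stats(
        res.variant_ids.to_numpy(),
        res.beta["__y__"].to_numpy(),
        res.se["__y__"].to_numpy(),
        int(res.n.iloc[0]),
        res.df,
    )


def feature_gwas(
    G: pd.DataFrame,
    X: pd.DataFrame,
    Z: pd.DataFrame,
    chunk_size: int | None = None,
    n_workers: int = 1,
) -> FeatureGwasTable:
    """Association scan of every feature column of ``X`` against every
    variant of ``G``, residualizing the genotypes once and reusing them.

    Variants are processed in chunks (optionally across threads); the output
    is identical for any chunking because the per-variant statistics are
    independent.
    """
    if not G.index.equals(X.index) or not G.index.equals(Z.index):
        raise ValueError("G, X and Z must share identical sample ids in order")
    G_res = residualize(G, Z)
    X_res = residualize(X, Z)
    df = G_res.df
    Gv = G_res.values.to_numpy()
    Xv = X_res.values.to_numpy()

    n_variants = Gv.shape[1]
    if chunk_size is None or chunk_size >= n_variants:
        chunk_bounds = [(0, n_variants)]
    else:
        starts = range(0, n_variants, chunk_size)
        chunk_bounds = [(s, min(s + chunk_size, n_variants)) for s in starts]

    def run_chunk(bounds):
        lo, hi = bounds
        return _scan_arrays(Gv[:, lo:hi], Xv, df)

    if n_workers > 1 and len(chunk_bounds) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            parts = list(pool.map(run_chunk, chunk_bounds))
    else:
        parts = [run_chunk(b) for b in chunk_bounds]

    beta = np.vstack([p[0] for p in parts])
    se = np.vstack([p[1] for p in parts])
    n = pd.Series(G.shape[0], index=X.columns)
    return FeatureGwasTable(
        beta=pd.DataFrame(beta, index=G.columns, columns=X.columns),
        se=pd.DataFrame(se, index=G.columns, columns=X.columns),
        n=n,
        df=df,
    )


def feature_gwas_rows(table: FeatureGwasTable, feature_id) -> pd.DataFrame:
    """Expand one feature's columns of a :class:`FeatureGwasTable` into the
    standard per-variant result layout (beta, se, t, p, n, df)."""
    return _rows_from_stats(
        table.variant_ids.to_numpy(),
        table.beta[feature_id].to_numpy(),
        table.se[feature_id].to_numpy(),
        int(table.n.loc[feature_id]),
        table.df,
    )


def partial_covariance(X: pd.DataFrame, Z: pd.DataFrame) -> PartialCovariance:
    """Covariate-adjusted covariance of the feature phenotypes,
    C = X~' X~ / d with d = N - C_total - 1.

    The divisor is recorded on the result; it must match the degrees of
    freedom of the per-feature scans for the indirect algebra to be exact.
    """
    X_res = residualize(X, Z)
    Xv = X_res.values.to_numpy()
    C = (Xv.T @ Xv) / X_res.df
    diag = np.diag(C)
    if np.any(diag <= _ZERO_SS_RTOL * max(diag.max(initial=0.0), 1.0)):
        logger.warning(
            "feature(s) constant after residualization: %s",
            list(X.columns[diag <= _ZERO_SS_RTOL * max(diag.max(initial=0.0), 1.0)]),
        )
    return PartialCovariance(
        values=pd.DataFrame(C, index=X.columns, columns=X.columns),
        normalization=X_res.df,
    )
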