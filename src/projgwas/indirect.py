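"""Indirect association statistics for linear combinations of phenotypes.

Given per-feature summary statistics (coefficients b, standard errors s,
sample sizes, degrees of freedom d) and the partial covariance matrix C of
the features, the scan for the combined phenotype y = X p is, per variant:

    beta_hat      = b' p
    Var(g~)_i     = Var(x~_i) / (s_i^2 d + b_i^2)          (per feature)
    Var(g~)-hat   = mean_i Var(g~)_i
    SE(beta_hat)  = sqrt( (1/d) * ( p' C p / Var(g~)-hat - beta_hat^2 ) )

No individual-level data enters: everything is a function of shareable
summary statistics.  The algebra is exact when all feature scans were run on
the same complete-case sample with the same covariates and every variance
term shares the divisor d — the construction guaranteed by
:mod:`projgwas.direct`.

The indirect sample size is the minimum sample size over the features that
actually enter the combination (nonzero coefficient), since that is the
sample a direct scan of y would have had.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FeatureGwasTable, PartialCovariance

logger = logging.getLogger(__name__)

#: Result-table layout; var_g_hat is the per-variant genotype partial
#: variance estimate the standard error is built from.
INDIRECT_COLUMNS = [
    "variant_id", "beta", "se", "t_stat", "p_value", "n", "df", "var_g_hat",
]


def _align(p: pd.Series, feature_ids: pd.Index) -> np.ndarray:
    """Align a projection vector to a feature ordering by id, never by
    position; raise listing the symmetric difference on mismatch."""
    if set(p.index) != set(feature_ids):
        missing = sorted(set(feature_ids) - set(p.index))
        extra = sorted(set(p.index) - set(feature_ids))
        raise ValueError(
            f"projection features do not match: missing={missing}, extra={extra}"
        )
    return p.reindex(feature_ids).to_numpy(dtype=float)


def genotype_variance_per_feature(
    b: np.ndarray, s: np.ndarray, var_x: np.ndarray, df: int
) -> np.ndarray:
    """Per-feature estimates Var(g~)_i = Var(x~_i) / (s_i^2 d + b_i^2).

    Features with a zero denominator yield NaN.
    """
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)
    var_x = np.asarray(var_x, dtype=float)
    denom = s**2 * df + b**2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, var_x / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def estimate_genotype_variance(
    b: np.ndarray, s: np.ndarray, var_x: np.ndarray, df: int
) -> float:
    """Genotype partial variance estimated from feature summary statistics,
    averaged (unweighted arithmetic mean) across features.

    Degenerate features (zero denominator) are dropped from the mean with a
    warning; if every feature is degenerate the result is NaN.
    """
    per_feature = genotype_variance_per_feature(b, s, var_x, df)
    valid = np.isfinite(per_feature)
    if not valid.any():
        logger.warning("all features degenerate; genotype variance flagged NA")
        return float("nan")
    if not valid.all():
        logger.warning(
            "%d degenerate feature(s) excluded from genotype-variance mean",
            int((~valid).sum()),
        )
    return float(per_feature[valid].mean())


def indirect_coefficient(b: pd.Series, p: pd.Series) -> float:
    """Coefficient for the combined phenotype: beta_hat = b' p.

    Alignment is by feature id; mismatched ids are an error, never a silent
    reorder.
    """
    pv = _align(p, b.index)
    return float(b.to_numpy(dtype=float) @ pv)


def indirect_se(
    p: pd.Series,
    C: PartialCovariance,
    var_g_hat: float,
    beta_hat: float,
    df: int,
) -> float:
    """Standard error for the combined phenotype.

    SE = sqrt( (1/d) * ( p' C p / var_g_hat - beta_hat^2 ) ).  A
    non-positive bracket (possible with inconsistent user-supplied inputs)
    or a non-positive genotype variance yields NaN with a warning, never an
    exception or an imaginary number.
    """
    if not var_g_hat > 0:
        logger.warning("non-positive genotype variance; SE flagged NA")
        return float("nan")
    pv = _align(p, C.feature_ids)
    var_y = float(pv @ C.values.to_numpy() @ pv)
    bracket = var_y / var_g_hat - beta_hat**2
    if bracket <= 0:
        logger.warning("non-positive variance bracket; SE flagged NA")
        return float("nan")
    return float(np.sqrt(bracket / df))


def indirect_sample_size(n_per_feature: pd.Series, p: pd.Series) -> int:
    """Minimum sample size over the features with a nonzero projection
    coefficient (features with p_i = 0 contribute nothing to y)."""
    if len(n_per_feature) == 0:
        raise ValueError("empty sample-size vector")
    pv = _align(p, pd.Index(n_per_feature.index))
    active = pv != 0
    if not active.any():
        active = np.ones_like(active, dtype=bool)
    return int(n_per_feature.to_numpy()[active].min())


def _scan_block(
    B: np.ndarray,
    S: np.ndarray,
    var_x: np.ndarray,
    C: np.ndarray,
    P: np.ndarray,
    df: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized indirect scan for a block of variants.

    B, S: (v x m) feature coefficients / SEs; P: (m x q) projection matrix.
    Returns (beta, se, var_g_hat) with shapes (v x q), (v x q), (v,).
    """
    denom = S**2 * df + B**2
    with np.errstate(invalid="ignore", divide="ignore"):
        per_feat = np.where(denom > 0, var_x[None, :] / np.where(denom > 0, denom, 1.0), np.nan)
    valid = np.isfinite(per_feat)
    counts = valid.sum(axis=1)
    sums = np.where(valid, per_feat, 0.0).sum(axis=1)
    var_g = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not valid.all():
        logger.warning("degenerate feature estimates excluded from genotype variance")

    beta = B @ P
    var_y = np.einsum("mq,mn,nq->q", P, C, P)  # p'Cp per projection
    with np.errstate(invalid="ignore", divide="ignore"):
        bracket = var_y[None, :] / var_g[:, None] - beta**2
        se = np.sqrt(np.where((bracket > 0) & (var_g[:, None] > 0), bracket, np.nan) / df)
    return beta, se, var_g


def indirect_scan(
    stats: FeatureGwasTable,
    C: PartialCovariance,
    projections: list[pd.Series] | pd.DataFrame,
    chunk_size: int | None = None,
    n_workers: int = 1,
) -> list[pd.DataFrame]:
    """Indirect association scan of every projection over every variant.

    ``projections`` is a list of coefficient Series indexed by feature id
    (or a DataFrame with one row per projection).  Returns one result table
    per projection, in the standard layout plus the ``var_g_hat`` column.
    Output is independent of chunk size and worker count.
    """
    feature_ids = stats.feature_ids
    if set(C.feature_ids) != set(feature_ids):
        missing = sorted(set(feature_ids) - set(C.feature_ids))
        extra = sorted(set(C.feature_ids) - set(feature_ids))
        raise ValueError(
            f"covariance features do not match stats: missing={missing}, extra={extra}"
        )
    if isinstance(projections, pd.DataFrame):
        proj_list = [projections.loc[i] for i in projections.index]
    else:
        proj_list = list(projections)

    P = np.column_stack([_align(p, feature_ids) for p in proj_list])
    Cv = C.values.reindex(index=feature_ids, columns=feature_ids).to_numpy(dtype=float)
    var_x = np.diag(Cv).copy()
    B = stats.beta.to_numpy(dtype=float)
    S = stats.se.to_numpy(dtype=float)
    df = stats.df

    n_variants = B.shape[0]
    if chunk_size is None or chunk_size >= n_variants:
        bounds = [(0, n_variants)]
    else:
        bounds = [
            (s, min(s + chunk_size, n_variants))
            for s in range(0, n_variants, chunk_size)
        ]

    def run_chunk(b):
        lo, hi = b
        return _scan_block(B[lo:hi], S[lo:hi], var_x, Cv, P, df)

    if n_workers > 1 and len(bounds) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            parts = list(pool.map(run_chunk, bounds))
    else:
        parts = [run_chunk(b) for b in bounds]

    beta = np.vstack([p[0] for p in parts])
    se = np.vstack([p[1] for p in parts])
    var_g = np.concatenate([p[2] for p in parts])

    out: list[pd.DataFrame] = []
    variant_ids = stats.variant_ids.to_numpy()
    for q, p in enumerate(proj_list):
        n_q = indirect_sample_size(stats.n, p)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta[:, q] / se[:, q]
            pval = 2.0 * sps.t.sf(np.abs(t), df)
        out.append(
            pd.DataFrame(
                {
                    "variant_id": variant_ids,
                    "beta": beta[:, q],
                    "se": se[:, q],
                    "t_stat": t,
                    "p_value": pval,
                    "n": n_q,
                    "df": df,
                    "var_g_hat": var_g,
                }
            )[INDIRECT_COLUMNS]
        )
    return out
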