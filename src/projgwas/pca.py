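"""PCA-accelerated multi-phenotype association scans.

Instead of running one direct scan per phenotype, the phenotype matrix is
compressed with principal component analysis, direct scans are run on a
subset of the component scores, and per-phenotype summary statistics are
reconstructed with the indirect machinery: since the residualized phenotype
matrix satisfies X~ = S L' (scores times transposed loadings), phenotype j
is exactly the linear combination of the scores with coefficients given by
row j of the loadings.  With all components retained the reconstruction is
exact; with fewer, fidelity degrades gracefully while the most extreme
associations are typically preserved.

PCA is fit on the covariate-residualized phenotypes so the score covariance
is consistent with the d-normalized partial-covariance machinery of the
direct scan.  Component signs are fixed deterministically (largest-magnitude
loading entry positive).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ConfusionCounts, FeatureGwasTable, PartialCovariance, PcaModel
from .direct import feature_gwas, partial_covariance, residualize
from .indirect import indirect_scan

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8

#: Retained-component fraction grid used in the acceleration experiment.
DEFAULT_FRACTIONS = (0.1, 0.25, 0.5, 0.75, 0.9, 1.0)


def fit_pca(X: pd.DataFrame, Z: pd.DataFrame) -> PcaModel:
    """Eigendecomposition of the partial covariance of ``X`` (residualized
    against ``Z``; the intercept column makes residualization center the
    data).  Components are ordered by non-increasing eigenvalue."""
    cov = partial_covariance(X, Z)
    Cv = cov.values.to_numpy()
    eigvals, eigvecs = np.linalg.eigh(Cv)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if (eigvals < -1e-10 * max(abs(eigvals).max(), 1.0)).any():
        logger.warning("negative eigenvalues clipped in PCA fit")
    near_zero = eigvals <= 1e-12 * max(eigvals.max(), 1.0)
    if near_zero.any():
        logger.warning("%d near-zero eigenvalue component(s) retained", near_zero.sum())
    # deterministic sign: largest-magnitude entry of each loading positive
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pc_ids = [f"PC{j + 1:03d}" for j in range(len(eigvals))]
    return PcaModel(
        feature_ids=X.columns,
        means=X.mean(axis=0),
        loadings=pd.DataFrame(eigvecs, index=X.columns, columns=pc_ids),
        eigenvalues=pd.Series(eigvals, index=pc_ids),
    )


def pc_scores(
    X: pd.DataFrame, Z: pd.DataFrame, model: PcaModel, n_components: int
) -> pd.DataFrame:
    """Project the residualized phenotypes onto the first ``n_components``
    loadings; the resulting score matrix is the phenotype set for the
    reduced direct scan."""
    if not 1 <= n_components <= len(model.eigenvalues):
        raise ValueError(
            f"n_components must be in [1, {len(model.eigenvalues)}], got {n_components}"
        )
    X_res = residualize(X[model.feature_ids], Z)
    L = model.loadings.iloc[:, :n_components]
    scores = X_res.values.to_numpy() @ L.to_numpy()
    return pd.DataFrame(scores, index=X.index, columns=L.columns)


def reconstruct_gwas(
    pc_stats: FeatureGwasTable,
    pc_cov: PartialCovariance,
    model: PcaModel,
    n_components: int,
) -> dict[str, pd.DataFrame]:
    """Reconstruct per-phenotype summary statistics from component scans.

    The projection vector for phenotype j is row j of the loadings
    restricted to the first ``n_components`` components.  Returns one
    result table per original phenotype, keyed by feature id.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    pc_ids = list(model.loadings.columns[:n_components])
    if set(pc_stats.feature_ids) != set(pc_ids):
        raise ValueError(
            "component stats do not match the requested components: "
            f"stats={list(pc_stats.feature_ids)}, expected={pc_ids}"
        )
    projections = [
        pd.Series(model.loadings.loc[fid, pc_ids], index=pc_ids)
        for fid in model.feature_ids
    ]
    results = indirect_scan(pc_stats, pc_cov, projections)
    return dict(zip(model.feature_ids, results))


def significance_confusion(
    p_direct, p_indirect, alpha: float = GENOME_WIDE_ALPHA
) -> ConfusionCounts:
    """Significance agreement at threshold ``alpha``; direct significance is
    truth, indirect is the prediction.  Missing (NaN) entries on either
    side are excluded from the counts and tallied separately."""
    pd_ = np.asarray(p_direct, dtype=float).ravel()
    pi_ = np.asarray(p_indirect, dtype=float).ravel()
    if pd_.shape != pi_.shape:
        raise ValueError("p-value grids must be aligned")
    ok = np.isfinite(pd_) & np.isfinite(pi_)
    truth = pd_[ok] < alpha
    pred = pi_[ok] < alpha
    return ConfusionCounts(
        tp=int((truth & pred).sum()),
        fp=int((~truth & pred).sum()),
        fn=int((truth & ~pred).sum()),
        tn=int((~truth & ~pred).sum()),
        alpha=alpha,
        n_missing=int((~ok).sum()),
    )


def gwas_fidelity(chi2_a, chi2_b) -> float:
    """Pearson correlation between two aligned chi-squared (t^2) statistic
    vectors — the scan-agreement metric.  Flagged NaN when either vector is
    constant; missing entries are dropped pairwise."""
    a = np.asarray(chi2_a, dtype=float).ravel()
    b = np.asarray(chi2_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("chi-squared vectors must be aligned with length >= 2")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        logger.warning("constant chi-squared vector; fidelity flagged NA")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pc_fraction_experiment(
    G: pd.DataFrame,
    X: pd.DataFrame,
    Z: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    alpha: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Run the full acceleration protocol over a grid of retained-component
    fractions.

    For each fraction: fit PCA, scan the retained scores directly,
    reconstruct per-phenotype statistics indirectly, and compare to the
    direct per-phenotype scans.  Returns one row per fraction with the mean
    chi-squared fidelity over phenotypes and the significance-confusion
    counts/metrics at ``alpha``.
    """
    m = X.shape[1]
    direct_stats = feature_gwas(G, X, Z)
    direct_chi2 = (direct_stats.beta / direct_stats.se) ** 2
    from scipy import stats as sps

    direct_p = 2.0 * sps.t.sf(
        np.abs((direct_stats.beta / direct_stats.se).to_numpy()), direct_stats.df
    )

    model = fit_pca(X, Z)
    rows = []
    for frac in fractions:
        n_comp = max(1, int(round(frac * m)))
        scores = pc_scores(X, Z, model, n_comp)
        pc_stats = feature_gwas(G, scores, Z)
        pc_cov = partial_covariance(scores, Z)
        recon = reconstruct_gwas(pc_stats, pc_cov, model, n_comp)

        fidelities = []
        recon_p = np.empty_like(direct_p)
        for j, fid in enumerate(model.feature_ids):
            tab = recon[fid]
            fidelities.append(
                gwas_fidelity(direct_chi2[fid].to_numpy(), tab["t_stat"].to_numpy() ** 2)
            )
            recon_p[:, j] = tab["p_value"].to_numpy()
        conf = significance_confusion(direct_p, recon_p, alpha)
        rows.append(
            {
                "fraction": frac,
                "n_components": n_comp,
                "mean_fidelity": float(np.nanmean(fidelities)),
                **conf.as_dict(),
            }
        )
    return pd.DataFrame(rows)
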