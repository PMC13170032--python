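"""Shared in-memory containers.

All tabular data is held in pandas objects with sample identifiers on the
row index and variant/feature identifiers on the column index.  The small
dataclasses here bundle a matrix with the scalar bookkeeping (degrees of
freedom, normalization constants, anonymity parameters) that the
summary-statistics algebra depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column layout of a per-variant association-scan result table.
GWAS_COLUMNS = ["variant_id", "beta", "se", "t_stat", "p_value", "n", "df"]


@dataclass
class ResidualizedMatrix:
    """A matrix after projection onto the orthogonal complement of the
    covariate column space, with the residual degrees of freedom
    ``d = N - C_total - 1`` carried alongside (one further df is reserved
    for the genotype term of the per-variant regression)."""

    values: pd.DataFrame
    df: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(
                f"residual degrees of freedom must be >= 1, got {self.df}"
            )


@dataclass
class FeatureGwasTable:
    """Per-variant, per-feature summary statistics.

    ``beta`` and ``se`` are (n_variants x m) DataFrames sharing a variant
    index and feature columns; ``n`` is the per-feature sample count and
    ``df`` the residual degrees of freedom shared by all scans.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    n: pd.Series
    df: int

    def __post_init__(self) -> None:
        if not self.beta.columns.equals(self.se.columns):
            raise ValueError("beta and se must share feature columns")
        if not self.beta.index.equals(self.se.index):
            raise ValueError("beta and se must share the variant index")
        if not self.beta.columns.equals(pd.Index(self.n.index)):
            raise ValueError("n must be indexed by the feature ids")

    @property
    def feature_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def variant_ids(self) -> pd.Index:
        return self.beta.index


@dataclass
class PartialCovariance:
    """Covariate-adjusted covariance of the feature phenotypes.

    ``values`` is the symmetric m x m matrix C = X~' X~ / d, where X~ is the
    residualized phenotype matrix.  ``normalization`` records the divisor d
    actually used; the indirect algebra is exact only when this divisor is
    shared with the variance terms of the per-feature scans.
    """

    values: pd.DataFrame
    normalization: int

    def __post_init__(self) -> None:
        C = np.asarray(self.values, dtype=float)
        if C.shape[0] != C.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def variances(self) -> pd.Series:
        """Per-feature partial variances Var(x~_i) (the diagonal)."""
        return pd.Series(np.diag(self.values.to_numpy()), index=self.feature_ids)


@dataclass
class LinearApproximation:
    """Least-squares approximation of a target phenotype by the features.

    ``coefficients`` is the projection vector handed to the indirect scan;
    the fitted intercept is kept separately because association statistics
    are invariant to location shifts once covariates include an intercept.
    ``fit_r2`` is the coefficient of determination between the target and
    its linear approximation, the user-facing quality gauge.
    """

    coefficients: pd.Series
    intercept: float
    fit_r2: float


@dataclass
class AnonymizedDataset:
    """Microaggregated phenotype data: every record replaced by the centroid
    of its group, each group holding at least ``k`` records."""

    values: pd.DataFrame
    group_assignment: pd.Series
    k: int


@dataclass
class PcaModel:
    """Principal components of the covariate-residualized phenotypes.

    ``loadings`` is the m x m orthonormal matrix whose columns are the
    components ordered by non-increasing ``eigenvalues``.  Component signs
    are fixed so each column's largest-magnitude entry is positive.
    """

    feature_ids: pd.Index
    means: pd.Series
    loadings: pd.DataFrame
    eigenvalues: pd.Series


@dataclass
class ConfusionCounts:
    """Significance agreement between two scans at a fixed threshold.

    The first (direct) scan defines truth; the second (reconstructed)
    defines the prediction.  Entries with missing statistics in either scan
    are excluded from the counts and tallied in ``n_missing``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    alpha: float
    n_missing: int = 0

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")

    def as_dict(self) -> dict:
        return {
            "fp": self.fp,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "alpha": self.alpha,
            "n_missing": self.n_missing,
        }


@dataclass
class SimulatedTruth:
    """Ground truth of a phenotype simulation: which variants are causal,
    the per-phenotype fixed effect sizes, and the drawn error matrix."""

    causal_variant_ids: list = field(default_factory=list)
    effect_sizes: pd.DataFrame | None = None
    errors: pd.DataFrame | None = None
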