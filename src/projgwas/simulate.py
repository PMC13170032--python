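"""Synthetic genotype/phenotype data with controllable shared structure.

The generator emulates the additive variance-component design commonly used
to validate multi-phenotype association methods.  Each phenotype is a sum of

* a genetic component built from a causal subset of variants, split into a
  shared part (one effect vector common to all phenotypes, weight ``theta``)
  and an independent part (per-phenotype effects, weight ``1 - theta``);
* a noise component with share ``delta`` of total variance, likewise split
  into shared (``phi``) and independent (``1 - phi``) parts;
* a covariate (confounder) component taking up the remaining variance, with
  per-phenotype covariate effects correlated across phenotypes at
  ``p_corr``.

Components are standardized empirically before weighting, so the realized
variance shares match the requested proportions on the simulated sample.
The fixed-SNP share of total variance is ``h2s``.  Everything is
deterministic given ``seed``.

Defaults mirror a typical validation configuration for indirect
multi-phenotype methods: 10 phenotypes, half the variants causal,
``h2s = 0.5``, ``theta = 0.8``, ``delta = 0.3``, ``phi = 0.6``,
``p_corr = 0.8``, 5 covariates plus an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SimulatedTruth
from .phenodef import And, Not, Or, FeatureRef, PhenotypeDefinition


@dataclass
class SimulationParams:
    """Parameters of the variance-component phenotype simulation."""

    n_samples: int = 10_000
    n_variants: int = 10_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_phenotypes: int = 10
    causal_fraction: float = 0.5
    h2s: float = 0.5          # fixed-SNP share of total variance
    theta: float = 0.8        # shared share of the genetic component
    delta: float = 0.3        # noise share of total variance
    phi: float = 0.6          # shared share of the noise component
    p_corr: float = 0.8       # correlation of confounder effects
    n_covariates: int = 5     # excluding the intercept
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("causal_fraction", "h2s", "theta", "delta", "phi", "p_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_samples < self.n_covariates + 2:
            raise ValueError("n_samples must be at least n_covariates + 2")
        if self.h2s + self.delta > 1.0 + 1e-12:
            raise ValueError(
                f"h2s + delta = {self.h2s + self.delta:.3f} > 1 implies a "
                "negative covariate variance share"
            )


def simulate_genotypes(params: SimulationParams) -> pd.DataFrame:
    """Additive 0/1/2 dosage matrix; variant j drawn binomial(2, f_j) with
    f_j uniform in ``maf_range``.  Monomorphic columns are resampled until
    polymorphic so every variant is usable downstream."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.maf_range
    freqs = rng.uniform(lo, hi, size=params.n_variants)
    G = rng.binomial(2, freqs[None, :], size=(params.n_samples, params.n_variants))
    G = G.astype(float)
    # resample monomorphic columns (rare unless maf or N is tiny)
    for _ in range(1000):
        mono = G.std(axis=0) == 0
        if not mono.any():
            break
        idx = np.where(mono)[0]
        G[:, idx] = rng.binomial(
            2, freqs[idx][None, :], size=(params.n_samples, idx.size)
        )
    sample_ids = [f"S{i:06d}" for i in range(params.n_samples)]
    variant_ids = [f"rs{j:07d}" for j in range(params.n_variants)]
    return pd.DataFrame(G, index=sample_ids, columns=variant_ids)


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean(axis=0)
    sd = v.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return v / sd


def _orthonormal_components(raw: np.ndarray) -> np.ndarray:
    """Center the columns of ``raw``, orthogonalize them (QR) and rescale to
    unit sample variance.

    Column 0 keeps its direction; later columns are made exactly orthogonal
    to all earlier ones, so "independent" components contribute zero sample
    correlation between phenotypes rather than the O(1/sqrt(dim)) overlap
    of unadjusted random vectors.
    """
    n, k = raw.shape
    centered = raw - raw.mean(axis=0)
    Q, _ = np.linalg.qr(centered)
    return Q[:, :k] * np.sqrt(n)


def simulate_phenotypes(
    G: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Quantitative phenotypes, covariates (with intercept), and ground
    truth under the additive shared/independent variance-component model."""
    rng = np.random.default_rng(params.seed + 1)
    n, v = G.shape
    m = params.n_phenotypes
    n_causal = int(round(params.causal_fraction * v))
    causal_idx = np.sort(rng.choice(v, size=n_causal, replace=False))
    Gc = _standardize(G.to_numpy()[:, causal_idx]) if n_causal else np.zeros((n, 0))

    var_gen = params.h2s
    var_noise = params.delta
    var_cov = 1.0 - var_gen - var_noise

    Y = np.zeros((n, m))
    effects = np.zeros((v, m))

    if n_causal and var_gen > 0:
        betas = rng.normal(size=(n_causal, m + 1))  # col 0 shared, 1.. independent
        raw = Gc @ betas
        if n_causal >= m + 1:
            comp = _orthonormal_components(raw)
        else:  # too few causal variants to orthogonalize; use raw directions
            comp = _standardize(raw)
        u_shared, u_indep = comp[:, 0], comp[:, 1:]
        w_shared = np.sqrt(var_gen * params.theta)
        w_indep = np.sqrt(var_gen * (1.0 - params.theta))
        Y += w_shared * u_shared[:, None] + w_indep * u_indep
        effects[causal_idx, :] = (
            w_shared * betas[:, :1] + w_indep * betas[:, 1:]
        )

    eps = np.zeros((n, m))
    if var_noise > 0:
        comp = _orthonormal_components(rng.normal(size=(n, m + 1)))
        eps = (
            np.sqrt(var_noise * params.phi) * comp[:, :1]
            + np.sqrt(var_noise * (1.0 - params.phi)) * comp[:, 1:]
        )
        Y += eps

    C = params.n_covariates
    sample_ids = G.index
    Zv = rng.normal(size=(n, C)) if C else np.zeros((n, 0))
    if C and var_cov > 0:
        # confounder directions live in the span of Z; with C > m they can
        # be made mutually orthogonal, otherwise random directions are used
        # and a small residual correlation is unavoidable
        mix = rng.normal(size=(C, m + 1))
        raw = _standardize(Zv) @ mix
        conf_basis = (
            _orthonormal_components(raw) if C >= m + 1 else _standardize(raw)
        )
        conf = (
            np.sqrt(params.p_corr) * conf_basis[:, :1]
            + np.sqrt(1.0 - params.p_corr) * conf_basis[:, 1:]
        )
        Y += np.sqrt(var_cov) * conf

    pheno_ids = [f"P{j:03d}" for j in range(m)]
    X = pd.DataFrame(Y, index=sample_ids, columns=pheno_ids)
    Z = pd.DataFrame(
        np.column_stack([np.ones(n), Zv]),
        index=sample_ids,
        columns=["intercept"] + [f"C{j:02d}" for j in range(C)],
    )
    truth = SimulatedTruth(
        causal_variant_ids=[G.columns[i] for i in causal_idx],
        effect_sizes=pd.DataFrame(effects, index=G.columns, columns=pheno_ids),
        errors=pd.DataFrame(eps, index=sample_ids, columns=pheno_ids),
    )
    return X, Z, truth


def simulate_dataset(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Convenience wrapper returning (G, X, Z, truth)."""
    G = simulate_genotypes(params)
    X, Z, truth = simulate_phenotypes(G, params)
    return G, X, Z, truth


def simulate_binary_features(
    n_samples: int,
    n_features: int,
    prevalence_range: tuple[float, float] = (0.05, 0.3),
    correlation: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Sparse 0/1 indicator features (diagnosis-code-like), generated by
    thresholding correlated latent Gaussians at per-feature prevalences.

    ``correlation`` is the pairwise latent correlation from a single shared
    factor; prevalences are uniform in ``prevalence_range``.
    """
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=(n_samples, 1))
    latent = (
        np.sqrt(correlation) * shared
        + np.sqrt(1.0 - correlation) * rng.normal(size=(n_samples, n_features))
    )
    prev = rng.uniform(*prevalence_range, size=n_features)
    from scipy.stats import norm

    thresh = norm.ppf(1.0 - prev)
    B = (latent > thresh[None, :]).astype(float)
    return pd.DataFrame(
        B,
        index=[f"S{i:06d}" for i in range(n_samples)],
        columns=[f"F{j:03d}" for j in range(n_features)],
    )


def random_projections(
    feature_ids, n_proj: int, seed: int = 0
) -> list[pd.Series]:
    """Dense random linear-combination coefficient vectors, standard normal
    entries, one Series per projection indexed by feature id."""
    feature_ids = pd.Index(feature_ids)
    if len(feature_ids) < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    return [
        pd.Series(rng.normal(size=len(feature_ids)), index=feature_ids)
        for _ in range(n_proj)
    ]


def random_boolean_definitions(
    feature_ids, n_defs: int, seed: int = 0
) -> list[PhenotypeDefinition]:
    """Random two-feature boolean definitions sampled uniformly over the
    families "x AND y", "x OR y" and "x AND NOT y", with distinct features
    in each definition."""
    feature_ids = list(feature_ids)
    if len(feature_ids) < 2:
        raise ValueError("need at least two binary features")
    rng = np.random.default_rng(seed)
    out: list[PhenotypeDefinition] = []
    for _ in range(n_defs):
        a, b = rng.choice(len(feature_ids), size=2, replace=False)
        x, y = FeatureRef(feature_ids[a]), FeatureRef(feature_ids[b])
        family = rng.integers(3)
        if family == 0:
            out.append(And(x, y))
        elif family == 1:
            out.append(Or(x, y))
        else:
            out.append(And(x, Not(y)))
    return out
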