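"""Indirect summary-statistics scan: hand-evaluated formulas, the identity
and scaling invariants, and exactness against the direct OLS oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from projgwas import (
    estimate_genotype_variance,
    indirect_coefficient,
    indirect_sample_size,
    indirect_scan,
    indirect_se,
)
from projgwas.containers import PartialCovariance
from projgwas.direct import gwas_scan, residualize
from projgwas.indirect import genotype_variance_per_feature


class TestGenotypeVariance:
    def test_hand_evaluated_single_feature(self):
        # Var(x)=1, b=1, s=0.1, d=99 -> 1 / (0.99 + 1)
        got = estimate_genotype_variance(
            np.array([1.0]), np.array([0.1]), np.array([1.0]), 99
        )
        assert got == pytest.approx(1.0 / 1.99, rel=1e-12)

    def test_mean_of_single_estimate_is_that_estimate(self):
        b, s, vx = np.array([0.3]), np.array([0.05]), np.array([2.0])
        per = genotype_variance_per_feature(b, s, vx, 50)
        assert estimate_genotype_variance(b, s, vx, 50) == pytest.approx(per[0])

    def test_recovers_true_residual_genotype_variance(self, small_dataset,
                                                      small_stats, rel_err):
        """From shared-dataset feature statistics, every per-feature
        estimate equals g~'g~ / d computed from the genotypes."""
        G, X, Z, _ = small_dataset
        stats, cov = small_stats
        G_res = residualize(G, Z)
        truth = (G_res.values.to_numpy() ** 2).sum(axis=0) / G_res.df
        var_x = cov.variances().to_numpy()
        for j in [0, 40, 149]:
            per = genotype_variance_per_feature(
                stats.beta.iloc[j].to_numpy(), stats.se.iloc[j].to_numpy(),
                var_x, stats.df,
            )
            assert rel_err(per, np.full_like(per, truth[j])) < 1e-10

    def test_degenerate_features_excluded(self):
        got = estimate_genotype_variance(
            np.array([0.0, 1.0]), np.array([0.0, 0.1]), np.array([1.0, 1.0]), 99
        )
        assert got == pytest.approx(1.0 / 1.99, rel=1e-12)
        assert np.isnan(
            estimate_genotype_variance(np.array([0.0]), np.array([0.0]),
                                       np.array([1.0]), 99)
        )


class TestCoefficientAndSe:
    def test_dot_product_and_unit_projection(self):
        b = pd.Series([0.2, -0.1], index=["x", "y"])
        assert indirect_coefficient(b, pd.Series([1.0, 1.0], index=["x", "y"])) == pytest.approx(0.1)
        assert indirect_coefficient(b, pd.Series([0.0, 1.0], index=["x", "y"])) == pytest.approx(-0.1)

    def test_alignment_is_by_id_not_position(self):
        b = pd.Series([0.2, -0.1], index=["x", "y"])
        p_reordered = pd.Series([1.0, 2.0], index=["y", "x"])
        assert indirect_coefficient(b, p_reordered) == pytest.approx(2 * 0.2 - 0.1)
        with pytest.raises(ValueError, match="missing.*extra"):
            indirect_coefficient(b, pd.Series([1.0], index=["z"]))

    def test_se_flags_bad_brackets(self):
        C = PartialCovariance(
            values=pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
            normalization=10,
        )
        p = pd.Series([1.0], index=["x"])
        assert np.isnan(indirect_se(p, C, var_g_hat=-1.0, beta_hat=0.0, df=10))
        # bracket 1/1 - 4 < 0
        assert np.isnan(indirect_se(p, C, var_g_hat=1.0, beta_hat=2.0, df=10))

    def test_sample_size_minimum_over_active_features(self):
        n = pd.Series([1000, 900, 950], index=list("abc"))
        dense = pd.Series([0.5, 1.0, -1.0], index=list("abc"))
        assert indirect_sample_size(n, dense) == 900
        e1 = pd.Series([1.0, 0.0, 0.0], index=list("abc"))
        assert indirect_sample_size(n, e1) == 1000


class TestIndirectScan:
    def test_identity_projection_recovers_feature_row(self, small_stats, rel_err):
        stats, cov = small_stats
        for i, fid in enumerate(stats.feature_ids):
            e = pd.Series(0.0, index=stats.feature_ids)
            e[fid] = 1.0
            res = indirect_scan(stats, cov, [e])[0]
            assert rel_err(res["beta"], stats.beta[fid]) < 1e-10
            assert rel_err(res["se"], stats.se[fid]) < 1e-10
            assert (res["n"] == stats.n[fid]).all()

    def test_matches_direct_scan_on_projected_phenotype(
        self, small_dataset, small_stats, rel_err
    ):
        from projgwas import random_projections

        G, X, Z, _ = small_dataset
        stats, cov = small_stats
        projs = random_projections(X.columns, 5, seed=99)
        results = indirect_scan(stats, cov, projs)
        for p, res in zip(projs, results):
            direct = gwas_scan(G, X @ p, Z)
            for col in ("beta", "se", "p_value"):
                assert rel_err(res[col], direct[col]) < 1e-8

    def test_scale_equivariance(self, small_stats, rel_err):
        stats, cov = small_stats
        p = pd.Series(np.linspace(-1, 1, len(stats.feature_ids)),
                      index=stats.feature_ids)
        base, scaled = indirect_scan(stats, cov, [p, 3.0 * p])
        assert rel_err(scaled["beta"], 3.0 * base["beta"]) < 1e-12
        assert rel_err(scaled["se"], 3.0 * base["se"]) < 1e-12
        assert rel_err(scaled["t_stat"], base["t_stat"]) < 1e-12

    def test_zero_projection_flagged(self, small_stats):
        stats, cov = small_stats
        res = indirect_scan(stats, cov, [pd.Series(0.0, index=stats.feature_ids)])[0]
        assert (res["beta"] == 0).all()
        assert res["se"].isna().all()

    def test_chunk_and_worker_invariance(self, small_stats):
        stats, cov = small_stats
        p = pd.Series(np.ones(len(stats.feature_ids)), index=stats.feature_ids)
        base = indirect_scan(stats, cov, [p])[0]
        for chunk, workers in [(1, 1), (7, 1), (None, 4), (7, 4)]:
            other = indirect_scan(stats, cov, [p], chunk_size=chunk,
                                  n_workers=workers)[0]
            for col in ("beta", "se", "t_stat", "p_value", "var_g_hat"):
                np.testing.assert_allclose(base[col], other[col], rtol=0, atol=1e-12)

    def test_feature_mismatch_lists_symmetric_difference(self, small_stats):
        stats, cov = small_stats
        bad = cov.values.rename(index={cov.feature_ids[0]: "ZZZ"},
                                columns={cov.feature_ids[0]: "ZZZ"})
        bad_cov = PartialCovariance(values=bad, normalization=cov.normalization)
        with pytest.raises(ValueError, match="ZZZ"):
            indirect_scan(stats, bad_cov, [pd.Series(1.0, index=stats.feature_ids)])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    coeffs=st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=6,
        max_size=6,
    ),
    scale=st.floats(min_value=0.01, max_value=100, allow_nan=False),
)
def test_property_positive_scaling_preserves_t(small_stats_global, coeffs, scale):
    """For any projection and positive scale c, beta and SE scale by c while
    t statistics are unchanged."""
    stats, cov = small_stats_global
    p = pd.Series(coeffs, index=stats.feature_ids)
    if np.allclose(p, 0):
        return
    base, scaled = indirect_scan(stats, cov, [p, scale * p])
    ok = base["se"].notna() & scaled["se"].notna()
    np.testing.assert_allclose(scaled["beta"][ok], scale * base["beta"][ok],
                               rtol=1e-9)
    np.testing.assert_allclose(scaled["t_stat"][ok], base["t_stat"][ok],
                               rtol=1e-9)


@pytest.fixture(scope="module")
def small_stats_global(small_stats):
    return small_stats
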