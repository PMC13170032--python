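"""Phenotype definitions: parsing round trips, boolean/fuzzy evaluation
semantics, and least-squares linearization with its quality gauge."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from projgwas import (
    evaluate_definition,
    fit_quality,
    linearize,
    parse_definition,
    serialize_definition,
)
from projgwas.phenodef import (
    And,
    Comparison,
    Constant,
    DefinitionSyntaxError,
    FeatureRef,
    Not,
    Or,
)


class TestParsing:
    def test_prefix_and_not(self):
        d = parse_definition("and E119 (not I10)")
        assert d == And(FeatureRef("E119"), Not(FeatureRef("I10")))

    def test_comparison_with_threshold(self):
        d = parse_definition("gt BMI 30")
        assert isinstance(d, Comparison)
        assert d.op == "gt" and d.threshold == 30.0
        assert d.child == FeatureRef("BMI")

    def test_numeric_token_is_constant(self):
        d = parse_definition("mul BMI 2.5")
        assert d.right == Constant(2.5)

    @pytest.mark.parametrize(
        "text",
        [
            "and E119 (not I10)",
            "or (and A B) (not C)",
            "gt (add BMI 1.5) 30",
            "sub (mul A B) (le C 0.5)",
        ],
    )
    def test_round_trip_prefix_and_json(self, text):
        d = parse_definition(text)
        assert parse_definition(d.to_prefix()) == d
        assert parse_definition(json.dumps(d.to_dict())) == d
        assert parse_definition(serialize_definition(d, "json")) == d

    def test_malformed_syntax_reports_position(self):
        with pytest.raises(DefinitionSyntaxError):
            parse_definition("and E119")
        with pytest.raises(DefinitionSyntaxError):
            parse_definition("gt BMI notanumber")
        with pytest.raises(DefinitionSyntaxError):
            parse_definition("(and A B))")

    def test_unknown_feature_against_catalog(self):
        with pytest.raises(ValueError, match="XXX"):
            parse_definition("and A XXX", feature_catalog=["A", "B"])


class TestEvaluation:
    @pytest.fixture()
    def crisp(self):
        return pd.DataFrame(
            {"a": [1.0, 0.0, 1.0, 0.0], "b": [1.0, 1.0, 0.0, 0.0]},
            index=list("wxyz"),
        )

    def test_truth_tables(self, crisp):
        assert evaluate_definition(
            parse_definition("and a (not b)"), crisp
        ).tolist() == [0, 0, 1, 0]
        assert evaluate_definition(parse_definition("or a b"), crisp).tolist() == [
            1, 1, 1, 0,
        ]

    def test_fuzzy_semantics_on_fractional_inputs(self):
        X = pd.DataFrame({"a": [0.3], "b": [0.6]})
        assert evaluate_definition(parse_definition("and a b"), X).iloc[0] == 0.3
        assert evaluate_definition(parse_definition("or a b"), X).iloc[0] == 0.6
        assert evaluate_definition(parse_definition("not a"), X).iloc[0] == pytest.approx(0.7)

    def test_product_mode_coincides_on_crisp_data(self, crisp):
        for text in ("and a b", "or a b", "and a (not b)"):
            d = parse_definition(text)
            a = evaluate_definition(d, crisp, bool_mode="minmax")
            b = evaluate_definition(d, crisp, bool_mode="product")
            pd.testing.assert_series_equal(a, b)

    def test_boolean_node_rejects_out_of_range(self):
        X = pd.DataFrame({"a": [2.0], "b": [0.5]})
        with pytest.raises(ValueError, match="outside"):
            evaluate_definition(parse_definition("and a b"), X)

    def test_comparisons_and_arithmetic(self):
        X = pd.DataFrame({"bmi": [25.0, 30.0, 35.0]})
        assert evaluate_definition(parse_definition("gt bmi 30"), X).tolist() == [0, 0, 1]
        assert evaluate_definition(parse_definition("ge bmi 30"), X).tolist() == [0, 1, 1]
        assert evaluate_definition(parse_definition("add bmi 5"), X).tolist() == [30, 35, 40]

    def test_depth_three_matches_truth_table_enumeration(self):
        """Boolean evaluation on {0,1} data agrees with brute-force logic
        for all operator trees up to depth 3 over 3 features."""
        rows = list(itertools.product([0.0, 1.0], repeat=3))
        X = pd.DataFrame(rows, columns=["a", "b", "c"])

        def brute(node, row):
            if isinstance(node, FeatureRef):
                return row[{"a": 0, "b": 1, "c": 2}[node.feature_id]]
            if isinstance(node, Not):
                return 1.0 - brute(node.child, row)
            l, r = brute(node.left, row), brute(node.right, row)
            return {And: min, Or: max}[type(node)](l, r)

        leaves = [FeatureRef(f) for f in "abc"]
        depth2 = [op(l, r) for op in (And, Or) for l in leaves for r in leaves] + [
            Not(l) for l in leaves
        ]
        depth3 = [op(l, r) for op in (And, Or) for l in depth2[:8] for r in leaves] + [
            Not(d) for d in depth2[:8]
        ]
        for d in depth2 + depth3:
            got = evaluate_definition(d, X).to_numpy()
            want = np.array([brute(d, row) for row in rows])
            np.testing.assert_array_equal(got, want)


class TestLinearize:
    def test_exact_linear_target_recovers_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x1", "x2"])
        y = 2.0 * X["x1"] - X["x2"] + 3.0
        approx = linearize(y, X)
        np.testing.assert_allclose(approx.coefficients, [2.0, -1.0], atol=1e-10)
        assert approx.intercept == pytest.approx(3.0, abs=1e-10)
        assert approx.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_target_gives_zero_r2(self, rng):
        X = pd.DataFrame({"x1": np.repeat([1.0, -1.0], 50)})
        y = pd.Series(np.tile([1.0, -1.0], 50))  # orthogonal to x1 and constant
        approx = linearize(y, X)
        assert approx.fit_r2 == pytest.approx(0.0, abs=1e-10)

    def test_and_of_independent_rare_binaries_fits_poorly(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(
            {"x1": rng.binomial(1, 0.05, 4000).astype(float),
             "x2": rng.binomial(1, 0.05, 4000).astype(float)}
        )
        y = np.minimum(X["x1"], X["x2"])
        or_y = np.maximum(X["x1"], X["x2"])
        r2_and = linearize(y, X).fit_r2
        r2_or = linearize(or_y, X).fit_r2
        assert r2_and < 0.4  # conjunctions of independent rare codes fit poorly
        assert r2_or > 0.8   # disjunctions are nearly linear

    def test_nested_feature_monotonicity(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=[f"x{i}" for i in range(6)])
        y = pd.Series(rng.normal(size=200), index=X.index)
        r2s = [linearize(y, X.iloc[:, :m]).fit_r2 for m in range(1, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_rank_deficient_features_warn_not_fail(self, rng, caplog):
        X = pd.DataFrame({"x1": rng.normal(size=50)})
        X["x2"] = X["x1"]
        y = X["x1"] * 2.0
        approx = linearize(y, X)
        assert approx.fit_r2 == pytest.approx(1.0, abs=1e-10)


class TestFitQuality:
    def test_identities(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert fit_quality(y, y) == pytest.approx(1.0)
        assert fit_quality(y, pd.Series([2.5] * 4)) == pytest.approx(0.0)
        assert np.isnan(fit_quality(pd.Series([1.0, 1.0, 1.0]),
                                    pd.Series([1.0, 1.0, 1.0])))

    def test_equals_squared_pearson_for_ols_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = pd.Series(
            X["a"] - 2 * X["b"] + rng.normal(size=80), index=X.index
        )
        approx = linearize(y, X)
        y_hat = approx.intercept + X.to_numpy() @ approx.coefficients.to_numpy()
        r2 = fit_quality(y, y_hat)
        pearson = np.corrcoef(y, y_hat)[0, 1]
        assert r2 == pytest.approx(pearson**2, abs=1e-10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=2, max_size=10))
def test_property_fuzzy_ops_stay_in_unit_interval(pairs):
    X = pd.DataFrame(pairs, columns=["a", "b"])
    for text in ("and a b", "or a b", "not a", "and a (not b)"):
        v = evaluate_definition(parse_definition(text), X)
        assert ((v >= 0) & (v <= 1)).all()
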