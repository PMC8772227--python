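"""Composite derivation: weight rule, selection rule, penalized-fit oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftdcog import (
    CompositeDefinition,
    CompositeError,
    compute_composite,
    derive_weights,
    average_definition,
    fit_penalized_logistic,
    published_coefficients,
    published_definitions,
    select_tests,
    weights_from_coefficients,
)
from ftdcog.battery import DEFAULT_BATTERY
from ftdcog.composite import FitError, PenalizedFit, fit_at_lambda, lambda_max


def _fit_from(coefs, gene="g"):
    return PenalizedFit(
        gene=gene, coefficients=dict(coefs), intercept=0.0,
        lambda_grid=np.array([0.1]), cv_deviance=np.array([1.0]),
        cv_deviance_se=np.array([0.1]), chosen_lambda=0.1, fold_seed=0,
        n_cases=10, n_controls=10,
    )


# ---------------------------------------------------------------- weight rule

@pytest.mark.parametrize("gene", ["C9orf72", "GRN", "MAPT"])
def test_published_weights_reproduce_from_published_coefficients(gene):
    """|coef|/sum|coef| over the negative coefficients reproduces every
    published weight at its printed precision."""
    table = published_coefficients()
    sub = table[table["gene"] == gene]
    coefs = dict(zip(sub["test"], sub["coefficient"]))
    definition = weights_from_coefficients(coefs, gene=gene)
    printed = dict(zip(sub["test"], sub["printed_weight"]))
    excluded = set(sub.loc[sub["excluded"], "test"])
    assert set(definition.tests) == set(sub["test"]) - excluded
    for t in definition.tests:
        decimals = 3 if printed[t] < 0.01 else 2
        assert round(definition.weights[t], decimals) == pytest.approx(printed[t]), (gene, t)


def test_weight_rule_on_already_normalized_coefficients():
    d = derive_weights(_fit_from({"a": -0.5, "b": -0.3, "c": -0.2}))
    assert d.weights == pytest.approx({"a": 0.5, "b": 0.3, "c": 0.2})


def test_selection_keeps_only_strictly_negative_in_battery_order():
    coefs = {t: 0.0 for t in DEFAULT_BATTERY.ids}
    coefs["tmt_b"] = -0.1
    coefs["fcsrt_free"] = -0.3
    coefs["phonemic_fluency"] = 0.2  # positive -> excluded
    sel = select_tests(_fit_from(coefs))
    assert sel == ["tmt_b", "fcsrt_free"]  # battery order


def test_all_zero_coefficients_raise_empty_composite_error():
    with pytest.raises(CompositeError, match="no tests with negative"):
        select_tests(_fit_from({t: 0.0 for t in DEFAULT_BATTERY.ids}))


@given(
    st.dictionaries(
        st.sampled_from(DEFAULT_BATTERY.ids),
        st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
        min_size=3,
    ).filter(lambda d: any(v < -1e-6 for v in d.values()))
)
@settings(deadline=None, max_examples=50)
def test_weights_always_positive_normalized_and_exclude_positives(coefs):
    d = derive_weights(_fit_from(coefs))
    assert sum(d.weights.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(w > 0 for w in d.weights.values())
    assert all(coefs[t] < 0 for t in d.tests)


# ------------------------------------------------------------- compute values

def _z_frame(rows, cols):
    return pd.DataFrame(rows, columns=cols, index=[f"p{i}" for i in range(len(rows))])


def test_composite_weighted_arithmetic_and_zero_input():
    d = CompositeDefinition(gene="g", mode="weighted", tests=["a", "b"], weights={"a": 0.25, "b": 0.75})
    z = _z_frame([[-1.0, -2.0], [0.0, 0.0]], ["a", "b"])
    vals = compute_composite(z, d)
    assert vals["p0"] == pytest.approx(-1.75)
    assert vals["p1"] == pytest.approx(0.0)


def test_average_equals_weighted_on_equal_z():
    za = _z_frame([[-1.3, -1.3, -1.3]], ["a", "b", "c"])
    w = CompositeDefinition(gene="g", mode="weighted", tests=["a", "b", "c"], weights={"a": 0.6, "b": 0.3, "c": 0.1})
    a = CompositeDefinition(gene="g", mode="average", tests=["a", "b", "c"], weights={t: 1 / 3 for t in "abc"})
    assert compute_composite(za, w)["p0"] == pytest.approx(compute_composite(za, a)["p0"])


def test_missing_policy_strict_vs_renormalize():
    d = CompositeDefinition(gene="g", mode="weighted", tests=["a", "b"], weights={"a": 0.25, "b": 0.75})
    z = _z_frame([[-2.0, np.nan]], ["a", "b"])
    assert np.isnan(compute_composite(z, d, missing="strict")["p0"])
    assert compute_composite(z, d, missing="renormalize")["p0"] == pytest.approx(-2.0)


def test_unknown_test_in_definition_raises_schema_error():
    d = CompositeDefinition(gene="g", mode="weighted", tests=["nope"], weights={"nope": 1.0})
    with pytest.raises(CompositeError, match="nope"):
        compute_composite(_z_frame([[0.0]], ["a"]), d)


def test_definition_weight_invariants_enforced():
    with pytest.raises(ValueError, match="sum to 1"):
        CompositeDefinition(gene="g", mode="weighted", tests=["a"], weights={"a": 0.5})
    with pytest.raises(ValueError, match="mode"):
        CompositeDefinition(gene="g", mode="median", tests=["a"], weights={"a": 1.0})


def test_published_definitions_fixture_integrity():
    for mode in ("weighted", "average"):
        defs = published_definitions(mode)
        assert set(defs) == {"C9orf72", "GRN", "MAPT"}
        for d in defs.values():
            assert sum(d.weights.values()) == pytest.approx(1.0, abs=1e-12)
        # positive-coefficient tests never appear
        assert "phonemic_fluency" not in defs["GRN"].tests
        assert "cwit_word" not in defs["GRN"].tests


# ------------------------------------------------------------ penalized fit

def _toy_logistic(n=400, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    eta = 0.6 * X[:, 0] - 0.9 * X[:, 1] + 0.1
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(X, columns=["a", "b"]), y


def test_negligible_penalty_matches_unpenalized_logistic_oracle():
    statsmodels = pytest.importorskip("statsmodels.api")
    z, y = _toy_logistic()
    ours = fit_at_lambda(z, y, 1e-8)
    oracle = statsmodels.Logit(y, statsmodels.add_constant(z.to_numpy())).fit(disp=0)
    assert ours["a"] == pytest.approx(oracle.params[1], abs=1e-4)
    assert ours["b"] == pytest.approx(oracle.params[2], abs=1e-4)


def test_full_shrinkage_at_analytic_lambda_max():
    z, y = _toy_logistic(seed=3)
    Xs = (z - z.mean()) / z.std(ddof=0)
    lmax = lambda_max(Xs.to_numpy(), y.astype(float))
    for lam in (lmax, 2 * lmax):
        assert all(v == 0.0 for v in fit_at_lambda(z, y, lam).values())
    # just below lambda_max at least one coefficient wakes up
    assert any(v != 0.0 for v in fit_at_lambda(z, y, 0.8 * lmax).values())


def test_nonzero_count_monotone_in_lambda():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((300, 6))
    beta = np.array([1.0, -0.8, 0.5, 0.0, 0.0, 0.0])
    y = (rng.random(300) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
    z = pd.DataFrame(X, columns=list("abcdef"))
    lmax = lambda_max(((X - X.mean(0)) / X.std(0)), y.astype(float))
    counts = [
        sum(v != 0.0 for v in fit_at_lambda(z, y, lam).values())
        for lam in lmax * np.logspace(0, -2.5, 8)
    ]
    assert all(b >= a for a, b in zip(counts, counts[1:]))  # descending lambda


def test_cv_fit_contract_and_reproducibility():
    z, y = _toy_logistic(n=300, seed=5)
    fit1 = fit_penalized_logistic(z, y, folds=5, seed=2, n_lambda=30, gene="toy")
    fit2 = fit_penalized_logistic(z, y, folds=5, seed=2, n_lambda=30, gene="toy")
    assert fit1.coefficients == fit2.coefficients
    assert fit1.chosen_lambda in fit1.lambda_grid
    assert set(fit1.coefficients) == {"a", "b"}
    assert fit1.n_cases + fit1.n_controls == 300
    assert len(fit1.cv_deviance) == 30


def test_complete_case_exclusion_and_small_sample_errors():
    z, y = _toy_logistic(n=60)
    z_missing = z.copy()
    z_missing.iloc[:55, 0] = np.nan  # only 5 complete cases
    with pytest.raises(FitError, match="complete-case"):
        fit_penalized_logistic(z_missing, y, folds=10)
    with pytest.raises(FitError, match="constant predictor"):
        zc = z.copy()
        zc["a"] = 1.0
        fit_penalized_logistic(zc, y, folds=10)


def test_one_se_rule_chooses_no_smaller_penalty_than_min_rule():
    z, y = _toy_logistic(n=300, seed=9)
    f_min = fit_penalized_logistic(z, y, folds=5, seed=0, n_lambda=30)
    f_1se = fit_penalized_logistic(z, y, folds=5, seed=0, n_lambda=30, lambda_rule="1se")
    assert f_1se.chosen_lambda >= f_min.chosen_lambda


def test_weighted_composite_separates_at_least_as_well_as_median_test(c9_fit):
    """Standardized carrier/control mean difference of the weighted composite
    is at least that of the median individual battery test."""
    fit, z, labels = c9_fit
    d = derive_weights(fit)
    comp = compute_composite(z, d, missing="renormalize")
    y = labels.to_numpy().astype(bool)

    def smd(vals):
        v = pd.Series(vals)
        a, b = v[y].dropna(), v[~y].dropna()
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        return abs(a.mean() - b.mean()) / pooled

    smd_tests = [smd(z[t]) for t in z.columns]
    assert smd(comp) >= np.median(smd_tests)
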