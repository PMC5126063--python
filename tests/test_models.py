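"""Statistical chain: screen, elimination, LMG shares, confounding, ROC, forest."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pdqeeg.models import (
    backward_eliminate,
    confound_check,
    lmg_decomposition,
    normality_check,
    rf_importance,
    roc_analysis,
    univariate_screen,
)


def _df(rng, n, p, prefix="x"):
    return pd.DataFrame(rng.standard_normal((n, p)),
                        columns=[f"{prefix}{i}" for i in range(p)])


# ---------------------------------------------------------------- normality

def test_shapiro_on_gaussian_and_heavy_tails(rng):
    _stat, p_norm = normality_check(rng.standard_normal(5000))
    assert p_norm > 0.01
    _stat, p_exp = normality_check(rng.exponential(size=200))
    assert p_exp < 0.01


def test_shapiro_preconditions():
    with pytest.raises(ValueError):
        normality_check([1.0, 2.0])
    with pytest.raises(ValueError, match="constant"):
        normality_check([1.0, 1.0, 1.0, 1.0])


# ------------------------------------------------------------------- screen

def test_screen_recovers_strong_predictor(rng):
    x = _df(rng, 100, 3)
    y = 2.0 * x["x0"] + 0.001 * rng.standard_normal(100)
    table, selected = univariate_screen(y, x)
    assert "x0" in selected
    assert table.loc["x0", "beta"] == pytest.approx(2.0, abs=0.01)


def test_screen_skips_constant_predictor(rng):
    x = _df(rng, 50, 2)
    x["flat"] = 1.0
    _table, selected = univariate_screen(pd.Series(rng.standard_normal(50)), x)
    assert "flat" not in selected


def test_screen_type_one_error_is_calibrated():
    """A pure-noise predictor passes the alpha=0.05 screen about 5% of the time."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = _df(rng, 200, 1)
        y = pd.Series(rng.standard_normal(200))
        _t, selected = univariate_screen(y, x)
        hits += "x0" in selected
    assert 2 <= hits <= 10


# -------------------------------------------------------------- elimination

def test_elimination_keeps_all_active_predictors(rng):
    x = _df(rng, 400, 3)
    y = 1.0 * x["x0"] - 0.8 * x["x1"] + 0.6 * x["x2"] + 0.3 * rng.standard_normal(400)
    final = backward_eliminate(y, x)
    assert sorted(final.predictors) == ["x0", "x1", "x2"]


def test_elimination_removes_pure_noise(rng):
    removed = 0
    for seed in range(40):
        r = np.random.default_rng(seed)
        x = _df(r, 200, 3)
        y = 1.0 * x["x0"] + 0.7 * x["x1"] + r.standard_normal(200)
        final = backward_eliminate(y, x)
        removed += "x2" not in final.predictors
    assert removed >= 36      # >= 90% of runs


def test_single_significant_predictor_is_fixed_point(rng):
    x = _df(rng, 100, 1)
    y = x["x0"] + 0.2 * rng.standard_normal(100)
    final = backward_eliminate(y, x)
    assert final.predictors == ["x0"]


def test_collinear_predictors_rejected(rng):
    x = _df(rng, 100, 2)
    x["dup"] = x["x0"] * 2.0
    with pytest.raises(ValueError, match="collinear"):
        backward_eliminate(pd.Series(rng.standard_normal(100)), x)


def test_elimination_result_independent_of_column_order(rng):
    x = _df(rng, 150, 4)
    y = x["x0"] + 0.5 * x["x1"] + rng.standard_normal(150)
    a = backward_eliminate(y, x)
    b = backward_eliminate(y, x[["x3", "x1", "x0", "x2"]])
    assert a.predictors == b.predictors
    assert a.adj_r2 == pytest.approx(b.adj_r2)


# ---------------------------------------------------------------------- LMG

def _lmg_bruteforce(y, x):
    """Average sequential R² gain over every ordering (independent oracle)."""
    cols = list(x.columns)
    shares = dict.fromkeys(cols, 0.0)
    orderings = list(permutations(cols))
    for order in orderings:
        seen = []
        prev = 0.0
        for c in order:
            seen.append(c)
            r2 = sm.OLS(y, sm.add_constant(x[seen])).fit().rsquared
            shares[c] += r2 - prev
            prev = r2
    return {c: 100.0 * v / len(orderings) for c, v in shares.items()}


def test_lmg_matches_bruteforce_ordering_average(rng):
    for _ in range(10):
        x = _df(rng, 60, 3)
        x["x1"] += 0.6 * x["x0"]          # make them correlated
        y = x["x0"] + 0.5 * x["x1"] - 0.3 * x["x2"] + rng.standard_normal(60)
        fast = lmg_decomposition(y, x)
        slow = _lmg_bruteforce(y, x)
        for c in x.columns:
            assert fast[c] == pytest.approx(slow[c], abs=1e-10)


def test_lmg_shares_sum_to_explained_variance(rng):
    x = _df(rng, 80, 4)
    y = x.sum(axis=1) + rng.standard_normal(80)
    shares = lmg_decomposition(y, x)
    r2 = sm.OLS(y, sm.add_constant(x)).fit().rsquared
    assert sum(shares.values()) == pytest.approx(100 * r2, abs=1e-6)


def test_lmg_orthogonal_predictors_get_univariate_r2(rng):
    raw = rng.standard_normal((200, 3))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    x = pd.DataFrame(q, columns=["a", "b", "c"])
    y = 1.0 * x["a"] + 0.5 * x["b"] + 0.1 * rng.standard_normal(200)
    shares = lmg_decomposition(y, x)
    for c in x.columns:
        uni = sm.OLS(y, sm.add_constant(x[[c]])).fit().rsquared
        assert shares[c] == pytest.approx(100 * uni, abs=1e-8)


def test_lmg_single_predictor_share_is_model_r2(rng):
    x = _df(rng, 50, 1)
    y = 2 * x["x0"] + rng.standard_normal(50)
    shares = lmg_decomposition(y, x)
    r2 = sm.OLS(y, sm.add_constant(x)).fit().rsquared
    assert shares["x0"] == pytest.approx(100 * r2, abs=1e-10)


def test_lmg_refuses_more_than_twelve_predictors(rng):
    x = _df(rng, 30, 13)
    with pytest.raises(ValueError, match="12 predictors"):
        lmg_decomposition(pd.Series(rng.standard_normal(30)), x)


# ---------------------------------------------------------------- confounds

def test_independent_confounders_do_not_shift_share(rng):
    n = 2000
    data = _df(rng, n, 1, prefix="pred")
    data[["age", "sex_male", "education_years"]] = rng.standard_normal((n, 3))
    y = 1.0 * data["pred0"] + rng.standard_normal(n)
    out = confound_check(y, ["pred0"], data)
    assert bool(out.loc["pred0", "no_confounding"])
    assert abs(out.loc["pred0", "delta_pct"]) < 2.0


def test_confounder_identical_to_predictor_errors(rng):
    data = _df(rng, 100, 1, prefix="pred")
    data["age"] = data["pred0"]
    data["sex_male"] = rng.standard_normal(100)
    data["education_years"] = rng.standard_normal(100)
    y = pd.Series(rng.standard_normal(100))
    with pytest.raises(ValueError, match="collinear"):
        confound_check(y, ["pred0"], data)


# ---------------------------------------------------------------------- ROC

def test_perfect_marker_has_unit_auc():
    out = roc_analysis(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
    assert out.auc == pytest.approx(1.0)
    assert out.sensitivity == pytest.approx(1.0)
    assert out.specificity == pytest.approx(1.0)


def test_null_marker_auc_is_half(rng):
    m = rng.standard_normal(2000)
    y = rng.random(2000) < 0.3
    out = roc_analysis(m, y)
    assert out.auc == pytest.approx(0.5, abs=0.03)


def test_auc_invariant_under_monotone_transform(rng):
    m = rng.standard_normal(300)
    y = (m + rng.standard_normal(300) > 0).astype(int)
    a = roc_analysis(m, y).auc
    b = roc_analysis(np.exp(2 * m), y).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_auc_of_negated_marker_complements(rng):
    m = rng.standard_normal(500)
    y = (m + rng.standard_normal(500) > 0).astype(int)
    assert roc_analysis(m, y).auc + roc_analysis(-m, y).auc == pytest.approx(1.0)


def test_one_class_outcome_rejected():
    with pytest.raises(ValueError, match="both outcome classes"):
        roc_analysis(np.arange(5.0), np.zeros(5))


# -------------------------------------------------------------- forest

def test_rf_importance_is_seed_deterministic(rng):
    x = _df(rng, 60, 4)
    y = x["x0"] + 0.5 * rng.standard_normal(60)
    a = rf_importance(y, x, n_trees=50, seed=4)
    b = rf_importance(y, x, n_trees=50, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_rf_ranks_the_driving_variable_first():
    wins = 0
    for seed in range(5):
        r = np.random.default_rng(seed)
        x = _df(r, 150, 6)
        y = np.sin(2 * x["x0"]) + 0.3 * r.standard_normal(150)
        imp = rf_importance(pd.Series(y), x, n_trees=100, seed=seed)
        wins += imp.index[0] == "x0"
    assert wins == 5


def test_rf_null_outcome_importances_hover_near_zero(rng):
    x = _df(rng, 150, 5)
    y = pd.Series(rng.standard_normal(150))
    imp = rf_importance(y, x, n_trees=100, seed=0)
    assert np.all(np.abs(imp["mda"]) < 0.5 * y.var())


def test_rf_rejects_constant_outcome(rng):
    x = _df(rng, 30, 2)
    with pytest.raises(ValueError, match="constant outcome"):
        rf_importance(pd.Series(np.ones(30)), x)
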