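"""Screening, ordinal/binary MLE, Brant and VIF diagnostics, pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cvmstage import (
    PRIMARY_MODEL,
    DevelopConfig,
    FittingError,
    OrdinalStageModel,
    brant_test,
    develop_model,
    fit_binary_logistic,
    fit_proportional_odds,
    simulate_features_from_model,
    spearman_screen,
    vif,
    zscore,
)
from cvmstage.synthetic import POOLED_FEATURE_DISTRIBUTIONS


# ---------------------------------------------------------------- z-scoring

def test_zscore_standardizes_and_round_trips():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": rng.normal(3, 2, 100), "b": rng.uniform(0, 1, 100)})
    z, std = zscore(df)
    assert z.mean().abs().max() < 1e-9
    assert (z.std(ddof=1) - 1).abs().max() < 1e-9
    pd.testing.assert_frame_equal(std.inverse(z), df, rtol=0, atol=1e-9)


def test_zscore_rejects_constant_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.raises(FittingError, match="flat"):
        zscore(df)


# ----------------------------------------------------------------- screening

def test_spearman_perfect_and_monotone_transform():
    stages = np.repeat([1, 2, 3, 4], 10)
    df = pd.DataFrame({"exact": stages.astype(float),
                       "mono": np.exp(stages.astype(float))})
    report = spearman_screen(df, stages)
    assert report.loc["exact", "rho"] == pytest.approx(1.0)
    assert report.loc["mono", "rho"] == pytest.approx(1.0)
    assert report["selected"].all()


def test_spearman_null_false_positive_rate_near_alpha():
    """Independent noise at n=480: the screen should fire at roughly the
    nominal 5% rate."""
    rng = np.random.default_rng(12)
    stages = np.repeat([1, 2, 3, 4], 120)
    hits = 0
    n_sim = 400
    for _ in range(n_sim):
        df = pd.DataFrame({"noise": rng.normal(size=480)})
        hits += int(spearman_screen(df, stages)["selected"].iloc[0])
    rate = hits / n_sim
    assert 0.02 < rate < 0.09


# -------------------------------------------------------------- binary logit

def two_by_two_frame(a, b, c, d):
    """x=1 rows: a successes, b failures; x=0 rows: c successes, d failures.
    'Success' = the more mature class (is_lower = 0)."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    is_lower = np.concatenate([np.zeros(a), np.ones(b), np.zeros(c), np.ones(d)])
    return pd.DataFrame({"x": x}), is_lower.astype(int)


def test_binary_logistic_matches_2x2_log_odds_ratio():
    a, b, c, d = 40, 20, 15, 45
    X, is_lower = two_by_two_frame(a, b, c, d)
    fit = fit_binary_logistic(X, is_lower, ["x"])
    # closed form: slope = log odds ratio, alpha = -log odds at x=0
    assert fit.slopes["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-5)
    assert fit.thresholds[0] == pytest.approx(-np.log(c / d), abs=1e-5)
    se_expected = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert fit.table.loc["x", "SE"] == pytest.approx(se_expected, abs=1e-5)


def test_balanced_label_independent_data_has_zero_slope():
    X = pd.DataFrame({"x": np.tile([0.0, 1.0], 50)})
    is_lower = np.tile([0, 0, 1, 1], 25)
    fit = fit_binary_logistic(X, is_lower, ["x"])
    assert fit.slopes["x"] == pytest.approx(0.0, abs=1e-6)


def test_two_stage_proportional_odds_equals_binary_logistic():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"x": rng.normal(size=400), "w": rng.normal(size=400)})
    p_mature = expit(0.8 * X["x"] - 0.4 * X["w"] - 0.2)
    stage = 3 + (rng.random(400) < p_mature).astype(int)  # stages {3, 4}
    po = fit_proportional_odds(X, stage, ["x", "w"])
    bl = fit_binary_logistic(X, (stage == 3).astype(int), ["x", "w"])
    assert po.slopes["x"] == pytest.approx(bl.slopes["x"], abs=1e-4)
    assert po.slopes["w"] == pytest.approx(bl.slopes["w"], abs=1e-4)
    assert po.thresholds[0] == pytest.approx(bl.thresholds[0], abs=1e-4)


# ------------------------------------------------------- proportional odds

TRUE_MODEL = OrdinalStageModel(
    slopes={"D2": 0.8, "UW3": -0.5, "PH4": 1.2},
    thresholds=(-1.0, 0.5, 2.0),
)
TRUE_DISTS = {"D2": (0.0, 1.0), "UW3": (0.0, 1.0), "PH4": (0.0, 1.0)}


def test_proportional_odds_recovers_known_slopes():
    X, stages = simulate_features_from_model(TRUE_MODEL, 3000, TRUE_DISTS, seed=17)
    fit = fit_proportional_odds(X, stages, list(TRUE_MODEL.slopes))
    assert fit.converged
    for name, truth in TRUE_MODEL.slopes.items():
        se = fit.table.loc[name, "SE"]
        assert abs(fit.slopes[name] - truth) < 3 * se, name
    for j, truth in enumerate(TRUE_MODEL.thresholds):
        assert abs(fit.thresholds[j] - truth) < 3 * fit.table.loc[f"alpha_{j+1}", "SE"]


def test_fit_table_internal_consistency():
    X, stages = simulate_features_from_model(TRUE_MODEL, 800, TRUE_DISTS, seed=23)
    fit = fit_proportional_odds(X, stages, list(TRUE_MODEL.slopes))
    t = fit.table
    np.testing.assert_allclose(t["Wald"], (t["B"] / t["SE"]) ** 2, rtol=1e-6)
    np.testing.assert_allclose(t["ci_low"], t["B"] - 1.959964 * t["SE"], atol=1e-6)
    np.testing.assert_allclose(t["ci_high"], t["B"] + 1.959964 * t["SE"], atol=1e-6)
    assert fit.thresholds == sorted(fit.thresholds)
    model = fit.to_ordinal_model()
    assert model.thresholds[0] < model.thresholds[1] < model.thresholds[2]


def test_table4_calibrated_cohort_gives_positive_slopes():
    """On features simulated under the published model, all four fitted
    slopes must come out positive (matching the published signs)."""
    X, stages = simulate_features_from_model(
        PRIMARY_MODEL, 2000, POOLED_FEATURE_DISTRIBUTIONS, seed=29, correlation=0.4)
    fit = fit_proportional_odds(X, stages, list(PRIMARY_MODEL.slopes))
    assert all(v > 0 for v in fit.slopes.values())


def test_degenerate_designs_are_rejected():
    X = pd.DataFrame({"x": np.ones(50)})
    with pytest.raises(FittingError, match="zero-variance"):
        fit_proportional_odds(X, np.tile([1, 2], 25), ["x"])
    X2 = pd.DataFrame({"x": np.arange(50.0)})
    with pytest.raises(FittingError, match="2 distinct"):
        fit_proportional_odds(X2, np.ones(50, dtype=int), ["x"])
    with pytest.raises(FittingError, match="included"):
        fit_proportional_odds(X2, np.tile([1, 2], 25), [])


# ------------------------------------------------------------------- Brant

def simulate_null_po(seed, n=400, k=2):
    model = OrdinalStageModel(slopes={"D2": 0.7, "UW3": -0.4},
                              thresholds=(-1.0, 0.3, 1.5))
    return simulate_features_from_model(
        model, n, {"D2": (0.0, 1.0), "UW3": (0.0, 1.0)}, seed=seed)


def test_brant_requires_three_levels():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"x": rng.normal(size=100)})
    with pytest.raises(FittingError, match="J"):
        brant_test(X, np.tile([1, 2], 50), ["x"])


def test_brant_does_not_reject_proportional_data():
    X, stages = simulate_null_po(seed=101, n=800)
    report = brant_test(X, stages, ["D2", "UW3"])
    assert report.loc["omnibus", "df"] == 4  # (J-2)*k = 2*2
    assert report.loc["D2", "df"] == 2
    assert report.loc["omnibus", "p_value"] > 0.01


def test_brant_detects_non_parallel_slopes():
    """Outcome generated with cutpoint-dependent slopes: power should be
    essentially 1 at n=1000."""
    rejections = 0
    n_rep = 20
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        n = 1000
        x = rng.normal(size=n)
        # cumulative splits driven by very different slopes
        g1 = expit(-0.8 - 2.0 * x)   # P(y <= 1)
        g2 = np.maximum(g1, expit(0.8 - 0.2 * x))  # P(y <= 2), kept monotone
        u = rng.random(n)
        y = np.where(u < g1, 1, np.where(u < g2, 2, 3))
        report = brant_test(pd.DataFrame({"D2": x}), y, ["D2"])
        rejections += int(report.loc["omnibus", "p_value"] < 0.05)
    assert rejections >= n_rep * 0.9


# --------------------------------------------------------------------- VIF

def test_vif_orthogonal_features_are_one():
    rng = np.random.default_rng(8)
    # QR against a leading constant column: centered, mutually orthogonal
    q, _ = np.linalg.qr(np.column_stack([np.ones(200), rng.normal(size=(200, 3))]))
    df = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
    report = vif(df)
    # exactly orthogonal, centered columns: R^2 = 0 for each regression
    np.testing.assert_allclose(report["vif"], 1.0, atol=1e-6)
    np.testing.assert_allclose(report["tolerance"], 1.0, atol=1e-6)
    assert not report["flagged"].any()


def test_vif_matches_closed_form_for_two_correlated_features():
    rng = np.random.default_rng(9)
    n = 500
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    for r in (0.3, 0.8, 0.95):
        y = r * (x - x.mean()) / x.std(ddof=0) + np.sqrt(1 - r**2) * e
        df = pd.DataFrame({"x": x, "y": y})
        r_emp = np.corrcoef(x, y)[0, 1]
        report = vif(df)
        expected = 1.0 / (1.0 - r_emp**2)
        assert report.loc["x", "vif"] == pytest.approx(expected, rel=1e-9)
        assert report.loc["y", "vif"] == pytest.approx(expected, rel=1e-9)
        assert report.loc["x", "tolerance"] == pytest.approx(1 / expected, rel=1e-9)


def test_vif_duplicated_feature_is_flagged_infinite():
    rng = np.random.default_rng(10)
    x = rng.normal(size=100)
    df = pd.DataFrame({"x": x, "copy": x, "z": rng.normal(size=100)})
    report = vif(df)
    assert np.isinf(report.loc["x", "vif"])
    assert report.loc["x", "flagged"]
    assert report.loc["x", "tolerance"] == 0.0


# ---------------------------------------------------------------- pipeline

def test_develop_model_retains_single_informative_feature():
    model = OrdinalStageModel(slopes={"D2": 1.5}, thresholds=(-1.0, 0.2, 1.4))
    X, stages = simulate_features_from_model(
        model, 1500, {"D2": (0.0, 1.0)}, seed=33, noise_features=3)
    report = develop_model(X, stages=stages)
    assert "D2" in report.retained
    assert set(report.retained) <= {"D2", "noise1", "noise2", "noise3"}
    assert report.fit.slopes["D2"] > 0
    assert report.diagnostics.vif is not None


def test_develop_model_reads_true_stage_column():
    X, stages = simulate_features_from_model(
        TRUE_MODEL, 800, TRUE_DISTS, seed=37)
    X = X.assign(true_stage=stages, subject_id=[f"s{i}" for i in range(len(X))])
    report = develop_model(X)
    assert set(TRUE_MODEL.slopes) <= set(report.retained)


def test_develop_model_errors_when_screening_empty():
    rng = np.random.default_rng(41)
    X = pd.DataFrame({"noise1": rng.normal(size=200), "noise2": rng.normal(size=200)})
    stages = np.tile([1, 2, 3, 4], 50)
    with pytest.raises(FittingError, match="no candidate"):
        develop_model(X, stages=stages, config=DevelopConfig(alpha_screen=1e-12))
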