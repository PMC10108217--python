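"""Composite Immune Risk Score: published formula semantics, patient-period
scoring, and stepwise refitting."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cirs import (Period, classify_risk, fit_score_model, published_score,
                  score_patient_period)
from cirs.cohort import Cohort, FEATURES
from cirs.errors import FitError
from cirs.score import PUBLISHED_COEFFICIENTS, stepwise_logistic

EIGHT = list(PUBLISHED_COEFFICIENTS)


def _zeros():
    return {f: 0.0 for f in EIGHT}


def test_all_zero_inputs_score_zero():
    assert published_score(_zeros()) == 0.0


@pytest.mark.parametrize("feature", EIGHT)
def test_unit_vector_returns_printed_coefficient(feature):
    v = _zeros()
    v[feature] = 1.0
    assert published_score(v) == PUBLISHED_COEFFICIENTS[feature]


def test_hand_computed_weighted_sum():
    v = {"wbc": 4.0, "neut": 2.0, "lymph_frac_nuc": 0.3, "lymph": 1.2,
         "nk_frac": 0.15, "t_frac": 0.7, "cd4_frac": 0.25, "b_frac": 0.05}
    # independent spreadsheet-style oracle
    expected = (4.0 * 0.7304 + 2.0 * (-0.4745) + 0.3 * (-16.7825)
                + 1.2 * (-1.7612) + 0.15 * (-7.9450) + 0.7 * 10.2955
                + 0.25 * (-7.9703) + 0.05 * (-15.7887))
    assert published_score(v) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0, 1), st.floats(0, 1))
def test_published_score_is_linear(seed, a, b):
    """score(a*u + b*v) == a*score(u) + b*score(v).

    Fraction entries are drawn in [0, 0.5] and mixing weights in [0, 1] so
    every evaluated vector stays a valid proportion input.
    """
    rng = np.random.default_rng(seed)

    def draw():
        vals = {}
        for f in EIGHT:
            vals[f] = float(rng.uniform(0, 0.5)) if "frac" in f \
                else float(rng.uniform(0, 10))
        return vals

    u, v = draw(), draw()
    combo = {f: a * u[f] + b * v[f] for f in EIGHT}
    assert published_score(combo) == pytest.approx(
        a * published_score(u) + b * published_score(v), abs=1e-12)


def test_classification_threshold_is_strict():
    assert classify_risk(2.50) == "low"
    assert classify_risk(2.51) == "high"
    assert classify_risk(-5.0) == "low"
    assert classify_risk(np.array([2.49, 2.50, 2.5000001])).tolist() == \
        ["low", "low", "high"]


@pytest.mark.parametrize("feature,direction", [
    ("wbc", +1), ("t_frac", +1), ("neut", -1), ("lymph", -1),
    ("lymph_frac_nuc", -1), ("nk_frac", -1), ("cd4_frac", -1), ("b_frac", -1),
])
def test_score_monotone_in_each_feature(feature, direction):
    base = {"wbc": 5.0, "neut": 3.0, "lymph_frac_nuc": 0.3, "lymph": 1.5,
            "nk_frac": 0.2, "t_frac": 0.6, "cd4_frac": 0.25, "b_frac": 0.1}
    bumped = dict(base)
    bumped[feature] += 0.1 if feature.endswith("frac") or feature == "lymph_frac_nuc" \
        else 1.0
    diff = published_score(bumped) - published_score(base)
    assert np.sign(diff) == direction


def test_missing_input_names_feature():
    v = _zeros()
    del v["t_frac"]
    with pytest.raises(FitError, match="t_frac"):
        published_score(v)


def test_percentage_scale_input_rejected():
    v = _zeros()
    v["nk_frac"] = 35.0   # a percentage, not a proportion
    with pytest.raises(FitError, match="proportion"):
        published_score(v)


def _score_cohort(day_scores):
    """Cohort with one patient whose in-window profiles produce the given
    per-profile scores via the wbc term alone."""
    rows = []
    for day, s in day_scores:
        row = {f: 0.0 for f in FEATURES}
        row.update({"patient_id": "A", "day": day, "wbc": s / 0.7304})
        rows.append(row)
    profiles = pd.DataFrame(rows)
    outcomes = pd.DataFrame({"patient_id": ["A"], "os_time": [500.0],
                             "death": [False], "cause": ["none"],
                             "cohort_split": ["training"]})
    return Cohort(profiles, outcomes)


def test_patient_period_scoring_mean_then_threshold():
    period = Period("d91_180", 91, 180)
    res = score_patient_period(_score_cohort([(100, 2.0), (170, 3.2)]), period)
    assert res["score"].iloc[0] == pytest.approx(2.6, abs=1e-9)
    assert res["label"].iloc[0] == "high"

    single = score_patient_period(_score_cohort([(100, 1.7)]), period)
    assert single["score"].iloc[0] == pytest.approx(1.7, abs=1e-9)
    assert single["label"].iloc[0] == "low"

    absent = score_patient_period(_score_cohort([(300, 9.9)]), period)
    assert len(absent) == 0   # no in-window profile -> excluded


def test_stepwise_recovers_planted_logistic_model():
    rng = np.random.default_rng(42)
    n = 2000
    X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
    truth = {"f1": 1.5, "f4": -2.0, "f7": 1.0}
    lin = sum(c * X[f] for f, c in truth.items()) + 0.3
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-lin))
    model = fit_score_model(X, y, candidates=list(X.columns))
    assert set(truth) <= set(model.coefficients)
    for f, c in truth.items():
        assert model.coefficients[f] == pytest.approx(c, rel=0.25)


def test_stepwise_null_selects_few_features():
    rng = np.random.default_rng(0)
    sizes = []
    for _ in range(50):
        X = pd.DataFrame(rng.normal(size=(300, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = rng.random(300) < 0.4
        sel, _, _ = stepwise_logistic(X, y.astype(float), list(X.columns))
        sizes.append(len(sel))
    assert np.mean(sizes) <= 2.0


def test_stepwise_matches_exhaustive_best_subset():
    """Greedy bidirectional AIC selection attains the exhaustive best-subset
    optimum on small, well-conditioned instances (brute-force oracle)."""
    import statsmodels.api as sm
    from itertools import combinations

    def exhaustive_aic(X, y):
        best = (np.inf, ())
        for k in range(X.shape[1] + 1):
            for sub in combinations(X.columns, k):
                Xs = np.column_stack([np.ones(len(y))]
                                     + [X[c].to_numpy() for c in sub])
                fit = sm.Logit(y, Xs).fit(disp=0)
                aic = 2 * (k + 1) - 2 * fit.llf
                if aic < best[0] - 1e-9:
                    best = (aic, sub)
        return best

    for seed in (5, 6, 7):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(400, 6)),
                         columns=[f"f{i}" for i in range(6)])
        lin = 1.2 * X["f0"] - 0.9 * X["f2"]
        y = (rng.random(400) < 1.0 / (1.0 + np.exp(-lin))).astype(float)
        sel, _, aic = stepwise_logistic(X, y, list(X.columns))
        best_aic, best_sub = exhaustive_aic(X, y)
        assert set(sel) == set(best_sub)
        assert aic == pytest.approx(best_aic, abs=1e-6)


def test_separation_triggers_ridge_fallback_warning():
    rng = np.random.default_rng(3)
    n = 100
    X = pd.DataFrame({"sep": np.concatenate([np.full(50, -2.0), np.full(50, 2.0)]),
                      "noise": rng.normal(size=n)})
    y = np.concatenate([np.zeros(50), np.ones(50)])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sel, params, _ = stepwise_logistic(X, y, ["sep", "noise"])
    assert "sep" in sel
    assert any("separation" in str(w.message) for w in caught)
    assert np.all(np.isfinite(params))


def test_fit_score_model_degenerate_inputs():
    X = pd.DataFrame({"f": np.arange(30, dtype=float)})
    with pytest.raises(FitError, match="single-class"):
        fit_score_model(X, np.zeros(30, bool), candidates=["f"])
    with pytest.raises(FitError, match="at least 20"):
        fit_score_model(X.head(10), np.arange(10) % 2 == 0, candidates=["f"])
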