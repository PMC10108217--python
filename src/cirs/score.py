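"""The Composite Immune Risk Score: published formula and stepwise refits.

The published score is an intercept-free weighted sum of eight blood
features measured during days 91-180 post-transplant; a score above 2.50
classifies the patient as high-risk. Counts are in 10^9/L and the four
cytometry inputs are proportions in [0, 1] (0.35, never 35); the
coefficient magnitudes already absorb the percentage convention.

``fit_score_model`` re-derives a score of the same shape from a
signature labeling: bidirectional stepwise logistic selection by AIC
over the 20 profile features, reported as an intercept-free linear
predictor with a Youden-optimal threshold for interface parity with the
published model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, FEATURES, Period, window_profiles
from .errors import FitError

#: the eight published coefficients (counts in 10^9/L, fractions as proportions)
PUBLISHED_COEFFICIENTS = {
    "wbc": 0.7304,
    "neut": -0.4745,
    "lymph_frac_nuc": -16.7825,
    "lymph": -1.7612,
    "nk_frac": -7.9450,
    "t_frac": 10.2955,
    "cd4_frac": -7.9703,
    "b_frac": -15.7887,
}
PUBLISHED_THRESHOLD = 2.50
FRACTION_INPUTS = ("lymph_frac_nuc", "nk_frac", "t_frac", "cd4_frac", "b_frac")


@dataclass
class RiskScoreModel:
    """A linear risk score: ordered (feature, coefficient) terms + threshold."""

    coefficients: dict
    threshold: float
    intercept: float | None = None       # None for the published model
    provenance: str = "fitted"           # "published" or "fitted"

    def score(self, features) -> np.ndarray | float:
        """Intercept-free weighted sum over the model's features.

        ``features`` is a mapping or DataFrame providing every model
        feature; fraction inputs must be proportions in [0, 1].
        """
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.coefficients if f not in features.columns]
            if missing:
                raise FitError(f"missing score input(s): {missing}")
            self._check_fractions(features)
            vals = features[list(self.coefficients)].to_numpy(float)
            if not np.isfinite(vals).all():
                raise FitError("non-finite score input")
            return vals @ np.array(list(self.coefficients.values()))
        missing = [f for f in self.coefficients if f not in features]
        if missing:
            raise FitError(f"missing score input(s): {missing}")
        self._check_fractions(features)
        total = 0.0
        for name, coef in self.coefficients.items():
            v = float(features[name])
            if not np.isfinite(v):
                raise FitError(f"non-finite score input: {name}")
            total += coef * v
        return total

    def _check_fractions(self, features) -> None:
        for name in self.coefficients:
            if name not in FRACTION_INPUTS:
                continue
            v = np.asarray(features[name], dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise FitError(
                    f"{name} must be a proportion in [0, 1] (got values outside); "
                    "percentages are not rescaled silently")

    def classify(self, score) -> np.ndarray | str:
        """'high' iff score strictly exceeds the threshold, else 'low'."""
        arr = np.asarray(score, dtype=float)
        labels = np.where(arr > self.threshold, "high", "low")
        return labels if arr.ndim else str(labels)


PUBLISHED_MODEL = RiskScoreModel(dict(PUBLISHED_COEFFICIENTS), PUBLISHED_THRESHOLD,
                                 intercept=None, provenance="published")


def published_score(features) -> float:
    """Evaluate the published eight-term score on one feature mapping."""
    return PUBLISHED_MODEL.score(features)


def classify_risk(score, threshold: float = PUBLISHED_THRESHOLD):
    """'high' iff score > threshold (strict); the boundary itself is 'low'."""
    arr = np.asarray(score, dtype=float)
    labels = np.where(arr > threshold, "high", "low")
    return labels if arr.ndim else str(labels)


def score_patient_period(cohort: Cohort, period: Period,
                         model: RiskScoreModel = PUBLISHED_MODEL) -> pd.DataFrame:
    """Per-patient score and high/low label for one time period.

    Each in-window profile is scored and the per-patient mean score is
    thresholded. Patients without in-window profiles are excluded.
    Columns: patient_id, score, label, n_profiles.
    """
    in_window, _ = window_profiles(cohort, period)
    if len(in_window) == 0:
        return pd.DataFrame(columns=["patient_id", "score", "label", "n_profiles"])
    scores = model.score(in_window)
    per_pat = pd.DataFrame({"patient_id": in_window["patient_id"].to_numpy(),
                            "score": scores}) \
        .groupby("patient_id", sort=True)["score"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "patient_id": per_pat["patient_id"],
        "score": per_pat["mean"],
        "label": np.where(per_pat["mean"] > model.threshold, "high", "low"),
        "n_profiles": per_pat["size"].astype(int),
    })


def _fit_logit(X: np.ndarray, y: np.ndarray, ridge_on_separation: bool = True):
    """Logistic fit returning (params, llf, separation_flag).

    X includes the constant column. Quasi-separation is detected by runaway
    coefficients; the fallback is a ridge-stabilized (L2, tiny alpha) fit.
    """
    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            params, llf = fit.params, fit.llf
        except Exception:
            params, llf = None, -np.inf
    if params is None or np.max(np.abs(params)) > 50.0:
        separated = True
        if ridge_on_separation:
            warnings.warn("separation detected; using ridge-stabilized logistic fit")
            fit = model.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
            params = np.asarray(fit.params)
            llf = model.loglike(params)
    return np.asarray(params), float(llf), separated


def _aic(llf: float, k: int) -> float:
    return 2.0 * k - 2.0 * llf


def stepwise_logistic(feature_table: pd.DataFrame, labels: np.ndarray,
                      candidates: list[str]) -> tuple[list[str], np.ndarray, float]:
    """Bidirectional stepwise AIC selection starting from the empty model.

    Deterministic: AIC ties are broken by candidate order. Returns the
    selected feature list, the coefficient vector (constant first) and the
    final AIC.
    """
    y = np.asarray(labels, dtype=float)
    n = len(y)

    def fit_set(feats):
        X = np.column_stack([np.ones(n)] + [feature_table[f].to_numpy(float)
                                            for f in feats])
        params, llf, _ = _fit_logit(X, y)
        return params, _aic(llf, len(feats) + 1)

    selected: list[str] = []
    _, best_aic = fit_set(selected)
    improved = True
    while improved:
        improved = False
        # forward step
        best_add, best_add_aic = None, best_aic
        for f in candidates:
            if f in selected:
                continue
            _, aic = fit_set(selected + [f])
            if aic < best_add_aic - 1e-9:
                best_add, best_add_aic = f, aic
        if best_add is not None:
            selected.append(best_add)
            best_aic = best_add_aic
            improved = True
        # backward step
        best_drop, best_drop_aic = None, best_aic
        for f in list(selected):
            trial = [g for g in selected if g != f]
            _, aic = fit_set(trial)
            if aic < best_drop_aic - 1e-9:
                best_drop, best_drop_aic = f, aic
        if best_drop is not None:
            selected.remove(best_drop)
            best_aic = best_drop_aic
            improved = True
    params, final_aic = fit_set(selected)
    return selected, params, final_aic


def fit_score_model(feature_table: pd.DataFrame, labels,
                    candidates: list[str] | None = None) -> RiskScoreModel:
    """Distill a binary signature into a linear score by stepwise logistic fit.

    ``feature_table`` has one row per labeled patient. The returned model
    keeps the fitted intercept internally but scores with the bare weighted
    sum; its threshold is chosen on that intercept-free linear predictor at
    the point maximizing Youden's J against the given labels.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(feature_table) < 20:
        raise FitError("need at least 20 labeled patients to fit a score model")
    if labels.all() or not labels.any():
        raise FitError("signature labels are single-class; cannot fit")
    candidates = list(candidates) if candidates is not None else list(FEATURES)

    selected, params, _ = stepwise_logistic(feature_table, labels, candidates)
    if not selected:
        raise FitError("stepwise selection retained no features")
    coef = dict(zip(selected, params[1:]))
    intercept = float(params[0])

    lin = feature_table[selected].to_numpy(float) @ params[1:]
    order = np.argsort(lin, kind="stable")
    thresholds = (lin[order][:-1] + lin[order][1:]) / 2.0
    best_j, best_thr = -np.inf, float(np.median(lin))
    pos = labels.sum()
    neg = (~labels).sum()
    for thr in thresholds:
        pred = lin > thr
        sens = (pred & labels).sum() / pos
        spec = (~pred & ~labels).sum() / neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return RiskScoreModel(coef, best_thr, intercept=intercept, provenance="fitted")
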