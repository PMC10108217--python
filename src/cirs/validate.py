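"""Survival validation battery: Kaplan-Meier stratification, landmark Cox
models, competing-risks cumulative incidence with Fine-Gray subdistribution
hazards, and the logistic model for predictors of a high score.

KM/log-rank and multivariate Cox go through lifelines. The competing-risks
pieces are implemented here: Aalen-Johansen cumulative incidence (which by
construction satisfies sum-of-incidences + overall survival = 1 at every
time), and the Fine-Gray subdistribution hazard via the IPCW-weighted Cox
formulation -- subjects failing from a competing cause remain in the risk
set with weights from the Kaplan-Meier estimate of the censoring
distribution, and the weighted fit is delegated to lifelines'
CoxTimeVaryingFitter on a counting-process expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import FitError


@dataclass
class SurvivalResult:
    """One model term reported in the field's HR/OR style."""

    term: str
    estimate: float          # HR or OR
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    events: int
    model_type: str          # "cox" | "fine_gray" | "logistic"

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(f"{self.term}: CI [{self.ci_low}, {self.ci_high}] "
                             f"does not bracket the estimate {self.estimate}")


def results_table(results: list[SurvivalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def km_by_group(times, status, labels):
    """Kaplan-Meier curves per group plus a two-sided log-rank p-value.

    Returns (curves, p) where curves maps group label -> DataFrame with
    columns (time, survival, ci_low, ci_high) using Greenwood variance.
    """
    times = np.asarray(times, float)
    status = np.asarray(status, bool)
    labels = np.asarray(labels)
    curves = {}
    for g in pd.unique(labels):
        m = labels == g
        kmf = KaplanMeierFitter().fit(times[m], status[m], label=str(g))
        ci = kmf.confidence_interval_survival_function_
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        })
    if len(curves) < 2:
        return curves, 1.0
    lr = multivariate_logrank_test(times, labels, status)
    return curves, float(lr.p_value)


def cox_fit(times, status, covariate_table: pd.DataFrame,
            landmark_day: float = 0.0) -> list[SurvivalResult]:
    """Multivariate Cox PH fit from a landmark (Efron ties, Wald 95% CIs).

    Patients whose event/censoring time is <= landmark are excluded and
    time is measured from the landmark. Constant covariates raise.
    """
    times = np.asarray(times, float)
    status = np.asarray(status, bool)
    keep = times > landmark_day
    if keep.sum() == 0 or status[keep].sum() == 0:
        raise FitError("no events after the landmark")
    cov = covariate_table.reset_index(drop=True).loc[np.flatnonzero(keep)]
    for col in cov.columns:
        if cov[col].nunique() <= 1:
            raise FitError(f"covariate {col!r} is constant after the landmark")
    df = cov.copy()
    df["_t"] = times[keep] - landmark_day
    df["_e"] = status[keep].astype(int)
    cph = CoxPHFitter()
    # full Newton steps first (tight convergence); damped retry on failure
    last_error = None
    for fit_options in ({"precision": 1e-12, "step_size": 1.0}, None):
        try:
            cph.fit(df, duration_col="_t", event_col="_e",
                    fit_options=fit_options)
            last_error = None
            break
        except Exception as e:
            last_error = e
    if last_error is not None:
        raise FitError(f"Cox fit failed to converge: {last_error}") from last_error
    out = []
    summ = cph.summary
    for term in summ.index:
        out.append(SurvivalResult(
            term=str(term),
            estimate=float(summ.loc[term, "exp(coef)"]),
            ci_low=float(summ.loc[term, "exp(coef) lower 95%"]),
            ci_high=float(summ.loc[term, "exp(coef) upper 95%"]),
            p_value=float(summ.loc[term, "p"]),
            n=int(keep.sum()), events=int(status[keep].sum()),
            model_type="cox"))
    return out


def cumulative_incidence(times, cause) -> pd.DataFrame:
    """Aalen-Johansen cumulative incidence functions for all causes.

    ``cause`` holds a cause label per subject, with "none" meaning
    censored. Returns a DataFrame indexed by event time with one column
    per cause plus ``survival`` (all-cause KM); at every time the cause
    columns and survival sum exactly to 1.
    """
    times = np.asarray(times, float)
    cause = np.asarray(cause, dtype=object)
    event = cause != "none"
    order = np.argsort(times, kind="stable")
    times, cause, event = times[order], cause[order], event[order]

    causes = [c for c in pd.unique(cause) if c != "none"]
    event_times = np.unique(times[event])
    n = len(times)
    surv = 1.0
    cif = {c: 0.0 for c in causes}
    rows = []
    for t in event_times:
        n_at_risk = np.sum(times >= t)
        d_total = np.sum((times == t) & event)
        surv_minus = surv
        for c in causes:
            d_c = np.sum((times == t) & (cause == c))
            cif[c] += surv_minus * d_c / n_at_risk
        surv = surv_minus * (1.0 - d_total / n_at_risk)
        rows.append({"time": t, **{c: cif[c] for c in causes}, "survival": surv})
    return pd.DataFrame(rows).set_index("time")


def _censoring_km(times, any_event):
    """Right-continuous KM of the censoring distribution G(t)."""
    kmf = KaplanMeierFitter().fit(times, ~np.asarray(any_event, bool))
    grid = kmf.survival_function_.index.to_numpy()
    vals = kmf.survival_function_.iloc[:, 0].to_numpy()

    def G(t):
        t = np.asarray(t, float)
        idx = np.searchsorted(grid, t, side="right") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])
    return G


def _finegray_expand(times, cause, target: str, covariates: pd.DataFrame):
    """Counting-process expansion with IPCW weights for one target cause.

    Subjects censored or failing from the target cause contribute a single
    interval (0, T]. Subjects failing from a competing cause remain in the
    risk set beyond their failure time with weight G(t-)/G(T_i-) at each
    later target-cause event time t.
    """
    times = np.asarray(times, float)
    cause = np.asarray(cause, dtype=object)
    event = cause != "none"
    G = _censoring_km(times, event)
    tau = np.unique(times[cause == target])
    if tau.size == 0:
        raise FitError(f"no events of cause {target!r}")
    eps = 1e-9  # left limits of the censoring KM

    rows = []
    for i in range(len(times)):
        Ti = times[i]
        covs = covariates.iloc[i]
        if cause[i] == target:
            rows.append((0.0, Ti, 1, 1.0, i))
        elif not event[i]:
            rows.append((0.0, Ti, 0, 1.0, i))
        else:  # competing cause: stays at risk with decaying weight
            rows.append((0.0, Ti, 0, 1.0, i))
            later = tau[tau > Ti]
            gTi = max(float(G(Ti - eps)), 1e-12)
            prev = Ti
            for t in later:
                w = float(G(t - eps)) / gTi
                if w <= 0:
                    break
                rows.append((prev, t, 0, w, i))
                prev = t
    df = pd.DataFrame(rows, columns=["start", "stop", "event", "weight", "_i"])
    df = df.join(covariates.reset_index(drop=True), on="_i").drop(columns="_i")
    return df


def finegray_fit(times, cause, target: str,
                 covariates: pd.DataFrame) -> list[SurvivalResult]:
    """Fine-Gray subdistribution-hazard regression for one cause."""
    covariates = covariates.reset_index(drop=True)
    expanded = _finegray_expand(times, cause, target, covariates)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(expanded, start_col="start", stop_col="stop",
                event_col="event", weights_col="weight")
    summ = ctv.summary
    n = len(times)
    events = int(np.sum(np.asarray(cause, dtype=object) == target))
    return [SurvivalResult(
        term=str(t), estimate=float(summ.loc[t, "exp(coef)"]),
        ci_low=float(summ.loc[t, "exp(coef) lower 95%"]),
        ci_high=float(summ.loc[t, "exp(coef) upper 95%"]),
        p_value=float(summ.loc[t, "p"]), n=n, events=events,
        model_type="fine_gray") for t in summ.index]


def _exposure_vector(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels.astype(float)
    uniq = set(pd.unique(labels))
    if uniq <= {"high", "low"}:
        return (labels == "high").astype(float)
    if len(uniq) != 2:
        raise FitError(f"exposure labels must be binary; got {sorted(map(str, uniq))}")
    ref = sorted(uniq)[0]
    warnings.warn(f"exposure reference level taken as {ref!r} (sorted order)")
    return (labels != ref).astype(float)


def competing_risks(times, status, cause, labels, causes=None):
    """Per-cause cumulative incidence and subdistribution HR of an exposure.

    ``labels`` is a binary exposure (boolean, or "high"/"low"). Returns
    (cif_by_group, results) where cif_by_group maps group -> Aalen-Johansen
    table and results holds one Fine-Gray SurvivalResult per cause. When
    ``causes`` is given, causes absent from the data are skipped with a
    warning instead of silently disappearing.
    """
    times = np.asarray(times, float)
    cause = np.asarray(cause, dtype=object)
    status = np.asarray(status, bool)
    cause = np.where(status, cause, "none")
    labels = np.asarray(labels)

    groups = pd.unique(labels)
    cif_by_group = {g: cumulative_incidence(times[labels == g], cause[labels == g])
                    for g in groups}
    exposure = pd.DataFrame({"exposure": _exposure_vector(labels)})
    results = []
    wanted = list(causes) if causes is not None \
        else [c for c in pd.unique(cause) if c != "none"]
    for c in wanted:
        try:
            res = finegray_fit(times, cause, c, exposure)
        except FitError as e:
            warnings.warn(f"cause {c!r} skipped: {e}")
            continue
        for r in res:
            r.term = f"exposure|{c}"
        results.extend(res)
    return cif_by_group, results


def high_score_risk_factors(outcomes: pd.DataFrame, high_label: pd.Series,
                            covariates: list[str] | None = None
                            ) -> list[SurvivalResult]:
    """Multivariable logistic regression for predictors of a high score.

    Default covariates: severe aGVHD in days 1-90, infection episodes in
    days 1-90, and patient age. ``high_label`` is a boolean Series indexed
    by patient_id; patients missing a label are excluded.
    """
    import statsmodels.api as sm

    covariates = covariates or ["severe_agvhd_100d", "infections_d1_90", "age"]
    df = outcomes.set_index("patient_id")
    common = df.index.intersection(high_label.index)
    y = high_label.reindex(common).astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise FitError("high-score label is single-class; cannot fit")
    X = df.loc[common, covariates].astype(float)
    X = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    params = fit.params
    ci = fit.conf_int()
    out = []
    for term in covariates:
        out.append(SurvivalResult(
            term=term, estimate=float(np.exp(params[term])),
            ci_low=float(np.exp(ci.loc[term, 0])),
            ci_high=float(np.exp(ci.loc[term, 1])),
            p_value=float(fit.pvalues[term]),
            n=len(y), events=int(y.sum()), model_type="logistic"))
    return out
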