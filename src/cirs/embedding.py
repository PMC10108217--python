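"""Phase-space embedding of immune profiles and trajectory summaries.

All scaled 20-feature profiles are projected onto a 2-D plane with
t-SNE; the plane is treated as a *phase space* of immune status in which
each blood draw is one point. Axis meaning is quantified by regressing
each raw feature on the two coordinates (``feature = c + alpha*x +
beta*y + eps``), and population kinetics are summarized by a bootstrap
average trajectory over sliding day windows whose width delta_t grows
with time post-transplant: 30 days for 0 < t <= 90, 90 days for
90 < t <= 360, and 180 days beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .errors import FitError


@dataclass
class EmbedParams:
    """t-SNE settings; fixed defaults for reproducibility."""

    perplexity: float = 30.0
    n_iter: int = 1000
    seed: int = 0


def embed_profiles(scaled: pd.DataFrame, meta: pd.DataFrame,
                   params: EmbedParams | None = None) -> pd.DataFrame:
    """Embed scaled profiles into 2-D; returns (patient_id, day, x, y).

    ``scaled`` is the [0, 1]-rescaled feature matrix, ``meta`` the aligned
    (patient_id, day) columns. PCA initialization, single-threaded, fixed
    seed: identical inputs give identical coordinates. Coordinates are
    centered per axis so the downstream grid is reproducible.
    """
    if params is None:
        params = EmbedParams()
    X = np.asarray(scaled, dtype=float)
    n = X.shape[0]
    if n < 3 * params.perplexity + 1:
        raise FitError(
            f"too few rows ({n}) for perplexity {params.perplexity}; "
            f"need > {int(3 * params.perplexity)} or a lower perplexity")
    tsne = TSNE(n_components=2, perplexity=params.perplexity,
                max_iter=params.n_iter, init="pca",
                random_state=params.seed, n_jobs=1)
    xy = tsne.fit_transform(X)
    xy = xy - xy.mean(axis=0, keepdims=True)
    out = pd.DataFrame({
        "patient_id": np.asarray(meta["patient_id"]),
        "day": np.asarray(meta["day"]),
        "x": xy[:, 0], "y": xy[:, 1],
    })
    return out


@dataclass
class GradientFit:
    """Least-squares plane fit of one feature over the phase space."""

    feature: str
    c: float        # intercept
    alpha: float    # coefficient of x
    beta: float     # coefficient of y
    residual_var: float


def fit_axis_gradients(embedded: pd.DataFrame,
                       feature_values: pd.DataFrame) -> list[GradientFit]:
    """OLS of each feature on (1, x, y); one GradientFit per column.

    ``feature_values`` rows must align with ``embedded`` rows.
    """
    x = embedded["x"].to_numpy(float)
    y = embedded["y"].to_numpy(float)
    if len(x) < 3:
        raise FitError("need at least 3 points to fit axis gradients")
    X = np.column_stack([np.ones_like(x), x, y])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        raise FitError("phase-space coordinates are collinear; gradients undefined")
    fits = []
    for col in feature_values.columns:
        phi = feature_values[col].to_numpy(float)
        coef, _, _, _ = np.linalg.lstsq(X, phi, rcond=None)
        resid = phi - X @ coef
        dof = max(len(phi) - 3, 1)
        fits.append(GradientFit(col, float(coef[0]), float(coef[1]),
                                float(coef[2]), float(resid @ resid / dof)))
    return fits


def delta_t(t: float) -> float:
    """Window width rule: 30 d for 0<t<=90, 90 d for 90<t<=360, 180 d after."""
    if t <= 0:
        raise ValueError("t must be positive")
    if t <= 90:
        return 30.0
    if t <= 360:
        return 90.0
    return 180.0


@dataclass
class TrajectoryPoint:
    t: float
    delta_t: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_profiles: int


def average_trajectory(embedded: pd.DataFrame, times,
                       n_boot: int = 100, seed: int = 0,
                       resample: bool = True) -> list[TrajectoryPoint]:
    """Bootstrap average phase-space location at each time.

    For each t the window is the closed interval [t - dt/2, t + dt/2] with
    dt from the delta_t rule. Each of ``n_boot`` bootstrap samples redraws
    the in-window profiles with replacement; the trajectory point is the
    mean of the bootstrap sample means (sd likewise across samples). Empty
    windows are skipped with a warning. ``resample=False`` degenerates to
    the plain window mean (used for exactness checks).
    """
    rng = np.random.default_rng(seed)
    day = embedded["day"].to_numpy(float)
    xy = embedded[["x", "y"]].to_numpy(float)
    points = []
    for t in times:
        dt = delta_t(t)
        mask = (day >= t - dt / 2.0) & (day <= t + dt / 2.0)
        sub = xy[mask]
        if sub.shape[0] == 0:
            warnings.warn(f"trajectory window around t={t} is empty; skipped")
            continue
        # canonical row order -> bootstrap results invariant to input ordering
        sub = sub[np.lexsort((sub[:, 1], sub[:, 0]))]
        if resample:
            idx = rng.integers(0, sub.shape[0], size=(n_boot, sub.shape[0]))
            boot_means = sub[idx].mean(axis=1)           # (n_boot, 2)
        else:
            boot_means = sub.mean(axis=0, keepdims=True)
        mean = boot_means.mean(axis=0)
        sd = boot_means.std(axis=0, ddof=0)
        points.append(TrajectoryPoint(float(t), dt, float(mean[0]), float(mean[1]),
                                      float(sd[0]), float(sd[1]), int(sub.shape[0])))
    return points


def variance_over_time(embedded: pd.DataFrame, times) -> pd.DataFrame:
    """Between-patient variance of mean in-window location, per time.

    Convention: each patient contributes the mean of their in-window
    coordinates; the reported variance is the *sample* variance (divide
    by n - 1) per axis, summed over the two axes; a single-patient
    window reports 0.
    """
    day = embedded["day"].to_numpy(float)
    rows = []
    for t in times:
        dt = delta_t(t)
        mask = (day >= t - dt / 2.0) & (day <= t + dt / 2.0)
        sub = embedded[mask]
        if len(sub) == 0:
            warnings.warn(f"variance window around t={t} is empty; skipped")
            continue
        per_patient = sub.groupby("patient_id")[["x", "y"]].mean()
        if len(per_patient) < 2:
            var = 0.0
        else:
            var = float(per_patient.var(axis=0, ddof=1).sum())
        rows.append({"t": float(t), "delta_t": dt,
                     "n_patients": len(per_patient), "variance": var})
    return pd.DataFrame(rows)
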