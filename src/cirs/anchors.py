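"""Grid-scan discovery of high-risk phase-space regions ("anchor points").

A regular 121-by-121 grid is overlaid on the bounding box of the
embedded profiles. For a candidate time period, each grid point splits
the patients with in-window profiles into those *near* it (any in-window
profile within the nearness radius) and those not, and a univariate Cox
model of all-cause death from the period-end landmark is fitted on that
binary label. Grid points with p below alpha (default .01, uncorrected;
held-out validation is the safeguard) are *anchor points*; a patient
near any anchor carries the high-risk composite immune signature.

Nearness is measured after rescaling each axis by its grid span, so the
radius is expressed in grid steps (default 2) and the neighborhood is
elliptical in raw units. Survival is clocked from the landmark (the
period's last day); patients dead or censored by the landmark are
excluded, avoiding immortal-time bias.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, Period
from .coxfast import binary_cox
from .errors import FitError, LeakageError

DEFAULT_GRID = 121
DEFAULT_RADIUS_STEPS = 5.0
DEFAULT_ALPHA = 0.01
MIN_GROUP = 5


@dataclass
class Grid:
    """Regular grid spanning the embedding bounding box (inclusive)."""

    x_axis: np.ndarray
    y_axis: np.ndarray

    @property
    def n_per_axis(self) -> int:
        return len(self.x_axis)

    @property
    def points(self) -> np.ndarray:
        """All grid points, row-major: index i * n + j -> (x_axis[i], y_axis[j])."""
        gx, gy = np.meshgrid(self.x_axis, self.y_axis, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def normalize(self, xy: np.ndarray) -> np.ndarray:
        """Map raw coordinates into [0, 1]^2 span units of this grid."""
        lo = np.array([self.x_axis[0], self.y_axis[0]])
        span = np.array([self.x_axis[-1] - self.x_axis[0],
                         self.y_axis[-1] - self.y_axis[0]])
        return (np.asarray(xy, dtype=float) - lo) / span


def build_grid(embedded: pd.DataFrame, n_per_axis: int = DEFAULT_GRID) -> Grid:
    """Equally spaced n x n grid over the bounding box of embedded points."""
    xy = embedded[["x", "y"]].to_numpy(float)
    if len(np.unique(xy, axis=0)) < 2:
        raise FitError("need at least 2 distinct coordinates to build a grid")
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    if np.any(hi - lo <= 0):
        raise FitError("degenerate bounding box: zero extent on an axis")
    return Grid(np.linspace(lo[0], hi[0], n_per_axis),
                np.linspace(lo[1], hi[1], n_per_axis))


def near_labels(grid_point, points_xy, radius: float) -> np.ndarray:
    """Boolean: is each point within Euclidean distance <= radius (inclusive)?"""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    d = np.linalg.norm(np.asarray(points_xy, float) - np.asarray(grid_point, float),
                       axis=1)
    return d <= radius


@dataclass
class AnchorSet:
    """Result of one grid scan: geometry, per-point statistics, anchors."""

    period: Period
    grid: Grid
    radius_steps: float
    alpha: float
    p_values: np.ndarray        # (n_grid,)
    hazard_ratios: np.ndarray   # (n_grid,)
    testable: np.ndarray        # (n_grid,) bool
    n_patients: int
    n_events: int

    @property
    def radius_norm(self) -> float:
        return self.radius_steps / (self.grid.n_per_axis - 1)

    @property
    def anchor_mask(self) -> np.ndarray:
        """Significant *deleterious* grid points (p < alpha and HR > 1).

        The two-sided Cox p-value alone would also flag protective
        regions (near-groups depleted of high-risk patients, HR < 1);
        the signature is a high-risk label, so anchors are restricted to
        the harmful direction.
        """
        return self.testable & (self.p_values < self.alpha) & (self.hazard_ratios > 1.0)

    @property
    def anchor_points(self) -> np.ndarray:
        """Raw-coordinate locations of the anchors, (m, 2)."""
        return self.grid.points[self.anchor_mask]

    def to_json(self, path, surface_path=None) -> None:
        payload = {
            "period": {"label": self.period.label,
                       "start_day": self.period.start_day,
                       "end_day": self.period.end_day},
            "n_per_axis": self.grid.n_per_axis,
            "x_range": [float(self.grid.x_axis[0]), float(self.grid.x_axis[-1])],
            "y_range": [float(self.grid.y_axis[0]), float(self.grid.y_axis[-1])],
            "radius_steps": self.radius_steps,
            "alpha": self.alpha,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "anchors": self.anchor_points.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        if surface_path is not None:
            pd.DataFrame({
                "x": self.grid.points[:, 0], "y": self.grid.points[:, 1],
                "p_value": self.p_values, "hazard_ratio": self.hazard_ratios,
                "testable": self.testable,
            }).to_csv(surface_path, index=False, float_format="%.10g")


def _landmark_survival(cohort: Cohort, period: Period):
    """Post-landmark durations/events; patients at risk past the landmark only."""
    out = cohort.outcomes
    at_risk = out["os_time"].to_numpy(float) > period.landmark
    time = out["os_time"].to_numpy(float)[at_risk] - period.landmark
    event = out["death"].to_numpy(bool)[at_risk]
    ids = out["patient_id"].to_numpy()[at_risk]
    return ids, time, event


def patient_near_matrix(cohort: Cohort, embedded: pd.DataFrame, period: Period,
                        grid: Grid, radius_steps: float = DEFAULT_RADIUS_STEPS,
                        chunk: int = 2048):
    """(patient x grid-point) boolean: any in-window profile within radius.

    Returns (patient_ids, matrix). Distances are computed in grid span
    units; the radius is ``radius_steps / (n_per_axis - 1)``.
    """
    emb_window = embedded[period.contains(embedded["day"].to_numpy())]
    codes, ids = pd.factorize(emb_window["patient_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    prof_xy = grid.normalize(emb_window[["x", "y"]].to_numpy(float))[order]
    starts = np.searchsorted(codes[order], np.arange(len(ids)))
    grid_xy = grid.normalize(grid.points)
    radius = radius_steps / (grid.n_per_axis - 1)

    G = grid_xy.shape[0]
    near = np.zeros((len(ids), G), dtype=bool)
    for start in range(0, G, chunk):
        block = grid_xy[start:start + chunk]
        d2 = ((prof_xy[:, None, :] - block[None, :, :]) ** 2).sum(axis=2)
        hit = d2 <= radius * radius + 1e-15
        # any-profile rule: reduce profile rows to patient rows
        near[:, start:start + block.shape[0]] = \
            np.logical_or.reduceat(hit, starts, axis=0)
    return np.asarray(ids), near


def scan_anchor_points(cohort: Cohort, embedded: pd.DataFrame, period: Period,
                       radius_steps: float = DEFAULT_RADIUS_STEPS,
                       alpha: float = DEFAULT_ALPHA,
                       n_per_axis: int = DEFAULT_GRID,
                       grid: Grid | None = None,
                       min_group: int = MIN_GROUP,
                       expected_split: str | None = None) -> AnchorSet:
    """Cox-test nearness to every grid point against post-landmark death.

    Per grid point, patients with in-window profiles and follow-up past the
    landmark are labeled near/far; a univariate Efron-ties Cox fit yields a
    likelihood-ratio p-value. Points where either group has fewer than
    ``min_group`` patients are untestable (p := 1). ``expected_split``
    guards discovery against outcome leakage from other splits.
    """
    if expected_split is not None:
        seen = set(cohort.outcomes["cohort_split"])
        if seen - {expected_split}:
            raise LeakageError(
                f"discovery received outcomes from splits {sorted(seen)}; "
                f"only {expected_split!r} is allowed")
    if grid is None:
        grid = build_grid(embedded, n_per_axis)

    ids_near, near = patient_near_matrix(cohort, embedded, period, grid, radius_steps)
    ids_surv, time, event = _landmark_survival(cohort, period)

    keep = np.isin(ids_near, ids_surv)
    ids_used = ids_near[keep]
    near = near[keep]
    surv_index = {p: i for i, p in enumerate(ids_surv)}
    sel = np.array([surv_index[p] for p in ids_used], dtype=int)
    time, event = time[sel], event[sel]

    G = near.shape[1]
    n_pat = near.shape[0]
    if n_pat == 0 or event.sum() == 0:
        warnings.warn(f"period {period.label}: no post-landmark events; empty anchor set")
        return AnchorSet(period, grid, radius_steps, alpha,
                         np.ones(G), np.ones(G), np.zeros(G, bool), n_pat, 0)

    n_near = near.sum(axis=0)
    testable = (n_near >= min_group) & (n_pat - n_near >= min_group)
    p = np.ones(G)
    hr = np.ones(G)
    if testable.any():
        res = binary_cox(time, event, near[:, testable])
        p[testable] = res["p_lr"]
        hr[testable] = res["hr"]
    return AnchorSet(period, grid, radius_steps, alpha, p, hr, testable,
                     n_pat, int(event.sum()))


def assign_signature(cohort: Cohort, embedded: pd.DataFrame,
                     anchors: AnchorSet, period: Period | None = None) -> pd.DataFrame:
    """Label each in-window patient as carrying the signature or not.

    A patient carries the signature iff any in-window profile lies within
    the nearness radius of any anchor point. Patients without in-window
    profiles are excluded from the table entirely (neither positive nor
    negative). Columns: patient_id, carries, nearest_anchor_dist (in grid
    span units; inf when there are no anchors).
    """
    period = period or anchors.period
    emb_window = embedded[period.contains(embedded["day"].to_numpy())]
    emb_window = emb_window[emb_window["patient_id"].isin(set(cohort.patient_ids))]
    ids = pd.unique(emb_window["patient_id"])
    apts = anchors.anchor_points
    if len(apts) == 0:
        return pd.DataFrame({"patient_id": ids, "carries": False,
                             "nearest_anchor_dist": np.inf})
    prof_xy = anchors.grid.normalize(emb_window[["x", "y"]].to_numpy(float))
    anch_xy = anchors.grid.normalize(apts)
    d = np.sqrt(((prof_xy[:, None, :] - anch_xy[None, :, :]) ** 2).sum(axis=2))
    prof_min = d.min(axis=1)
    dist = pd.Series(prof_min).groupby(emb_window["patient_id"].to_numpy()).min()
    dist = dist.reindex(ids)
    return pd.DataFrame({
        "patient_id": ids,
        "carries": (dist <= anchors.radius_norm + 1e-15).to_numpy(),
        "nearest_anchor_dist": dist.to_numpy(),
    })


def signature_cox(cohort: Cohort, signature: pd.DataFrame, period: Period):
    """Univariate post-landmark Cox of all-cause death on the signature label."""
    ids_surv, time, event = _landmark_survival(cohort, period)
    lab = signature.set_index("patient_id")["carries"]
    keep = np.isin(ids_surv, lab.index)
    z = lab.reindex(ids_surv[keep]).to_numpy(bool)
    res = binary_cox(time[keep], event[keep], z)
    res["n"] = int(keep.sum())
    res["events"] = int(event[keep].sum())
    return res


def cross_validate_period(cohort: Cohort, embedded: pd.DataFrame, period: Period,
                          k: int = 10, seed: int = 0,
                          expected_split: str | None = None,
                          **scan_kwargs) -> dict:
    """k-fold cross-validated test that a period carries a mortality signature.

    Patients are partitioned into k seeded folds; anchors are discovered on
    the k-1 training folds and the held-out patients' signature labels are
    recorded; the pooled held-out labels are tested by one post-landmark
    Cox regression. Returns the pooled p-value plus per-fold anchor counts.
    """
    ids = np.asarray(cohort.patient_ids)
    if k < 2 or k > len(ids):
        raise ValueError(f"k must be in [2, n_patients]; got {k} for {len(ids)} patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)

    grid = scan_kwargs.pop("grid", None)
    if grid is None:
        grid = build_grid(embedded, scan_kwargs.pop("n_per_axis", DEFAULT_GRID))
    else:
        scan_kwargs.pop("n_per_axis", None)

    pooled = []
    anchor_counts = []
    for fold in folds:
        held = set(ids[fold])
        train = cohort.subset([p for p in ids if p not in held])
        aset = scan_anchor_points(train, embedded, period, grid=grid,
                                  expected_split=expected_split, **scan_kwargs)
        anchor_counts.append(int(aset.anchor_mask.sum()))
        held_cohort = cohort.subset(held)
        sig = assign_signature(held_cohort, embedded, aset, period)
        if len(sig) == 0:
            warnings.warn("cross-validation fold with no in-window patients; skipped")
            continue
        pooled.append(sig)
    if not pooled:
        raise FitError("no fold produced in-window patients")
    pooled_sig = pd.concat(pooled, ignore_index=True)
    res = signature_cox(cohort, pooled_sig, period)
    return {"period": period.label, "p_value": float(res["p_lr"]),
            "hazard_ratio": float(res["hr"]), "n": res["n"],
            "events": res["events"], "anchor_counts": anchor_counts,
            "signature": pooled_sig}


def permutation_null_anchor_fraction(cohort: Cohort, embedded: pd.DataFrame,
                                     period: Period, n_permutations: int = 50,
                                     seed: int = 0,
                                     radius_steps: float = DEFAULT_RADIUS_STEPS,
                                     alpha: float = DEFAULT_ALPHA,
                                     n_per_axis: int = DEFAULT_GRID,
                                     min_group: int = MIN_GROUP) -> np.ndarray:
    """Anchor fraction among testable grid points under outcome permutation.

    The near-label matrix is computed once; each permutation shuffles the
    (time, event) pairs across patients, breaking any outcome-location
    association while preserving both marginals. Returns one fraction per
    permutation.
    """
    grid = build_grid(embedded, n_per_axis)
    ids_near, near = patient_near_matrix(cohort, embedded, period, grid, radius_steps)
    ids_surv, time, event = _landmark_survival(cohort, period)
    keep = np.isin(ids_near, ids_surv)
    near = near[keep]
    surv_index = {p: i for i, p in enumerate(ids_surv)}
    sel = np.array([surv_index[p] for p in ids_near[keep]], dtype=int)
    time, event = time[sel], event[sel]

    n_near = near.sum(axis=0)
    testable = (n_near >= min_group) & (near.shape[0] - n_near >= min_group)
    if not testable.any():
        raise FitError("no testable grid points at this resolution")
    near_t = near[:, testable]

    rng = np.random.default_rng(seed)
    fracs = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(near.shape[0])
        res = binary_cox(time[perm], event[perm], near_t)
        fracs[b] = float((res["p_lr"] < alpha).mean())
    return fracs
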