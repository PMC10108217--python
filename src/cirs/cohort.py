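"""Cohort data model: immune-profile and outcome tables, validation, derived
counts, min-max rescaling, time-period windowing and per-patient aggregation.

An *immune profile* is one blood draw described by 20 features:

==============  =================================================
``wbc`` .. ``lymph``        six complete-blood-count cell counts (10^9/L)
``mono_frac_nuc``, ``lymph_frac_nuc``  fractions of nucleated cells, in [0, 1]
``nk_frac`` .. ``b_frac``   six flow-cytometry fractions of lymphocytes, in [0, 1]
``nk_count`` .. ``b_count`` six subset counts derived as lymph x fraction
==============  =================================================

Fractions are stored as proportions (0.35, never 35). Tables are plain CSV
with a header row; column names are exactly the field names above plus
``patient_id`` and ``day``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

# canonical feature order; the 20 columns every analysis step consumes
COUNT_FEATURES = ["wbc", "neut", "eos", "baso", "mono", "lymph"]
NUC_FRAC_FEATURES = ["mono_frac_nuc", "lymph_frac_nuc"]
LYMPH_FRAC_FEATURES = ["nk_frac", "t_frac", "cd4_frac", "cd8_frac", "treg_frac", "b_frac"]
DERIVED_COUNT_FEATURES = ["nk_count", "t_count", "cd4_count", "cd8_count", "treg_count", "b_count"]
FEATURES = COUNT_FEATURES + NUC_FRAC_FEATURES + LYMPH_FRAC_FEATURES + DERIVED_COUNT_FEATURES

#: derived count -> the lymphocyte fraction it is the product of
DERIVED_FROM = dict(zip(DERIVED_COUNT_FEATURES, LYMPH_FRAC_FEATURES))

PROFILE_COLUMNS = ["patient_id", "day"] + FEATURES

OUTCOME_COLUMNS = [
    "patient_id", "age", "sex", "primary_disease", "transplant_type",
    "conditioning", "atg_used", "os_time", "death", "cause",
    "severe_agvhd_100d",
    "infections_d1_90", "infections_d91_180", "infections_d181_270", "infections_d271_360",
    "cohort_split",
]

CAUSES = ("relapse", "infection_nrm", "other_nrm", "none")
SPLITS = ("training", "validation", "test")


@dataclass(frozen=True)
class Period:
    """A closed integer interval of days post-transplant."""

    label: str
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.start_day > self.end_day:
            raise ValueError(f"Period {self.label}: start {self.start_day} > end {self.end_day}")

    def contains(self, day) -> np.ndarray:
        day = np.asarray(day)
        return (day >= self.start_day) & (day <= self.end_day)

    @property
    def landmark(self) -> int:
        """Day from which post-period survival is measured (the period's end)."""
        return self.end_day


#: the four candidate discovery periods screened by cross-validation
CANONICAL_PERIODS = (
    Period("d1_90", 1, 90),
    Period("d91_180", 91, 180),
    Period("d181_270", 181, 270),
    Period("d271_360", 271, 360),
)


def period_by_label(label: str) -> Period:
    for p in CANONICAL_PERIODS:
        if p.label == label:
            return p
    raise KeyError(f"unknown period label {label!r}; known: "
                   f"{[p.label for p in CANONICAL_PERIODS]}")


@dataclass
class Cohort:
    """A validated pair of tables: per-draw immune profiles and per-patient
    outcomes/covariates."""

    profiles: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self):
        self.profiles = self.profiles.reset_index(drop=True)
        self.outcomes = self.outcomes.reset_index(drop=True)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.outcomes["patient_id"])

    def subset(self, patient_ids) -> "Cohort":
        ids = set(patient_ids)
        return Cohort(
            self.profiles[self.profiles["patient_id"].isin(ids)].copy(),
            self.outcomes[self.outcomes["patient_id"].isin(ids)].copy(),
        )

    def split(self, name: str) -> "Cohort":
        if name not in SPLITS:
            raise KeyError(f"unknown split {name!r}")
        keep = self.outcomes.loc[self.outcomes["cohort_split"] == name, "patient_id"]
        return self.subset(keep)


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {missing}")


def validate_profiles(profiles: pd.DataFrame, strict: bool = True) -> list[str]:
    """Check hard per-row invariants; return a per-row violation report.

    Hard: day > 0, counts >= 0, fractions in [0, 1]. Soft (warn only, aimed
    at real laboratory data): lymph <= wbc, cd4_frac + cd8_frac <= t_frac.
    With ``strict`` the offending rows raise; otherwise the report is
    returned for the caller to drop rows.
    """
    report = []
    day = profiles["day"]
    bad_day = ~(pd.to_numeric(day, errors="coerce") > 0)
    for i in profiles.index[bad_day]:
        report.append(f"row {i}: day must be a positive integer (got {day[i]!r})")
    for col in COUNT_FEATURES + DERIVED_COUNT_FEATURES:
        vals = pd.to_numeric(profiles[col], errors="coerce")
        bad = vals < 0
        for i in profiles.index[bad.fillna(False)]:
            report.append(f"row {i}: {col} must be >= 0 (got {vals[i]})")
    for col in NUC_FRAC_FEATURES + LYMPH_FRAC_FEATURES:
        vals = pd.to_numeric(profiles[col], errors="coerce")
        bad = (vals < 0) | (vals > 1)
        for i in profiles.index[bad.fillna(False)]:
            report.append(f"row {i}: {col} must lie in [0, 1] (got {vals[i]})")

    soft = profiles["lymph"] > profiles["wbc"] + 1e-9
    if soft.any():
        warnings.warn(f"{int(soft.sum())} profile row(s) have lymph > wbc; kept as-is")
    soft2 = profiles["cd4_frac"] + profiles["cd8_frac"] > profiles["t_frac"] + 1e-9
    if soft2.any():
        warnings.warn(f"{int(soft2.sum())} profile row(s) have cd4_frac + cd8_frac > t_frac")

    if strict and report:
        raise ValidationError(f"{len(report)} profile row(s) violate hard invariants", report)
    return report


def validate_outcomes(outcomes: pd.DataFrame, strict: bool = True) -> list[str]:
    report = []
    for i, row in outcomes.iterrows():
        if not row["os_time"] > 0:
            report.append(f"row {i}: os_time must be > 0 (got {row['os_time']})")
        if bool(row["death"]) != (row["cause"] != "none"):
            report.append(f"row {i}: cause must be 'none' iff death is False "
                          f"(death={row['death']}, cause={row['cause']!r})")
        if row["cause"] not in CAUSES:
            report.append(f"row {i}: unknown cause {row['cause']!r}")
    if strict and report:
        raise ValidationError(f"{len(report)} outcome row(s) violate hard invariants", report)
    return report


def load_cohort(profiles_path, outcomes_path, drop_invalid: bool = False) -> Cohort:
    """Read and validate the two cohort CSVs.

    With ``drop_invalid`` rows violating hard invariants are dropped and the
    violations reported as a warning instead of raising.
    """
    profiles = pd.read_csv(profiles_path)
    outcomes = pd.read_csv(outcomes_path)
    _require_columns(profiles, PROFILE_COLUMNS, "profiles")
    _require_columns(outcomes, ["patient_id", "os_time", "death", "cause", "cohort_split"],
                     "outcomes")
    for col in ["day"] + FEATURES:
        try:
            profiles[col] = pd.to_numeric(profiles[col])
        except (ValueError, TypeError) as e:
            bad = pd.to_numeric(profiles[col], errors="coerce").isna() & profiles[col].notna()
            idx = list(profiles.index[bad][:5])
            raise SchemaError(f"profiles column {col!r} is not numeric "
                              f"(first bad row indices: {idx})") from e

    if drop_invalid:
        report = validate_profiles(profiles, strict=False)
        if report:
            warnings.warn("dropped invalid profile rows:\n" + "\n".join(report))
            bad_rows = sorted({int(r.split()[1].rstrip(":")) for r in report})
            profiles = profiles.drop(index=bad_rows)
        validate_outcomes(outcomes, strict=True)
    else:
        validate_profiles(profiles, strict=True)
        validate_outcomes(outcomes, strict=True)
    return Cohort(profiles, outcomes)


def write_cohort(cohort: Cohort, profiles_path, outcomes_path) -> None:
    """Write the two cohort CSVs (UTF-8, header row, full float precision)."""
    cohort.profiles.to_csv(profiles_path, index=False, float_format="%.12g")
    cohort.outcomes.to_csv(outcomes_path, index=False, float_format="%.12g")


def derive_counts(profiles: pd.DataFrame) -> pd.DataFrame:
    """Set each derived subset count to lymphocyte count x subset fraction.

    E.g. nk_count = lymph * nk_frac. Other columns pass through unchanged;
    missing inputs propagate as missing.
    """
    out = profiles.copy()
    for count_col, frac_col in DERIVED_FROM.items():
        out[count_col] = out["lymph"] * out[frac_col]
    return out


@dataclass
class ScalingMap:
    """Frozen per-feature min-max ranges fitted on a profile set."""

    mins: pd.Series
    maxs: pd.Series
    features: list[str] = field(default_factory=lambda: list(FEATURES))

    def __post_init__(self):
        if (self.maxs < self.mins).any():
            raise ValueError("ScalingMap: max < min for some feature")


def fit_rescaler(profiles: pd.DataFrame, features=None) -> ScalingMap:
    """Fit the linear [0, 1] rescaling on the given profile set.

    The map is fitted once on the full set of profiles being analyzed and
    then frozen; later data are transformed with the same map and clipped.
    """
    features = list(features) if features is not None else list(FEATURES)
    if len(profiles) < 2:
        raise ValueError("fit_rescaler needs at least 2 profiles")
    sub = profiles[features].astype(float)
    m = ScalingMap(sub.min(axis=0), sub.max(axis=0), features)
    constant = m.features and (m.maxs == m.mins)
    if isinstance(constant, pd.Series) and constant.any():
        warnings.warn(f"constant feature(s) mapped to 0 everywhere: "
                      f"{list(m.mins.index[constant])}")
    return m


def apply_rescaler(scaling: ScalingMap, profiles: pd.DataFrame) -> pd.DataFrame:
    """Apply a frozen min-max map; out-of-range values are clipped to [0, 1].

    Constant features (max == min in the fitted set) map to 0 everywhere.
    """
    sub = profiles[scaling.features].astype(float)
    span = (scaling.maxs - scaling.mins).replace(0.0, np.nan)
    scaled = (sub - scaling.mins) / span
    scaled = scaled.fillna(0.0).clip(0.0, 1.0)
    return scaled


def window_profiles(cohort: Cohort, period: Period) -> tuple[pd.DataFrame, pd.Index]:
    """Profiles with start_day <= day <= end_day (both ends inclusive).

    Returns the in-window profile rows and the ids of patients with *no*
    in-window profile; absent patients are flagged, never imputed.
    """
    mask = period.contains(cohort.profiles["day"].to_numpy())
    in_window = cohort.profiles[mask]
    present = set(in_window["patient_id"])
    absent = pd.Index([p for p in cohort.patient_ids if p not in present])
    return in_window, absent


def average_features(cohort: Cohort, period: Period, features=None) -> pd.DataFrame:
    """Per-patient mean of each feature over in-window profiles.

    Patients with no in-window profile get NaN rows (they are *absent*, not
    zero). Indexed by patient_id, one column per feature.
    """
    features = list(features) if features is not None else list(FEATURES)
    in_window, _ = window_profiles(cohort, period)
    means = in_window.groupby("patient_id")[features].mean()
    return means.reindex(cohort.patient_ids)
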