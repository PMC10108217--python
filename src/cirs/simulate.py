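"""Synthetic cohort generator with planted ground truth.

Emulates visit-scheduled multivariate immune recovery after transplant:
each blood lineage recovers along a saturating curve
``mean(t) = plateau * (1 - exp(-t / rise_time))`` with multiplicative
log-normal observation noise and a per-patient, per-lineage log-normal
random effect. A latent fraction of patients is "derailed": their
lymphoid plateaus are multiplied by ``exp(-derail_shift)`` (myeloid
recovery untouched), which places their profiles in a distinct region of
feature space, and their all-cause death hazard is multiplied by
``exp(derail_log_hr)``. Death causes are drawn from a fixed mix
independently of time; follow-up is administratively censored.

The generator exports the planted truth (derailed flag, true log hazard
ratio, true cause) so downstream discovery can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, derive_counts, PROFILE_COLUMNS, OUTCOME_COLUMNS
from .errors import ConfigError

# recovery-curve parameters per simulated lineage: (plateau 10^9/L, rise days,
# log-normal observation noise sd). CD8 recovers fastest among lymphocytes,
# CD4 and B slowest; myeloid lineages engraft within weeks.
DEFAULT_LINEAGES = {
    "neut":        (3.00, 15.0, 0.35),
    "eos":         (0.15, 60.0, 0.45),
    "baso":        (0.04, 60.0, 0.45),
    "mono":        (0.50, 20.0, 0.35),
    "nk":          (0.30, 45.0, 0.40),
    "cd8":         (0.60, 60.0, 0.40),
    "cd4":         (0.50, 180.0, 0.40),
    "b":           (0.25, 180.0, 0.45),
    "other_t":     (0.10, 90.0, 0.40),
    "other_lymph": (0.05, 90.0, 0.45),
}
LYMPHOID = ("nk", "cd8", "cd4", "b", "other_t", "other_lymph")


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 2000
    visit_days: tuple = (30, 60, 90, 135, 180, 270, 360)
    visit_jitter_sd: float = 4.0            # days
    lineage_params: dict = field(default_factory=lambda: dict(DEFAULT_LINEAGES))
    patient_effect_sd: float = 0.25         # between-patient log-scale sd (plateau)
    rise_time_sd: float = 0.6               # between-patient log-scale sd (kinetics)
    treg_frac_of_cd4: float = 0.08
    derail_fraction: float = 0.15
    derail_shift: float = 2.0               # log-scale lymphoid plateau shift
    baseline_hazard: float = 2e-4           # events per day for non-derailed
    derail_log_hr: float = math.log(3.0)
    cause_mix: dict = field(default_factory=lambda: {
        "relapse": 0.45, "infection_nrm": 0.25, "other_nrm": 0.30})
    censor_day: float = 1095.0
    # covariate model (feeds the logistic risk-factor validation)
    agvhd_prob: tuple = (0.08, 0.20)        # (background, derailed)
    infection_rate_d1_90: tuple = (0.25, 0.60)
    infection_rate_late: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        days = np.asarray(self.visit_days, dtype=float)
        if len(days) == 0 or (days <= 0).any() or (np.diff(days) <= 0).any():
            raise ConfigError("visit_days must be strictly increasing and positive")
        if self.visit_jitter_sd < 0:
            raise ConfigError("visit_jitter_sd must be >= 0")
        if self.patient_effect_sd < 0:
            raise ConfigError("patient_effect_sd must be >= 0")
        if self.rise_time_sd < 0:
            raise ConfigError("rise_time_sd must be >= 0")
        for name, (plateau, rise, sd) in self.lineage_params.items():
            if plateau < 0 or rise <= 0 or sd < 0:
                raise ConfigError(f"lineage_params[{name!r}] must have plateau >= 0, "
                                  "rise_time > 0, noise sd >= 0")
        if not 0.0 <= self.derail_fraction <= 1.0:
            raise ConfigError("derail_fraction must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-12:
            raise ConfigError("cause_mix probabilities must sum to 1")
        if self.censor_day < 0:
            raise ConfigError("censor_day must be >= 0")


def simulate_survival(linear_predictor: np.ndarray, config: SimConfig,
                      rng: np.random.Generator | None = None):
    """Exponential event times under hazard = baseline * exp(linear_predictor).

    Events after ``censor_day`` are censored there; the death cause is drawn
    from ``cause_mix`` independently of the event time. Returns
    ``(time, death, cause)`` arrays.
    """
    config.validate()
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.isfinite(lp).all():
        raise ConfigError("linear_predictor contains non-finite values")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    hazard = config.baseline_hazard * np.exp(lp)
    raw = rng.exponential(1.0 / hazard)
    death = raw <= config.censor_day
    time = np.minimum(raw, config.censor_day)
    causes = list(config.cause_mix)
    probs = np.array([config.cause_mix[c] for c in causes])
    drawn = rng.choice(len(causes), size=lp.size, p=probs)
    cause = np.where(death, np.array(causes, dtype=object)[drawn], "none")
    return time, death, cause


def _simulate_covariates(derailed: np.ndarray, config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    n = derailed.size
    age = np.clip(np.round(rng.normal(32, 16, n)), 2, 70).astype(int)
    sex = rng.choice(["M", "F"], size=n, p=[0.55, 0.45])
    disease = rng.choice(["ALL_AML", "MDS", "other_neoplasm", "BMF"],
                         size=n, p=[0.66, 0.13, 0.08, 0.13])
    ttype = rng.choice(["MSD", "haplo", "MUD", "UCB"],
                       size=n, p=[0.40, 0.25, 0.05, 0.30])
    conditioning = rng.choice(["MAC", "RIC"], size=n, p=[0.85, 0.15])
    atg = rng.random(n) < 0.40
    p_agvhd = np.where(derailed, config.agvhd_prob[1], config.agvhd_prob[0])
    agvhd = rng.random(n) < p_agvhd
    rate_early = np.where(derailed, config.infection_rate_d1_90[1],
                          config.infection_rate_d1_90[0])
    inf_1_90 = rng.poisson(rate_early)
    inf_late = rng.poisson(config.infection_rate_late, size=(3, n))
    return pd.DataFrame({
        "age": age, "sex": sex, "primary_disease": disease,
        "transplant_type": ttype, "conditioning": conditioning, "atg_used": atg,
        "severe_agvhd_100d": agvhd,
        "infections_d1_90": inf_1_90,
        "infections_d91_180": inf_late[0],
        "infections_d181_270": inf_late[1],
        "infections_d271_360": inf_late[2],
    })


def simulate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a full cohort; returns ``(cohort, ground_truth)``.

    The ground-truth table has one row per patient: the latent derailed
    flag, the true log hazard ratio applied, and the true cause label.
    Profiles dated after a patient's event/censoring day are not emitted.
    Deterministic: the same config (including seed) yields byte-identical
    tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pid = np.array([f"P{i:05d}" for i in range(n)])

    derailed = rng.random(n) < config.derail_fraction
    lp = np.where(derailed, config.derail_log_hr, 0.0)
    os_time, death, cause = simulate_survival(lp, config, rng)
    covars = _simulate_covariates(derailed, config, rng)

    split = rng.choice(["training", "validation", "test"], size=n, p=[0.5, 0.25, 0.25])

    # visit schedule with jitter, truncated at event/censoring
    nominal = np.asarray(config.visit_days, dtype=float)
    n_visits = nominal.size
    jitter = rng.normal(0.0, config.visit_jitter_sd, size=(n, n_visits)) \
        if config.visit_jitter_sd > 0 else np.zeros((n, n_visits))
    days = np.maximum(np.round(nominal[None, :] + jitter), 1.0)

    lineages = list(config.lineage_params)
    params = {k: config.lineage_params[k] for k in lineages}
    # per-patient, per-lineage log-normal random effects: plateau level and
    # recovery speed (rate heterogeneity fans patients out mid-recovery and
    # re-converges them at plateau, peaking between-patient variance early)
    pat_eff = np.exp(rng.normal(0.0, config.patient_effect_sd, size=(n, len(lineages))))
    rise_eff = np.exp(rng.normal(0.0, config.rise_time_sd, size=(n, len(lineages))))
    counts = {}
    for j, name in enumerate(lineages):
        plateau, rise, sd = params[name]
        plat = np.full(n, plateau)
        if name in LYMPHOID:
            plat = plat * np.where(derailed, np.exp(-config.derail_shift), 1.0)
        rise_i = rise * rise_eff[:, j][:, None]
        mean = plat[:, None] * pat_eff[:, j][:, None] * (1.0 - np.exp(-days / rise_i))
        noise = np.exp(rng.normal(0.0, sd, size=(n, n_visits)))
        counts[name] = mean * noise

    treg = config.treg_frac_of_cd4 * counts["cd4"] * \
        np.exp(rng.normal(0.0, 0.2, size=(n, n_visits)))

    t_cells = counts["cd4"] + counts["cd8"] + counts["other_t"]
    lymph = t_cells + counts["nk"] + counts["b"] + counts["other_lymph"]
    wbc = lymph + counts["neut"] + counts["eos"] + counts["baso"] + counts["mono"]

    keep = days <= os_time[:, None]
    rows = {
        "patient_id": np.repeat(pid, n_visits),
        "day": days.astype(int).ravel(),
        "wbc": wbc.ravel(), "neut": counts["neut"].ravel(),
        "eos": counts["eos"].ravel(), "baso": counts["baso"].ravel(),
        "mono": counts["mono"].ravel(), "lymph": lymph.ravel(),
        "mono_frac_nuc": (counts["mono"] / wbc).ravel(),
        "lymph_frac_nuc": (lymph / wbc).ravel(),
        "nk_frac": (counts["nk"] / lymph).ravel(),
        "t_frac": (t_cells / lymph).ravel(),
        "cd4_frac": (counts["cd4"] / lymph).ravel(),
        "cd8_frac": (counts["cd8"] / lymph).ravel(),
        "treg_frac": (treg / lymph).ravel(),
        "b_frac": (counts["b"] / lymph).ravel(),
    }
    profiles = pd.DataFrame(rows)[keep.ravel()]
    profiles = derive_counts(profiles)[PROFILE_COLUMNS].reset_index(drop=True)

    outcomes = pd.DataFrame({
        "patient_id": pid,
        **{c: covars[c] for c in covars.columns},
        "os_time": os_time, "death": death, "cause": cause,
        "cohort_split": split,
    })[OUTCOME_COLUMNS]

    truth = pd.DataFrame({
        "patient_id": pid,
        "derailed": derailed,
        "true_log_hr": lp,
        "true_cause": cause,
    })
    return Cohort(profiles, outcomes), truth
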