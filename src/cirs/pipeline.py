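"""End-to-end orchestration: simulate (or load) -> rescale -> embed ->
cross-validated period screening -> anchor discovery on the training split
-> score-model fit -> verification on every split.

Anchors and the score model are computed strictly from the training
split; the other splits' outcomes reach only the verification stage (a
leakage guard raises otherwise). Every stage writes deterministic CSV/JSON
artifacts so that two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anchors import (assign_signature, build_grid, cross_validate_period,
                      scan_anchor_points, signature_cox)
from .cohort import (Cohort, apply_rescaler, average_features, fit_rescaler,
                     load_cohort, period_by_label, write_cohort,
                     CANONICAL_PERIODS)
from .embedding import EmbedParams, embed_profiles
from .errors import ConfigError
from .score import PUBLISHED_MODEL, RiskScoreModel, fit_score_model, score_patient_period
from .simulate import SimConfig, simulate_cohort

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one full discovery run."""

    sim: SimConfig = field(default_factory=SimConfig)
    profiles_path: str | None = None     # load instead of simulate when set
    outcomes_path: str | None = None
    periods: tuple = tuple(p.label for p in CANONICAL_PERIODS)
    discovery_period: str = "d91_180"
    n_per_axis: int = 121
    radius_steps: float = 5.0
    alpha: float = 0.01
    cv_folds: int = 10
    screen_alpha: float = 0.05
    perplexity: float = 30.0
    tsne_iter: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "seed" not in raw and "seed" not in sim_raw:
            raise ConfigError("seed is mandatory in pipeline configs")
        cfg = cls(sim=SimConfig(**sim_raw), **raw)
        cfg.sim.seed = cfg.sim.seed if "seed" in sim_raw else cfg.seed
        return cfg

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _get_cohort(config: RunConfig) -> tuple[Cohort, pd.DataFrame | None]:
    if config.profiles_path is not None:
        if config.outcomes_path is None:
            raise ConfigError("outcomes_path required when profiles_path is set")
        return load_cohort(config.profiles_path, config.outcomes_path), None
    return simulate_cohort(config.sim)


def embed_cohort(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    """Rescale the 20 features over the full profile set and embed."""
    scaling = fit_rescaler(cohort.profiles)
    scaled = apply_rescaler(scaling, cohort.profiles)
    return embed_profiles(scaled, cohort.profiles[["patient_id", "day"]],
                          EmbedParams(config.perplexity, config.tsne_iter, config.seed))


def run_discovery(config: RunConfig, out_dir=None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report.

    Raises ConfigError when a referenced split is empty; raises
    LeakageError if a discovery stage ever sees non-training outcomes.
    """
    cohort, truth = _get_cohort(config)
    for split_name in ("training", "validation", "test"):
        if (cohort.outcomes["cohort_split"] == split_name).sum() == 0:
            raise ConfigError(f"split {split_name!r} is empty")

    embedded = embed_cohort(cohort, config)
    training = cohort.split("training")
    grid = build_grid(embedded, config.n_per_axis)

    # 1) screen candidate periods by k-fold CV inside the training split
    screening = []
    for label in config.periods:
        period = period_by_label(label)
        cv = cross_validate_period(training, embedded, period, k=config.cv_folds,
                                   seed=config.seed, expected_split="training",
                                   grid=grid, radius_steps=config.radius_steps,
                                   alpha=config.alpha)
        screening.append({"period": label, "p_value": cv["p_value"],
                          "hazard_ratio": cv["hazard_ratio"], "n": cv["n"],
                          "events": cv["events"],
                          "passed": cv["p_value"] < config.screen_alpha})
    screening = pd.DataFrame(screening)

    # 2) discover anchors for the configured period on the full training split
    period = period_by_label(config.discovery_period)
    anchors = scan_anchor_points(training, embedded, period, grid=grid,
                                 radius_steps=config.radius_steps,
                                 alpha=config.alpha, expected_split="training")
    train_sig = assign_signature(training, embedded, anchors, period)

    # 3) distill the signature into a score on training features only
    feats = average_features(training, period).dropna()
    sig = train_sig.set_index("patient_id")["carries"]
    common = feats.index.intersection(sig.index)
    model = fit_score_model(feats.loc[common], sig.reindex(common).to_numpy())

    # 4) verify signature and score on each split separately
    verification = []
    for split_name in ("training", "validation", "test"):
        sub = cohort.split(split_name)
        sub_sig = assign_signature(sub, embedded, anchors, period)
        sig_res = signature_cox(sub, sub_sig, period)
        scores = score_patient_period(sub, period, model)
        lab = scores.set_index("patient_id")["label"] == "high"
        score_res = signature_cox(
            sub, pd.DataFrame({"patient_id": lab.index, "carries": lab.to_numpy()}),
            period)
        verification.append({
            "split": split_name,
            "signature_hr": float(sig_res["hr"]), "signature_p": float(sig_res["p_lr"]),
            "score_hr": float(score_res["hr"]), "score_p": float(score_res["p_lr"]),
            "n": sig_res["n"], "events": sig_res["events"],
            "high_fraction": float(lab.mean()) if len(lab) else float("nan"),
        })
    verification = pd.DataFrame(verification)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_patients": int(len(cohort.outcomes)),
        "n_profiles": int(len(cohort.profiles)),
        "screening": screening.to_dict(orient="records"),
        "discovery_period": config.discovery_period,
        "n_anchors": int(anchors.anchor_mask.sum()),
        "score_model": {
            "features": list(model.coefficients),
            "coefficients": {k: float(v) for k, v in model.coefficients.items()},
            "intercept": model.intercept,
            "threshold": model.threshold,
            "provenance": model.provenance,
        },
        "verification": verification.to_dict(orient="records"),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "profiles.csv", out / "outcomes.csv")
        if truth is not None:
            truth.to_csv(out / "ground_truth.csv", index=False, float_format=FLOAT_FMT)
        embedded.to_csv(out / "embedded.csv", index=False, float_format=FLOAT_FMT)
        screening.to_csv(out / "period_screening.csv", index=False, float_format=FLOAT_FMT)
        anchors.to_json(out / "anchors.json", out / "p_surface.csv")
        train_sig.to_csv(out / "training_signature.csv", index=False,
                         float_format=FLOAT_FMT)
        verification.to_csv(out / "verification.csv", index=False, float_format=FLOAT_FMT)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_score_only(features: pd.DataFrame | dict,
                   model: RiskScoreModel = PUBLISHED_MODEL) -> pd.DataFrame:
    """Calculator mode: published score + label for rows of feature values."""
    if isinstance(features, dict):
        features = pd.DataFrame([features])
    scores = model.score(features)
    return pd.DataFrame({
        "score": np.atleast_1d(scores),
        "label": np.where(np.atleast_1d(scores) > model.threshold, "high", "low"),
    })
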