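"""Shared fixtures.

The expensive session fixture (`planted_run`) simulates the default
planted cohort once, embeds it and scans the days-91-180 grid; several
discovery and acceptance tests share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from cirs import (EmbedParams, SimConfig, apply_rescaler, embed_profiles,
                  fit_rescaler, period_by_label, scan_anchor_points,
                  simulate_cohort)
from cirs.anchors import build_grid


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 250-patient cohort for data-model tests."""
    cohort, truth = simulate_cohort(SimConfig(n_patients=250, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def planted_run():
    """Default planted cohort (n=2000, seed 0), embedded and scanned.

    Returns a dict with the cohort, ground truth, embedding, grid and the
    days-91-180 anchor set discovered on the training split.
    """
    config = SimConfig()          # n=2000, derail_fraction .15, HR 3, seed 0
    cohort, truth = simulate_cohort(config)
    scaling = fit_rescaler(cohort.profiles)
    embedded = embed_profiles(apply_rescaler(scaling, cohort.profiles),
                              cohort.profiles[["patient_id", "day"]],
                              EmbedParams(seed=0))
    period = period_by_label("d91_180")
    training = cohort.split("training")
    grid = build_grid(embedded)
    anchors = scan_anchor_points(training, embedded, period, grid=grid,
                                 expected_split="training")
    return {"config": config, "cohort": cohort, "truth": truth,
            "embedded": embedded, "grid": grid, "period": period,
            "training": training, "anchors": anchors}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
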