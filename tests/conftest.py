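from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from flms import PanelDataset, SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(
    scores: dict[str, dict[int, int]],
    modalities: tuple[str, ...] = ("m1", "m2"),
    n_features: int = 2,
    feature_values: dict | None = None,
    rng_seed: int = 0,
) -> PanelDataset:
    """Small deterministic panel: one feature row per (slot, modality, feature).

    ``feature_values`` may override specific cells keyed by
    (participant, week, modality, feature); a value of None drops the cell
    (missingness).
    """
    rng = np.random.default_rng(rng_seed)
    participants = list(scores)
    weeks = sorted({t for s in scores.values() for t in s})
    feature_values = feature_values or {}
    feat_rows, truth_rows = [], []
    for p in participants:
        for t, score in sorted(scores[p].items()):
            truth_rows.append((p, t, score))
            for m in modalities:
                for f_idx in range(n_features):
                    fname = f"f{f_idx}"
                    key = (p, t, m, fname)
                    if key in feature_values:
                        value = feature_values[key]
                        if value is None:
                            continue
                    else:
                        value = float(rng.normal())
                    feat_rows.append((p, t, m, fname, value))
    return PanelDataset(
        participants=participants,
        time_units=weeks,
        modalities=list(modalities),
        features=pd.DataFrame(
            feat_rows,
            columns=["participant", "time_unit", "modality", "feature", "value"],
        ),
        ground_truth=pd.DataFrame(
            truth_rows, columns=["participant", "time_unit", "score"]
        ),
    )


@pytest.fixture
def tiny_panel() -> PanelDataset:
    """2 participants x 4 weeks x 2 modalities, fully observed."""
    return make_panel(
        {
            "A": {1: 5, 2: 7, 3: 7, 4: 4},
            "B": {1: 10, 2: 8, 3: 11, 4: 11},
        }
    )


@pytest.fixture
def small_cohort() -> PanelDataset:
    """Simulated mini-cohort: 8 participants, 10 weeks, 3 modalities."""
    return simulate_cohort(
        SimConfig(
            n_participants=8,
            n_weeks=10,
            mean_weeks=9.0,
            weeks_sd=1.0,
            min_weeks=6,
            modalities={"a": 4, "b": 3, "c": 3},
            informative=("a", "b"),
            seed=7,
        )
    )
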