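"""Synthetic multimodal longitudinal cohorts for exercising the pipeline.

The generator emulates the statistical regime the framework targets: a few
dozen participants observed weekly for up to 24 weeks (with dropout leaving
~13 observed weeks each), six sensor modalities totalling ~61 features,
zero-inflated sparse feature values with heterogeneous per-participant
scales, and a PHQ-9-like integer score (0-27) whose week-over-week change
is the prediction target.

Each participant follows a latent AR(1) severity trajectory; informative
modalities' features are noisy linear readouts of that trajectory, while
the remaining modalities are pure noise.  That makes sensor-selection
behaviour testable: fusion sets containing informative modalities should
rank better (lower hamming distance) than noise-only sets when noise is
low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    SCORE_MAX,
    SCORE_MIN,
    ChangeSeries,
    PanelDataset,
    PanelValidationError,
    compute_change_scores,
)
from .ranking import encode_change

#: Feature counts per modality; totals 61, the size of the regime's final
#: feature table after redundancy pruning.
DEFAULT_MODALITIES: dict[str, int] = {
    "calls": 15,
    "location": 12,
    "screen": 10,
    "conversation": 14,
    "fitbit": 2,
    "wifi": 8,
}

DEFAULT_INFORMATIVE = ("calls", "location", "screen", "conversation")


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the reference regime."""

    n_participants: int = 45
    n_weeks: int = 24
    modalities: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MODALITIES)
    )
    informative: tuple[str, ...] = DEFAULT_INFORMATIVE
    rho: float = 0.8  # AR(1) persistence of latent severity
    sigma: float = 1.0  # feature observation noise (sd)
    tau: float = 1.0  # participant-offset scale (sd)
    zero_inflation: float = 0.35  # P(feature cell forced to exact 0)
    missing_rate: float = 0.05  # P(feature cell absent)
    mean_weeks: float = 13.0  # per-participant observed weeks (dropout)
    weeks_sd: float = 3.0
    min_weeks: int = 5
    score_slope: float = 3.0  # latent -> PHQ-like score map a*z + b
    score_intercept: float = 10.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise PanelValidationError("rho must be in (0, 1)")
        if not 0 <= self.zero_inflation < 1:
            raise PanelValidationError("zero_inflation must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise PanelValidationError("missing_rate must be in [0, 1)")
        if self.sigma < 0 or self.tau < 0:
            raise PanelValidationError("sigma and tau must be >= 0")
        if self.n_participants < 1 or self.n_weeks < 2:
            raise PanelValidationError("need >=1 participant and >=2 weeks")
        unknown = set(self.informative) - set(self.modalities)
        if unknown:
            raise PanelValidationError(f"informative modalities unknown: {unknown}")


def simulate_cohort(config: SimConfig) -> PanelDataset:
    """Draw one cohort; identical config + seed gives an identical panel."""
    rng = np.random.default_rng(config.seed)
    modalities = list(config.modalities)
    participants = [f"P{idx + 1:03d}" for idx in range(config.n_participants)]

    # fixed linear readout per feature: informative modalities load on the
    # severity level and on its week-over-week change (behavioural streams
    # track both state and shifts in state); noise modalities load on neither
    level_load: dict[str, np.ndarray] = {}
    change_load: dict[str, np.ndarray] = {}
    for m in modalities:
        k = config.modalities[m]
        if m in config.informative:
            level_load[m] = rng.normal(0.7, 0.3, size=k)
            change_load[m] = rng.normal(0.7, 0.3, size=k)
        else:
            level_load[m] = np.zeros(k)
            change_load[m] = np.zeros(k)

    feat_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for p in participants:
        offset = rng.normal(0.0, config.tau)
        n_obs = int(
            np.clip(
                round(rng.normal(config.mean_weeks, config.weeks_sd)),
                config.min_weeks,
                config.n_weeks,
            )
        )
        # participant-specific feature scale heterogeneity per modality
        scales = {m: rng.lognormal(0.0, 0.4) for m in modalities}

        x = rng.normal(0.0, 1.0)  # stationary AR(1) deviation
        prev_score: int | None = None
        for week in range(1, n_obs + 1):
            if week > 1:
                x = config.rho * x + np.sqrt(1 - config.rho**2) * rng.normal()
            z = offset + x
            score = int(
                np.clip(
                    round(config.score_intercept + config.score_slope * z),
                    SCORE_MIN,
                    SCORE_MAX,
                )
            )
            truth_rows.append((p, week, score))
            dscore = 0 if prev_score is None else score - prev_score
            prev_score = score
            for m in modalities:
                k = config.modalities[m]
                noise = rng.normal(0.0, 1.0, size=k)
                values = scales[m] * (
                    level_load[m] * z + change_load[m] * dscore + config.sigma * noise
                )
                zero = rng.random(k) < config.zero_inflation
                missing = rng.random(k) < config.missing_rate
                values = np.where(zero, 0.0, values)
                for f_idx in range(k):
                    if missing[f_idx]:
                        continue
                    feat_rows.append(
                        (p, week, m, f"f{f_idx + 1:02d}", float(values[f_idx]))
                    )

    features = pd.DataFrame(
        feat_rows, columns=["participant", "time_unit", "modality", "feature", "value"]
    )
    truth = pd.DataFrame(truth_rows, columns=["participant", "time_unit", "score"])
    return PanelDataset(
        participants=participants,
        time_units=list(range(1, config.n_weeks + 1)),
        modalities=modalities,
        features=features,
        ground_truth=truth,
        feature_names={
            m: [f"f{i + 1:02d}" for i in range(config.modalities[m])]
            for m in modalities
        },
    )


def ground_truth_encoding(
    dataset: PanelDataset, changes: ChangeSeries | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """0/1-encode the true change scores: (truth tensor, target mask)."""
    if changes is None:
        changes = compute_change_scores(dataset)
    values, mask = changes.to_matrix(dataset.participants, dataset.time_units)
    truth = np.zeros(values.shape, dtype=int)
    truth[mask] = encode_change(values[mask])
    return truth, mask
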