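"""Run configuration: every tunable of the four-stage pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Stage-2 regression suite mirroring the seven classical regressors the
#: framework was designed around.  Order matters: it is the tie-break order
#: for best-model selection.
DEFAULT_SUITE = (
    "linear",
    "elastic_net",
    "random_forest",
    "adaboost",
    "extra_trees",
    "gradient_boosting",
    "xgboost",
)

#: Compact linear suite used by the bundled experiment harnesses, where the
#: full combinatorial sweep (63 fusion sets x 4 strategies x ~10^3 splits)
#: makes heavyweight ensembles impractically slow.
FAST_SUITE = ("ols", "ridge")

STRATEGIES = ("ATU", "LOTPO", "LOPO", "LTXO")

_FUSION_SCOPES = ("per_combination", "per_cardinality", "both")
_WEIGHTINGS = ("inverse", "softmax_neg_distance")
_TIE_RULES = ("half_up", "half_down")


class ConfigError(ValueError):
    """A configuration value is outside its documented range."""


@dataclass
class RunConfig:
    """Configuration for a full framework run.

    Defaults follow the reference setup: all four cross-validation
    strategies, the seven-regressor suite, KNN imputation with k=5,
    |r| > 0.9 correlated-feature drop, inverse-hamming strategy weights and
    random state 42.
    """

    modalities: list[str] | None = None
    strategies: tuple[str, ...] = STRATEGIES
    suite: tuple[str, ...] = DEFAULT_SUITE
    fusion_scope: str = "both"

    # split-plan parameters
    atu_w0: int = 2
    atu_step: int = 1
    lotpo_min_units: int = 3

    # stage-1 preprocessing
    impute_k: int = 5
    corr_threshold: float = 0.9
    log_features: tuple[str, ...] = ()
    participant_missing_max: float = 0.6
    global_preprocessing: bool = False

    # selection / ensembling
    honest_selection: bool = False
    weighting: str = "inverse"
    epsilon: float = 1e-9
    tie_rule: str = "half_up"
    ensemble_on_raw: bool = False

    seed: int = 42
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.fusion_scope not in _FUSION_SCOPES:
            raise ConfigError(f"fusion_scope must be one of {_FUSION_SCOPES}")
        if self.weighting not in _WEIGHTINGS:
            raise ConfigError(f"weighting must be one of {_WEIGHTINGS}")
        if self.tie_rule not in _TIE_RULES:
            raise ConfigError(f"tie_rule must be one of {_TIE_RULES}")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ConfigError(f"unknown strategies: {sorted(unknown)}")
        if not self.strategies:
            raise ConfigError("at least one strategy required")
        if self.impute_k < 1:
            raise ConfigError("impute_k must be >= 1")
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ConfigError("corr_threshold must be in (0, 1]")
        if not 0.0 <= self.participant_missing_max <= 1.0:
            raise ConfigError("participant_missing_max must be in [0, 1]")
        if self.atu_w0 < 1 or self.atu_step < 1:
            raise ConfigError("atu_w0 and atu_step must be >= 1")
        if self.lotpo_min_units < 2:
            raise ConfigError("lotpo_min_units must be >= 2")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        self.strategies = tuple(self.strategies)
        self.suite = tuple(self.suite)
        self.log_features = tuple(self.log_features)

    # -- YAML round trip ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config YAML must be a mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("strategies", "suite", "log_features"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
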