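"""End-to-end orchestration of the four-stage ranking framework.

``run_flms`` takes a validated panel and a :class:`~flms.config.RunConfig`
and executes: stage 1 (combinatorial fusion + preprocessing), stage 2
(regression suite under the four CV strategies with per-participant best
model selection), stage 3 (mean aggregation, 0/1 encoding, hamming-distance
ranking) and stage 4 (hamming-weighted ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FAST_SUITE, RunConfig
from .datamodel import PanelDataset, compute_change_scores
from .evaluation import per_user_metrics
from .fusion import (
    Preprocessor,
    build_fusion_set,
    enumerate_fusions,
    exclude_sparse_participants,
)
from .modeling import PredictionCube, build_plans, fit_predict_suite, select_best_model
from .ranking import (
    RankRecord,
    aggregate_mean,
    compute_weights,
    make_record,
    rank_candidates,
    weighted_ensemble,
)
from .synthetic import ground_truth_encoding


def harness_config(**overrides) -> RunConfig:
    """Configuration used by the bundled experiment harnesses.

    A compact linear suite and whole-dataset (stage-1-then-stage-2)
    preprocessing keep the full 63-fusion-set sweep tractable on one CPU;
    everything else follows the defaults.
    """
    params = dict(suite=FAST_SUITE, global_preprocessing=True)
    params.update(overrides)
    return RunConfig(**params)


@dataclass
class FLMSResult:
    """Everything a framework run produced, addressable by panel slot."""

    participants: list[str]
    time_units: list[int]
    weights: dict[str, float]
    min_hamming: dict[str, int]
    chosen_scope: dict[str, str]
    strategy_layers: dict[str, tuple[np.ndarray, np.ndarray]]
    fused: np.ndarray
    final: np.ndarray
    mask: np.ndarray
    truth: np.ndarray
    truth_mask: np.ndarray
    hamming_table: list[dict]
    metrics: dict[str, dict]
    seed: int
    best_algorithms: dict[str, dict[int, str]] = field(default_factory=dict)
    ranked_records: dict[str, list[RankRecord]] = field(default_factory=dict)


def _scope_label(subset: tuple[str, ...]) -> str:
    return "+".join(subset)


def run_flms(dataset: PanelDataset, config: RunConfig | None = None) -> FLMSResult:
    """Execute all four stages on a panel and return the ranked ensemble."""
    config = config or RunConfig()
    if config.participant_missing_max < 1.0:
        dataset = exclude_sparse_participants(dataset, config.participant_missing_max)
    if config.modalities is not None:
        modalities = list(config.modalities)
    else:
        modalities = dataset.modalities

    changes = compute_change_scores(dataset)
    target_values, target_mask = changes.to_matrix(
        dataset.participants, dataset.time_units
    )
    truth, truth_mask = ground_truth_encoding(dataset, changes)

    slot_pairs = list(zip(*np.nonzero(target_mask)))
    slots = [
        (dataset.participants[i], dataset.time_units[j]) for i, j in slot_pairs
    ]
    slot_of = {(int(i), int(j)): r for r, (i, j) in enumerate(slot_pairs)}

    wide = dataset.wide_features()
    plans = build_plans(target_mask, dataset.time_units, config)
    subsets = enumerate_fusions(modalities)

    def preprocessor_factory() -> Preprocessor:
        return Preprocessor(
            impute_k=config.impute_k,
            corr_threshold=config.corr_threshold,
            log_features=config.log_features,
        )

    best: dict[str, dict[tuple[str, ...], PredictionCube]] = {
        s: {} for s in plans
    }
    for subset in subsets:
        fs = build_fusion_set(dataset, subset, slots, wide)
        X_global = None
        if config.global_preprocessing:
            X_global = preprocessor_factory().fit_transform(fs.matrix)
        for strategy, plan in plans.items():
            cubes = fit_predict_suite(
                plan,
                fs.matrix,
                slots,
                slot_of,
                target_values,
                config.suite,
                config.seed,
                preprocessor_factory=None if X_global is not None else preprocessor_factory,
                X_global=X_global,
                fusion_id=subset,
            )
            best[strategy][subset] = select_best_model(
                cubes, target_values, config.suite, honest=config.honest_selection
            )

    # -- stage 3: candidate records, ranking, per-strategy choice ----------
    ranked_records: dict[str, list[RankRecord]] = {}
    chosen: dict[str, RankRecord] = {}
    hamming_table: list[dict] = []
    for strategy in plans:
        records: list[RankRecord] = []
        if config.fusion_scope in ("per_combination", "both"):
            for subset, cube in best[strategy].items():
                records.append(
                    make_record(cube, truth, _scope_label(subset), len(subset))
                )
        if config.fusion_scope in ("per_cardinality", "both"):
            for x in range(1, len(modalities) + 1):
                group = [
                    cube for subset, cube in best[strategy].items()
                    if len(subset) == x
                ]
                if not group:
                    continue
                agg = aggregate_mean(group)
                records.append(
                    make_record(agg, truth, f"{x}-sensor-mean", x)
                )
        ranked = rank_candidates(records)
        ranked_records[strategy] = ranked
        chosen[strategy] = next(r for r in ranked if r.chosen)
        hamming_table.extend(
            {
                "strategy": strategy,
                "scope": r.scope,
                "cardinality": r.cardinality,
                "distance": int(r.distance),
                "chosen": bool(r.chosen),
            }
            for r in ranked
        )

    # -- stage 4: weights and final ensemble -------------------------------
    weights = compute_weights(
        {s: chosen[s].distance for s in plans},
        epsilon=config.epsilon,
        scheme=config.weighting,
    )
    if config.ensemble_on_raw:
        layers = {
            s: (np.where(chosen[s].mask, chosen[s].raw, 0.0), chosen[s].mask)
            for s in plans
        }
        ens = weighted_ensemble(
            layers, weights, tie_rule=config.tie_rule, encode_output=False
        )
        ens.strategy_layers = {
            s: (chosen[s].encoded, chosen[s].mask) for s in plans
        }
    else:
        layers = {s: (chosen[s].encoded, chosen[s].mask) for s in plans}
        ens = weighted_ensemble(layers, weights, tie_rule=config.tie_rule)

    # -- evaluation ---------------------------------------------------------
    metrics: dict[str, dict] = {}
    metrics["FLMS"] = per_user_metrics(
        ens.final, truth, ens.mask & truth_mask, dataset.participants, "FLMS"
    ).to_dict()
    for s in plans:
        metrics[s] = per_user_metrics(
            chosen[s].encoded,
            truth,
            chosen[s].mask & truth_mask,
            dataset.participants,
            s,
        ).to_dict()

    return FLMSResult(
        participants=list(dataset.participants),
        time_units=list(dataset.time_units),
        weights=weights,
        min_hamming={s: int(chosen[s].distance) for s in plans},
        chosen_scope={s: chosen[s].scope for s in plans},
        strategy_layers={s: (chosen[s].encoded, chosen[s].mask) for s in plans},
        fused=ens.fused,
        final=ens.final,
        mask=ens.mask,
        truth=truth,
        truth_mask=truth_mask,
        hamming_table=hamming_table,
        metrics=metrics,
        seed=config.seed,
        best_algorithms={
            s: dict(best[s][tuple(modalities)].best_alg or {})
            for s in plans
            if tuple(modalities) in best[s]
        },
        ranked_records=ranked_records,
    )
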