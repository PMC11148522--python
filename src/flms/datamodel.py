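"""Core containers and tidy-CSV I/O for longitudinal multimodal panels.

The framework consumes a *panel*: per-participant, per-week feature rows
tagged by sensor modality (calls, location, screen, ...) together with a
weekly symptom score (PHQ-9-like, integer 0-27).  The regression target at
week ``m`` is the change score ``W_m - W_{m-1}``, defined only when both
weeks were scored and are consecutive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCORE_MIN = 0
SCORE_MAX = 27

FEATURE_COLUMNS = ["participant", "time_unit", "modality", "feature", "value"]
TRUTH_COLUMNS = ["participant", "time_unit", "score"]


class PanelValidationError(ValueError):
    """A structurally well-formed input violated a panel invariant."""


class PanelParseError(ValueError):
    """A CSV input could not be interpreted as panel data."""


def _ordered_unique(values: Iterable) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class PanelDataset:
    """Long-format participant x week x (modality, feature) observations.

    ``participants``, ``time_units`` and ``modalities`` are fixed, ordered
    axes; every matrix/tensor produced downstream addresses its slots by
    position in these lists, which makes tensor slot addressing
    deterministic across the whole pipeline.
    """

    participants: list[str]
    time_units: list[int]
    modalities: list[str]
    features: pd.DataFrame
    ground_truth: pd.DataFrame
    feature_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        self.ground_truth = self.ground_truth.reset_index(drop=True)
        self._validate()
        if not self.feature_names:
            self.feature_names = {
                m: _ordered_unique(
                    self.features.loc[self.features["modality"] == m, "feature"]
                )
                for m in self.modalities
            }

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        f, g = self.features, self.ground_truth
        missing = [c for c in FEATURE_COLUMNS if c not in f.columns]
        if missing:
            raise PanelParseError(f"feature table lacks columns {missing}")
        missing = [c for c in TRUTH_COLUMNS if c not in g.columns]
        if missing:
            raise PanelParseError(f"ground-truth table lacks columns {missing}")
        if f.empty:
            raise PanelValidationError("no observations")

        unknown = set(f["modality"]) - set(self.modalities)
        if unknown:
            raise PanelValidationError(f"unknown modalities: {sorted(unknown)}")
        unknown = set(f["participant"]) - set(self.participants)
        if unknown:
            raise PanelValidationError(f"unknown participants: {sorted(unknown)}")
        unknown = set(f["time_unit"]) - set(self.time_units)
        if unknown:
            raise PanelValidationError(f"unknown time units: {sorted(unknown)}")

        dup = f.duplicated(subset=["participant", "time_unit", "modality", "feature"])
        if dup.any():
            row = f[dup].iloc[0]
            raise PanelValidationError(
                "duplicate observation for "
                f"({row['participant']}, {row['time_unit']}, "
                f"{row['modality']}, {row['feature']})"
            )

        scores = g["score"]
        if not np.all(scores == scores.astype(int)):
            raise PanelValidationError("ground-truth scores must be integers")
        bad = g[(scores < SCORE_MIN) | (scores > SCORE_MAX)]
        if not bad.empty:
            row = bad.iloc[0]
            raise PanelValidationError(
                f"score {row['score']} for participant {row['participant']} "
                f"at time {row['time_unit']} outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        if g.duplicated(subset=["participant", "time_unit"]).any():
            raise PanelValidationError("duplicate ground-truth rows")

    # -- convenience views -------------------------------------------------

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def all_feature_columns(self, subset: Iterable[str] | None = None) -> list[str]:
        """Flat ``modality__feature`` column names, modality order first."""
        subset = list(subset) if subset is not None else self.modalities
        cols: list[str] = []
        for m in self.modalities:
            if m in subset:
                cols.extend(f"{m}__{name}" for name in self.feature_names[m])
        return cols

    def wide_features(self, subset: Iterable[str] | None = None) -> pd.DataFrame:
        """Pivot observations to one row per (participant, time_unit).

        Missing cells are NaN.  Rows appear for every (participant, week)
        combination on the panel axes so callers can align by slot.
        """
        subset = list(subset) if subset is not None else self.modalities
        f = self.features[self.features["modality"].isin(subset)].copy()
        f["column"] = f["modality"].astype(str) + "__" + f["feature"].astype(str)
        wide = f.pivot(index=["participant", "time_unit"], columns="column", values="value")
        full_index = pd.MultiIndex.from_product(
            [self.participants, self.time_units], names=["participant", "time_unit"]
        )
        wide = wide.reindex(index=full_index, columns=self.all_feature_columns(subset))
        return wide

    def score_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, observed-mask) arrays of shape (P, T)."""
        p_idx = {p: i for i, p in enumerate(self.participants)}
        t_idx = {t: j for j, t in enumerate(self.time_units)}
        scores = np.full((len(self.participants), len(self.time_units)), np.nan)
        for row in self.ground_truth.itertuples(index=False):
            scores[p_idx[row.participant], t_idx[row.time_unit]] = row.score
        return scores, ~np.isnan(scores)


@dataclass
class ChangeSeries:
    """Per-participant week-over-week change scores ``W_m - W_{m-1}``.

    A participant with n scored weeks arranged in maximal consecutive runs
    contributes (run length - 1) changes per run; changes are never taken
    across gaps.
    """

    changes: dict[str, list[tuple[int, int]]]

    def n_targets(self) -> int:
        return sum(len(v) for v in self.changes.values())

    def to_matrix(
        self, participants: list[str], time_units: list[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(change values, target mask) of shape (P, T); NaN off-mask."""
        p_idx = {p: i for i, p in enumerate(participants)}
        t_idx = {t: j for j, t in enumerate(time_units)}
        values = np.full((len(participants), len(time_units)), np.nan)
        for p, pairs in self.changes.items():
            for t, delta in pairs:
                values[p_idx[p], t_idx[t]] = delta
        return values, ~np.isnan(values)


def compute_change_scores(dataset: PanelDataset) -> ChangeSeries:
    """Difference consecutive weekly scores into the regression target.

    The change at week ``m`` exists only when weeks ``m`` and ``m-1`` were
    both scored; gaps in the ground truth produce no change (a multi-week
    difference is not a weekly change).
    """
    changes: dict[str, list[tuple[int, int]]] = {}
    for p in dataset.participants:
        rows = dataset.ground_truth[dataset.ground_truth["participant"] == p]
        rows = rows.sort_values("time_unit")
        weeks = rows["time_unit"].to_numpy()
        scores = rows["score"].to_numpy()
        out: list[tuple[int, int]] = []
        for i in range(1, len(weeks)):
            if weeks[i] - weeks[i - 1] == 1:
                out.append((int(weeks[i]), int(scores[i] - scores[i - 1])))
        changes[p] = out
    if sum(len(v) for v in changes.values()) == 0:
        raise PanelValidationError("no modellable targets")
    return ChangeSeries(changes=changes)


# -- CSV I/O ---------------------------------------------------------------


def read_panel(
    features_path: str | Path,
    ground_truth_path: str | Path,
    modalities: list[str] | None = None,
) -> PanelDataset:
    """Load the two tidy CSVs into a validated :class:`PanelDataset`.

    Participant and modality order follow first appearance in the feature
    file; weeks are sorted ascending.  Passing ``modalities`` restricts and
    orders the modality axis; rows with other modalities are rejected.
    """
    try:
        features = pd.read_csv(features_path)
        truth = pd.read_csv(ground_truth_path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PanelParseError(str(exc)) from exc

    for col in ("time_unit",):
        for df, name in ((features, "features"), (truth, "ground truth")):
            if col in df.columns:
                try:
                    df[col] = df[col].astype(int)
                except (TypeError, ValueError) as exc:
                    raise PanelParseError(
                        f"non-integer {col} in {name} table"
                    ) from exc
    if features.empty:
        raise PanelValidationError("no observations")
    if "value" in features.columns:
        try:
            features["value"] = features["value"].astype(float)
        except (TypeError, ValueError) as exc:
            raise PanelParseError("non-numeric feature value") from exc

    participants = _ordered_unique(features["participant"].astype(str))
    features["participant"] = features["participant"].astype(str)
    truth["participant"] = truth["participant"].astype(str)
    extra = _ordered_unique(
        p for p in truth["participant"] if p not in set(participants)
    )
    participants += extra
    time_units = sorted(
        set(features["time_unit"]).union(truth["time_unit"] if not truth.empty else [])
    )
    if modalities is None:
        modalities = _ordered_unique(features["modality"])
    return PanelDataset(
        participants=participants,
        time_units=[int(t) for t in time_units],
        modalities=list(modalities),
        features=features,
        ground_truth=truth,
    )


def write_panel(
    dataset: PanelDataset, features_path: str | Path, ground_truth_path: str | Path
) -> None:
    """Write the panel back to the two tidy CSVs (inverse of read_panel)."""
    dataset.features.to_csv(features_path, index=False, columns=FEATURE_COLUMNS)
    dataset.ground_truth.to_csv(ground_truth_path, index=False, columns=TRUTH_COLUMNS)


def write_report(result, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a run's predictions CSV and JSON summary.

    ``result`` is the ensemble output of a framework run (see
    :mod:`flms.pipeline`).  The CSV holds one row per predicted slot with
    each strategy's encoded contribution, the fused fractional value and
    the final 0/1 call; the JSON holds weights, the hamming-distance table
    and metric summaries.  Output is byte-stable for a fixed seed.
    """
    import json

    if getattr(result, "final", None) is None:
        raise PanelValidationError("incomplete result: no final tensor")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    strategies = list(result.weights)
    for i, p in enumerate(result.participants):
        for j, t in enumerate(result.time_units):
            if not result.mask[i, j]:
                continue
            row: dict = {"participant": p, "time_unit": t}
            for s in strategies:
                enc, mask = result.strategy_layers[s]
                row[f"{s}_encoded"] = int(enc[i, j]) if mask[i, j] else ""
            row["fused"] = float(np.round(result.fused[i, j], 10))
            row["final"] = int(result.final[i, j])
            row["truth"] = int(result.truth[i, j]) if result.truth_mask[i, j] else ""
            rows.append(row)
    pred_path = out_dir / "predictions.csv"
    pd.DataFrame(rows).to_csv(pred_path, index=False)

    summary = {
        "weights": {s: float(np.round(w, 12)) for s, w in result.weights.items()},
        "min_hamming": {s: int(d) for s, d in result.min_hamming.items()},
        "chosen_scope": {s: str(c) for s, c in result.chosen_scope.items()},
        "hamming_table": result.hamming_table,
        "metrics": result.metrics,
        "seed": result.seed,
    }
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return pred_path, json_path
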