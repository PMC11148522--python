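"""Stage 2: cross-validation strategies and the pluggable regression suite.

Four strategies span the user-agnostic/personalized axis:

* LOPO  — leave one participant out (cold start for a new user);
* LTXO  — leave one time unit out across all participants;
* ATU   — per-participant expanding-window forecasting of the next unit;
* LOTPO — per-participant leave-one-unit-out using past *and* future units.

Every (strategy, fusion set, algorithm) run fills a participants x weeks
prediction matrix; per participant the algorithm with the lowest absolute
sum error over that participant's held-out slots is retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import PanelValidationError

logger = logging.getLogger(__name__)

Slot = tuple[int, int]  # (participant index, time-unit index)


@dataclass
class SplitPlan:
    """An ordered list of disjoint (train slots, predict slots) pairs."""

    strategy: str
    splits: list[tuple[list[Slot], list[Slot]]]
    params: dict = field(default_factory=dict)

    def predicted_slots(self) -> list[Slot]:
        out: list[Slot] = []
        for _, predict in self.splits:
            out.extend(predict)
        return out


@dataclass
class PredictionCube:
    """Participants x weeks predictions for one (strategy, fusion) pair."""

    strategy: str
    fusion: tuple[str, ...] | str
    pred: np.ndarray
    mask: np.ndarray
    best_alg: dict[int, str] | None = None
    algorithm: str | None = None

    def __post_init__(self) -> None:
        if self.pred.shape != self.mask.shape:
            raise PanelValidationError("prediction/mask shape mismatch")


def _slots_of(mask: np.ndarray) -> list[Slot]:
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]


# -- split planning --------------------------------------------------------


def plan_lopo(target_mask: np.ndarray) -> SplitPlan:
    """One split per participant: hold out all of their target slots."""
    rows_with_targets = np.nonzero(target_mask.any(axis=1))[0]
    if len(rows_with_targets) < 2:
        raise PanelValidationError("LOPO requires >=2 participants with targets")
    splits = []
    for i in rows_with_targets:
        predict = _slots_of(np.isin(np.arange(target_mask.shape[0]), [i])[:, None] & target_mask)
        train = _slots_of((~np.isin(np.arange(target_mask.shape[0]), [i]))[:, None] & target_mask)
        splits.append((train, predict))
    return SplitPlan(strategy="LOPO", splits=splits)


def plan_ltxo(target_mask: np.ndarray) -> SplitPlan:
    """One split per time unit: hold out that unit for all participants."""
    cols_with_targets = np.nonzero(target_mask.any(axis=0))[0]
    if len(cols_with_targets) < 2:
        raise PanelValidationError("LTXO requires >=2 time units with targets")
    splits = []
    for j in cols_with_targets:
        col_sel = np.isin(np.arange(target_mask.shape[1]), [j])[None, :]
        predict = _slots_of(col_sel & target_mask)
        train = _slots_of(~col_sel & target_mask)
        splits.append((train, predict))
    return SplitPlan(strategy="LTXO", splits=splits)


def plan_atu(
    target_mask: np.ndarray, time_units: list[int], w0: int = 2, step: int = 1
) -> SplitPlan:
    """Per-participant expanding-window forecasting.

    A window of the first ``w0`` time units predicts unit ``w0 + 1``; the
    window then grows by ``step`` units and the process repeats until the
    participant's units are exhausted.  Training slots always strictly
    precede the predicted unit, so the strategy never sees the future.
    """
    if w0 < 1 or step < 1:
        raise PanelValidationError("w0 and step must be >= 1")
    time_units = list(time_units)
    t_of = np.asarray(time_units)
    splits = []
    for i in range(target_mask.shape[0]):
        cols = np.nonzero(target_mask[i])[0]
        if len(cols) == 0:
            continue
        times = t_of[cols]
        t = w0
        emitted = False
        while t + 1 <= times.max():
            target_time = t + 1
            predict = [
                (i, int(j)) for j in cols if time_units[j] == target_time
            ]
            train = [(i, int(j)) for j in cols if time_units[j] <= t]
            if predict and train:
                splits.append((train, predict))
                emitted = True
            t += step
        if not emitted:
            logger.warning("participant row %d produced no ATU windows", i)
    return SplitPlan(strategy="ATU", splits=splits, params={"w0": w0, "step": step})


def plan_lotpo(target_mask: np.ndarray, min_units: int = 3) -> SplitPlan:
    """Per-participant leave-one-unit-out over past and future units."""
    if min_units < 2:
        raise PanelValidationError("min_units must be >= 2")
    splits = []
    for i in range(target_mask.shape[0]):
        cols = np.nonzero(target_mask[i])[0]
        if len(cols) < min_units:
            if len(cols) > 0:
                logger.warning(
                    "participant row %d has %d target units (< %d); skipped by LOTPO",
                    i, len(cols), min_units,
                )
            continue
        for j in cols:
            predict = [(i, int(j))]
            train = [(i, int(c)) for c in cols if c != j]
            splits.append((train, predict))
    return SplitPlan(strategy="LOTPO", splits=splits, params={"min_units": min_units})


def build_plans(target_mask, time_units, config) -> dict[str, SplitPlan]:
    """All split plans requested by ``config.strategies``."""
    out: dict[str, SplitPlan] = {}
    for s in config.strategies:
        if s == "LOPO":
            out[s] = plan_lopo(target_mask)
        elif s == "LTXO":
            out[s] = plan_ltxo(target_mask)
        elif s == "ATU":
            out[s] = plan_atu(target_mask, time_units, config.atu_w0, config.atu_step)
        elif s == "LOTPO":
            out[s] = plan_lotpo(target_mask, config.lotpo_min_units)
    return out


# -- regression suite ------------------------------------------------------


class _OLS:
    """Least-squares linear regression via numpy (minimal-overhead path)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        A = np.hstack([np.ones((X.shape[0], 1)), X])
        self.coef_, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        A = np.hstack([np.ones((X.shape[0], 1)), X])
        return A @ self.coef_


class _Ridge:
    """Closed-form ridge regression with unpenalized intercept."""

    def __init__(self, alpha: float = 1.0) -> None:
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        G = Xc.T @ Xc + self.alpha * np.eye(X.shape[1])
        self.coef_ = np.linalg.solve(G, Xc.T @ (y - self.y_mean_))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


class _MeanPredictor:
    """Predicts the training-target mean; the degenerate baseline."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


def make_estimator(name: str, seed: int):
    """Instantiate a suite member by name with a fixed random state."""
    seed = int(seed) % (2**31 - 1)
    if name == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression()
    if name == "elastic_net":
        from sklearn.linear_model import ElasticNet

        return ElasticNet(random_state=seed)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=100, random_state=seed)
    if name == "adaboost":
        from sklearn.ensemble import AdaBoostRegressor

        return AdaBoostRegressor(random_state=seed)
    if name == "extra_trees":
        from sklearn.ensemble import ExtraTreesRegressor

        return ExtraTreesRegressor(n_estimators=100, random_state=seed)
    if name == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingRegressor

        return GradientBoostingRegressor(random_state=seed)
    if name == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=100, random_state=seed, verbosity=0, n_jobs=1
        )
    if name == "ols":
        return _OLS()
    if name == "ridge":
        return _Ridge(alpha=1.0)
    if name == "mean":
        return _MeanPredictor()
    raise PanelValidationError(f"unknown algorithm: {name}")


# -- fitting ---------------------------------------------------------------


def fit_predict_suite(
    plan: SplitPlan,
    matrix: pd.DataFrame,
    slots: list[tuple[str, int]],
    slot_of: dict[Slot, int],
    target_values: np.ndarray,
    suite: tuple[str, ...],
    seed: int,
    preprocessor_factory=None,
    X_global: np.ndarray | None = None,
    fusion_id: tuple[str, ...] | str = "",
) -> dict[str, PredictionCube]:
    """Run every suite member over every split of a plan.

    ``matrix`` rows align 1:1 with ``slots``; ``slot_of`` maps a (participant
    index, time index) slot to its row.  With ``X_global`` set, stage-1
    preprocessing has already been applied to the whole fusion set (the
    reference pipeline's order); otherwise ``preprocessor_factory`` builds a
    fresh preprocessor per split, fitted on the training rows only.
    """
    if X_global is None and preprocessor_factory is None:
        raise PanelValidationError("need X_global or a preprocessor_factory")
    shape = target_values.shape
    cubes = {
        name: PredictionCube(
            strategy=plan.strategy,
            fusion=fusion_id,
            pred=np.full(shape, np.nan),
            mask=np.zeros(shape, dtype=bool),
            algorithm=name,
        )
        for name in suite
    }
    for train, predict in plan.splits:
        if len(train) == 0:
            logger.warning("degenerate training fold (0 rows); slots left unmasked")
            continue
        tr_rows = [slot_of[s] for s in train]
        te_rows = [slot_of[s] for s in predict]
        y_tr = np.array([target_values[s] for s in train], dtype=float)
        if X_global is not None:
            X_tr = X_global[tr_rows]
            X_te = X_global[te_rows]
        else:
            prep = preprocessor_factory()
            X_tr = prep.fit_transform(matrix.iloc[tr_rows])
            X_te = prep.transform(matrix.iloc[te_rows])
        for name in suite:
            est = make_estimator(name, seed)
            est.fit(X_tr, y_tr)
            y_hat = np.asarray(est.predict(X_te), dtype=float)
            cube = cubes[name]
            for slot, value in zip(predict, y_hat):
                cube.pred[slot] = value
                cube.mask[slot] = True
    return cubes


def select_best_model(
    cubes: dict[str, PredictionCube],
    target_values: np.ndarray,
    suite_order: tuple[str, ...] | None = None,
    honest: bool = False,
    mode: str = "regression",
) -> PredictionCube:
    """Per participant, keep the algorithm with the lowest absolute sum error.

    Error is summed over the participant's held-out slots across all splits
    of the strategy; ties break by suite order.  ``honest=True`` scores
    algorithms on only the first (chronological) half of each participant's
    held-out slots, limiting how much test label information enters
    selection.  ``mode="classification"`` flips the criterion to maximum
    0/1-encoded accuracy.
    """
    if not cubes:
        raise PanelValidationError("no cubes to select from")
    order = [n for n in (suite_order or cubes.keys()) if n in cubes]
    first = cubes[order[0]]
    out = PredictionCube(
        strategy=first.strategy,
        fusion=first.fusion,
        pred=np.full(first.pred.shape, np.nan),
        mask=np.zeros(first.pred.shape, dtype=bool),
        best_alg={},
    )
    n_participants = first.pred.shape[0]
    for i in range(n_participants):
        best_name, best_err = None, math.inf
        for name in order:
            cube = cubes[name]
            cols = np.nonzero(cube.mask[i])[0]
            if len(cols) == 0:
                continue
            score_cols = cols[: max(1, (len(cols) + 1) // 2)] if honest else cols
            diffs = cube.pred[i, score_cols] - target_values[i, score_cols]
            if mode == "classification":
                err = float(
                    np.mean(
                        (cube.pred[i, score_cols] > 0).astype(int)
                        != (target_values[i, score_cols] > 0).astype(int)
                    )
                )
            else:
                err = float(np.abs(diffs).sum())
            if err < best_err - 1e-15:
                best_name, best_err = name, err
        if best_name is None:
            continue
        winner = cubes[best_name]
        out.pred[i] = winner.pred[i]
        out.mask[i] = winner.mask[i]
        out.best_alg[i] = best_name
    return out
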