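"""Stages 3-4: tensor aggregation, 0/1 encoding, hamming ranking, ensemble.

Regression outputs carry large variance relative to the week-over-week
change they target, so predictions are encoded to direction only: 1 for an
increase in the symptom score, 0 for no change or a decrease.  Candidate
prediction tensors are ranked by their aggregated hamming distance to the
encoded truth; the minimum distance per cross-validation strategy sets
that strategy's weight in the final ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import PanelValidationError
from .modeling import PredictionCube


def encode_change(values):
    """Encode a regressed change: 0 if the change is <= 0, else 1."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise PanelValidationError("cannot encode non-finite value")
    encoded = (arr > 0).astype(int)
    return encoded if arr.shape else int(encoded)


def encode_cube(cube: PredictionCube) -> tuple[np.ndarray, np.ndarray]:
    """0/1-encode a cube's masked predictions; off-mask slots encode as 0."""
    pred = np.where(cube.mask, cube.pred, 0.0)
    if not np.isfinite(pred).all():
        raise PanelValidationError("cannot encode non-finite prediction")
    return (pred > 0).astype(int), cube.mask.copy()


def hamming_distance(
    encoded: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> int:
    """Count masked slots where the encoded prediction disagrees with truth."""
    encoded = np.asarray(encoded)
    truth = np.asarray(truth)
    if encoded.shape != truth.shape:
        raise PanelValidationError("shape mismatch in hamming distance")
    if mask is None:
        mask = np.ones(encoded.shape, dtype=bool)
    if mask.shape != encoded.shape:
        raise PanelValidationError("mask shape mismatch in hamming distance")
    return int(np.sum((encoded != truth) & mask))


def aggregate_mean(cubes: list[PredictionCube]) -> PredictionCube:
    """Slot-wise mean across cubes of a common strategy (Fig.-6-style).

    A slot's value is the mean over the cubes that predicted it; the output
    mask is the union of input masks.
    """
    if not cubes:
        raise PanelValidationError("no cubes to aggregate")
    strategy = cubes[0].strategy
    shape = cubes[0].pred.shape
    for c in cubes:
        if c.pred.shape != shape:
            raise PanelValidationError("axis mismatch across cubes")
        if c.strategy != strategy:
            raise PanelValidationError("cannot aggregate across strategies")
    masks = np.stack([c.mask for c in cubes])
    mask = masks.any(axis=0)
    counts = masks.sum(axis=0)
    sums = np.stack([np.where(c.mask, c.pred, 0.0) for c in cubes]).sum(axis=0)
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return PredictionCube(
        strategy=strategy,
        fusion=f"mean_of_{len(cubes)}",
        pred=np.where(mask, mean, np.nan),
        mask=mask,
    )


@dataclass
class RankRecord:
    """A candidate tensor's identity and its aggregated hamming distance."""

    strategy: str
    scope: str
    cardinality: int
    encoded: np.ndarray
    mask: np.ndarray
    distance: int
    raw: np.ndarray | None = None
    chosen: bool = False

    def __post_init__(self) -> None:
        n_masked = int(self.mask.sum())
        if not 0 <= self.distance <= n_masked:
            raise PanelValidationError("distance outside [0, masked slots]")


def make_record(
    cube: PredictionCube, truth: np.ndarray, scope: str, cardinality: int
) -> RankRecord:
    encoded, mask = encode_cube(cube)
    return RankRecord(
        strategy=cube.strategy,
        scope=scope,
        cardinality=cardinality,
        encoded=encoded,
        mask=mask,
        distance=hamming_distance(encoded, truth, mask),
        raw=np.where(mask, cube.pred, np.nan),
    )


def rank_candidates(records: list[RankRecord]) -> list[RankRecord]:
    """Sort ascending by distance; ties prefer fewer sensors, then name.

    Per strategy, the minimum-distance record is flagged chosen.
    """
    ranked = sorted(records, key=lambda r: (r.distance, r.cardinality, r.scope))
    seen: set[str] = set()
    for r in ranked:
        r.chosen = False
    for r in ranked:
        if r.strategy not in seen:
            r.chosen = True
            seen.add(r.strategy)
    return ranked


def compute_weights(
    min_distances: dict[str, int],
    epsilon: float = 1e-9,
    scheme: str = "inverse",
) -> dict[str, float]:
    """Strategy weights from minimum hamming distances.

    ``inverse``: w_k proportional to 1/(D_k + eps) — strictly decreasing in
    D_k and summing to 1.  ``softmax_neg_distance``: softmax over -D_k
    (shifted by min(D) for numerical stability).
    """
    if not min_distances:
        raise PanelValidationError("no distances")
    dists = np.array([min_distances[k] for k in min_distances], dtype=float)
    if (dists < 0).any():
        raise PanelValidationError("negative hamming distance")
    if scheme == "inverse":
        raw = 1.0 / (dists + epsilon)
    elif scheme == "softmax_neg_distance":
        raw = np.exp(-(dists - dists.min()))
    else:
        raise PanelValidationError(f"unknown weighting scheme: {scheme}")
    weights = raw / raw.sum()
    return {k: float(w) for k, w in zip(min_distances, weights)}


@dataclass
class EnsembleResult:
    """Final weighted-ensemble output over the panel's slot grid."""

    weights: dict[str, float]
    fused: np.ndarray
    final: np.ndarray
    mask: np.ndarray
    strategy_layers: dict[str, tuple[np.ndarray, np.ndarray]]
    tie_rule: str
    min_hamming: dict[str, int] = field(default_factory=dict)
    chosen_scope: dict[str, str] = field(default_factory=dict)


def weighted_ensemble(
    layers: dict[str, tuple[np.ndarray, np.ndarray]],
    weights: dict[str, float],
    tie_rule: str = "half_up",
    encode_output: bool = True,
) -> EnsembleResult:
    """Fuse per-strategy encoded tensors with hamming-derived weights.

    Each slot's fused value is the weight-renormalized combination of the
    strategies that cover it (strategies differ in coverage: the
    forecasting strategy has no predictions inside its initial window).
    The fused fraction re-encodes to 1 when >= 0.5 under ``half_up`` (or
    strictly > 0.5 under ``half_down``).
    """
    if not layers:
        raise PanelValidationError("no strategy layers")
    names = list(layers)
    total = sum(weights[n] for n in names)
    if not np.isclose(total, 1.0, atol=1e-9):
        raise PanelValidationError("weights must be normalized")
    shape = next(iter(layers.values()))[0].shape
    num = np.zeros(shape)
    den = np.zeros(shape)
    for n in names:
        enc, mask = layers[n]
        if enc.shape != shape or mask.shape != shape:
            raise PanelValidationError("layer shape mismatch")
        num += weights[n] * np.where(mask, enc, 0.0)
        den += weights[n] * mask
    covered = den > 0
    fused = np.where(covered, num / np.where(covered, den, 1.0), np.nan)
    if encode_output:
        if tie_rule == "half_up":
            final = np.where(covered, (fused >= 0.5).astype(int), 0)
        else:
            final = np.where(covered, (fused > 0.5).astype(int), 0)
    else:
        final = np.where(covered, (fused > 0).astype(int), 0)
    return EnsembleResult(
        weights=dict(weights),
        fused=fused,
        final=final,
        mask=covered,
        strategy_layers={n: (layers[n][0].copy(), layers[n][1].copy()) for n in names},
        tie_rule=tie_rule,
    )
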