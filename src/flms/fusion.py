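"""Stage 1: combinatorial sensor fusion and per-fusion-set preprocessing.

With Z modalities the framework enumerates all 2^Z - 1 nonempty subsets and
builds one modeling dataset per subset: the wide feature matrix restricted
to the subset's columns, KNN-imputed, optionally log-transformed,
z-scored, and pruned of highly correlated columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.preprocessing import StandardScaler

from .datamodel import PanelDataset, PanelValidationError

logger = logging.getLogger(__name__)


def enumerate_fusions(modalities: Sequence[str]) -> list[tuple[str, ...]]:
    """All nonempty modality subsets, by cardinality then input order.

    Six modalities yield the framework's 63 fusion datasets.
    """
    modalities = list(modalities)
    if len(modalities) == 0:
        raise PanelValidationError("no modalities")
    out: list[tuple[str, ...]] = []
    for x in range(1, len(modalities) + 1):
        out.extend(combinations(modalities, x))
    return out


@dataclass
class FusionSet:
    """One fused modeling dataset: a modality subset and its feature matrix.

    ``matrix`` rows align 1:1 with the pipeline's target slots (participant,
    week pairs carrying a change score); missing cells are NaN until
    preprocessing imputes them.
    """

    subset: tuple[str, ...]
    matrix: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subset) == 0:
            raise PanelValidationError("fusion subset must be nonempty")
        if not self.feature_names:
            self.feature_names = list(self.matrix.columns)

    @property
    def cardinality(self) -> int:
        return len(self.subset)


def build_fusion_set(
    dataset: PanelDataset,
    subset: Sequence[str],
    slots: Sequence[tuple[str, int]],
    wide: pd.DataFrame | None = None,
) -> FusionSet:
    """Assemble the raw (unpreprocessed) matrix for one modality subset.

    ``slots`` are the (participant, week) pairs with a change-score target;
    passing a precomputed full ``wide`` table avoids re-pivoting per subset.
    """
    subset = tuple(subset)
    unknown = set(subset) - set(dataset.modalities)
    if unknown:
        raise PanelValidationError(f"unknown modalities in subset: {sorted(unknown)}")
    if wide is None:
        wide = dataset.wide_features()
    cols = dataset.all_feature_columns(subset)
    index = pd.MultiIndex.from_tuples(slots, names=["participant", "time_unit"])
    matrix = wide.loc[index, cols]
    return FusionSet(subset=subset, matrix=matrix)


def impute_missing(matrix: pd.DataFrame | np.ndarray, k: int = 5):
    """KNN-impute absent cells (Euclidean distance on mutually present features).

    Identity on complete input; a feature absent in every row is an error
    because no neighbourhood can inform it.
    """
    if k < 1:
        raise PanelValidationError("k must be >= 1")
    values = np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise PanelValidationError("empty matrix")
    if not np.isnan(values).any():
        return matrix
    all_nan = np.isnan(values).all(axis=0)
    if all_nan.any():
        if isinstance(matrix, pd.DataFrame):
            name = matrix.columns[int(np.argmax(all_nan))]
        else:
            name = f"column {int(np.argmax(all_nan))}"
        raise PanelValidationError(f"feature absent everywhere: {name}")
    imputed = KNNImputer(n_neighbors=min(k, values.shape[0])).fit_transform(values)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(imputed, index=matrix.index, columns=matrix.columns)
    return imputed


def _signed_log1p(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.log1p(np.abs(values))


class Preprocessor:
    """Fold-safe stage-1 preprocessing: log -> impute -> prune -> z-score.

    Fitted on training rows only; ``transform`` never touches statistics of
    the rows it is applied to, so held-out rows cannot leak into the fit.
    Zero-variance and (within the fitting rows) all-absent features are
    dropped with a warning; of any pair with |r| above ``corr_threshold``
    the first column in deterministic order is kept.
    """

    def __init__(
        self,
        impute_k: int = 5,
        corr_threshold: float = 0.9,
        log_features: Iterable[str] = (),
    ) -> None:
        self.impute_k = impute_k
        self.corr_threshold = corr_threshold
        self.log_features = tuple(log_features)
        self.columns_: list[str] | None = None
        self.kept_: list[str] | None = None

    def _log(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.log_features:
            return X
        X = X.copy()
        for col in self.log_features:
            if col in X.columns:
                X[col] = _signed_log1p(X[col].to_numpy(dtype=float))
        return X

    def fit(self, X: pd.DataFrame) -> "Preprocessor":
        if X.shape[0] == 0:
            raise PanelValidationError("cannot fit preprocessor on 0 rows")
        self.columns_ = list(X.columns)
        X = self._log(X)
        values = X.to_numpy(dtype=float)

        usable = ~np.isnan(values).all(axis=0)
        if not usable.any():
            raise PanelValidationError("no usable features: all columns absent")
        dropped = [c for c, u in zip(self.columns_, usable) if not u]
        if dropped:
            logger.warning("dropping all-absent features in fold: %s", dropped)
        cols = [c for c, u in zip(self.columns_, usable) if u]
        values = values[:, usable]

        self._imputer = KNNImputer(
            n_neighbors=min(self.impute_k, max(1, values.shape[0] - 1))
        )
        values = self._imputer.fit_transform(values)
        self._imputer_columns = cols

        variances = values.var(axis=0)
        keep = variances > 0
        dropped = [c for c, k in zip(cols, keep) if not k]
        if dropped:
            logger.warning("dropping zero-variance features: %s", dropped)
        cols = [c for c, k in zip(cols, keep) if k]
        values = values[:, keep]
        if values.shape[1] == 0:
            raise PanelValidationError("no usable features after variance pruning")

        if values.shape[0] > 2 and values.shape[1] > 1:
            corr = np.corrcoef(values, rowvar=False)
            corr = np.abs(np.nan_to_num(corr, nan=0.0))
            kept_idx: list[int] = []
            for j in range(len(cols)):
                if all(corr[j, i] <= self.corr_threshold for i in kept_idx):
                    kept_idx.append(j)
        else:
            kept_idx = list(range(len(cols)))
        self.kept_ = [cols[j] for j in kept_idx]
        values = values[:, kept_idx]

        self._scaler = StandardScaler().fit(values)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if self.kept_ is None:
            raise RuntimeError("Preprocessor not fitted")
        X = self._log(X[self.columns_])
        values = X[self._imputer_columns].to_numpy(dtype=float)
        values = self._imputer.transform(values)
        frame = pd.DataFrame(values, columns=self._imputer_columns)
        return self._scaler.transform(frame[self.kept_].to_numpy(dtype=float))

    def fit_transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)


def preprocess(fusion: FusionSet, config) -> FusionSet:
    """Fit-and-apply preprocessing to a whole fusion set (global mode)."""
    prep = Preprocessor(
        impute_k=config.impute_k,
        corr_threshold=config.corr_threshold,
        log_features=config.log_features,
    )
    values = prep.fit_transform(fusion.matrix)
    matrix = pd.DataFrame(values, index=fusion.matrix.index, columns=prep.kept_)
    return FusionSet(
        subset=fusion.subset,
        matrix=matrix,
        provenance={
            "impute_k": config.impute_k,
            "corr_threshold": config.corr_threshold,
            "log_features": list(config.log_features),
            "dropped": [c for c in fusion.matrix.columns if c not in prep.kept_],
        },
    )


def exclude_sparse_participants(
    dataset: PanelDataset, max_missing: float = 0.6
) -> PanelDataset:
    """Drop participants missing more than ``max_missing`` of their sensor data.

    Missingness is the NaN fraction of a participant's wide feature rows over
    their scored weeks.
    """
    wide = dataset.wide_features()
    keep: list[str] = []
    for p in dataset.participants:
        scored = dataset.ground_truth.loc[
            dataset.ground_truth["participant"] == p, "time_unit"
        ]
        if scored.empty:
            continue
        rows = wide.loc[[(p, int(t)) for t in scored]]
        frac = float(np.isnan(rows.to_numpy(dtype=float)).mean())
        if frac <= max_missing:
            keep.append(p)
    if not keep:
        raise PanelValidationError("all participants excluded by missingness rule")
    if keep == dataset.participants:
        return dataset
    return PanelDataset(
        participants=keep,
        time_units=dataset.time_units,
        modalities=dataset.modalities,
        features=dataset.features[dataset.features["participant"].isin(keep)],
        ground_truth=dataset.ground_truth[
            dataset.ground_truth["participant"].isin(keep)
        ],
        feature_names=dataset.feature_names,
    )
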