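"""Per-user binary metrics, the sparsity statistic, and experiment harnesses.

The framework's final output is a 0/1 tensor (1 = the symptom score rose
that week), so evaluation reports per-user accuracy, recall and F1 with
their mean and SD across users.  Recall and F1 are defined as 0 (and
counted) for users whose covered weeks contain no positive truth — the
aggregation convention is stated rather than inherited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PanelDataset, PanelValidationError


@dataclass
class MetricSummary:
    """Per-user metric table plus across-user mean/SD (sample SD, ddof=1)."""

    per_user: pd.DataFrame
    identity: str = ""
    n_excluded: int = 0

    def mean_sd(self, metric: str) -> tuple[float, float]:
        col = self.per_user[metric]
        sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        return float(col.mean()), sd

    def to_dict(self) -> dict:
        out: dict = {"identity": self.identity, "n_users": int(len(self.per_user)),
                     "n_excluded": int(self.n_excluded)}
        for metric in ("accuracy", "recall", "f1"):
            mean, sd = self.mean_sd(metric)
            out[f"{metric}_mean"] = round(mean, 10)
            out[f"{metric}_sd"] = round(sd, 10)
        return out


def per_user_metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray,
    participants: list[str] | None = None,
    identity: str = "",
) -> MetricSummary:
    """Accuracy, recall and F1 per user over the masked slots.

    Positive class is 1 (an increase in the symptom score).  Users with no
    masked predictions are excluded and counted.
    """
    pred, truth, mask = (np.asarray(a) for a in (pred, truth, mask))
    if not pred.shape == truth.shape == mask.shape:
        raise PanelValidationError("pred/truth/mask shape mismatch")
    if participants is None:
        participants = [f"row{i}" for i in range(pred.shape[0])]
    rows, excluded = [], 0
    for i, p in enumerate(participants):
        sel = mask[i]
        n = int(sel.sum())
        if n == 0:
            excluded += 1
            continue
        yp = pred[i, sel].astype(int)
        yt = truth[i, sel].astype(int)
        tp = int(((yp == 1) & (yt == 1)).sum())
        fn = int(((yp == 0) & (yt == 1)).sum())
        fp = int(((yp == 1) & (yt == 0)).sum())
        accuracy = float((yp == yt).mean())
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        rows.append(
            {"participant": p, "n": n, "accuracy": accuracy,
             "recall": recall, "f1": f1}
        )
    if not rows:
        raise PanelValidationError("no users with predictions")
    return MetricSummary(
        per_user=pd.DataFrame(rows), identity=identity, n_excluded=excluded
    )


def sparsity(matrix) -> float:
    """Fraction of exact-zero entries; absent (NaN) cells excluded entirely."""
    values = np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise PanelValidationError("empty matrix")
    present = ~np.isnan(values)
    n_present = int(present.sum())
    if n_present == 0:
        raise PanelValidationError("matrix has no present entries")
    return float((values[present] == 0.0).sum() / n_present)


# -- experiment harnesses --------------------------------------------------


def run_experiment1(dataset: PanelDataset, config=None) -> dict:
    """Framework vs singular strategies on one panel (comparison table).

    Returns ``summary`` (per-candidate metric means/SDs), ``hamming``
    (per-strategy minimum distance and best fusion scope) and the full
    pipeline ``result``.
    """
    from .pipeline import harness_config, run_flms

    config = config or harness_config()
    result = run_flms(dataset, config)
    summary_rows = []
    for name in ["FLMS", *result.weights]:
        m = dict(result.metrics[name])
        m["candidate"] = name
        summary_rows.append(m)
    summary = pd.DataFrame(summary_rows).set_index("candidate")
    hamming = pd.DataFrame(
        [
            {
                "strategy": s,
                "min_hamming": result.min_hamming[s],
                "best_fusion": result.chosen_scope[s],
            }
            for s in result.weights
        ]
    ).set_index("strategy")
    return {"summary": summary, "hamming": hamming, "result": result}


_BASELINES = ("majority", "knn", "decision_tree", "random_forest", "xgboost")


def _make_baseline(name: str, seed: int):
    seed = int(seed) % (2**31 - 1)
    if name == "majority":
        from sklearn.dummy import DummyClassifier

        return DummyClassifier(strategy="most_frequent")
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier()
    if name == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, random_state=seed, verbosity=0, n_jobs=1)
    raise PanelValidationError(f"unknown baseline: {name}")


def run_baselines(
    dataset: PanelDataset,
    config=None,
    baselines: tuple[str, ...] = _BASELINES,
    flms_result=None,
) -> pd.DataFrame:
    """Leave-one-participant-out classical classifiers on encoded targets.

    Each baseline is fitted per fold on the 0/1-encoded change labels of
    the full-modality fusion set and reports per-user test metrics plus a
    train-vs-test accuracy gap (overfitting diagnostic).  When a framework
    ``flms_result`` is supplied, its metrics head the table; its gap is 0
    by construction because every framework prediction is out-of-fold.
    """
    from .datamodel import compute_change_scores
    from .fusion import Preprocessor, build_fusion_set
    from .modeling import plan_lopo
    from .pipeline import harness_config
    from .synthetic import ground_truth_encoding

    config = config or harness_config()
    changes = compute_change_scores(dataset)
    target_values, target_mask = changes.to_matrix(
        dataset.participants, dataset.time_units
    )
    truth, _ = ground_truth_encoding(dataset, changes)
    slots = [
        (dataset.participants[i], dataset.time_units[j])
        for i, j in zip(*np.nonzero(target_mask))
    ]
    slot_of = {
        (int(i), int(j)): r for r, (i, j) in enumerate(zip(*np.nonzero(target_mask)))
    }
    fs = build_fusion_set(dataset, dataset.modalities, slots)
    X = Preprocessor(
        impute_k=config.impute_k,
        corr_threshold=config.corr_threshold,
        log_features=config.log_features,
    ).fit_transform(fs.matrix)
    y = truth[target_mask].astype(int)

    plan = plan_lopo(target_mask)
    rows = []
    if flms_result is not None:
        m = dict(flms_result.metrics["FLMS"])
        m.update({"candidate": "FLMS", "train_accuracy": m["accuracy_mean"],
                  "train_test_gap": 0.0})
        rows.append(m)
    for name in baselines:
        pred = np.zeros(target_mask.shape, dtype=int)
        train_acc, test_acc, n_train, n_test = 0.0, 0.0, 0, 0
        for train, predict in plan.splits:
            tr = [slot_of[s] for s in train]
            te = [slot_of[s] for s in predict]
            clf = _make_baseline(name, config.seed)
            clf.fit(X[tr], y[tr])
            yhat_tr = np.asarray(clf.predict(X[tr]))
            yhat_te = np.asarray(clf.predict(X[te]))
            train_acc += float((yhat_tr == y[tr]).sum())
            test_acc += float((yhat_te == y[te]).sum())
            n_train += len(tr)
            n_test += len(te)
            for s, v in zip(predict, yhat_te):
                pred[s] = int(v)
        summary = per_user_metrics(
            pred, truth, target_mask, dataset.participants, identity=name
        )
        m = summary.to_dict()
        m["candidate"] = name
        m["train_accuracy"] = train_acc / max(n_train, 1)
        m["train_test_gap"] = m["train_accuracy"] - test_acc / max(n_test, 1)
        rows.append(m)
    return pd.DataFrame(rows).set_index("candidate")
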