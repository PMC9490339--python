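"""Phase classifiers: 1-NN baseline, gradient-boosted trees, neural net.

All three models map the four mechanical features of a dataset space to
the probability that the parameter combination yields an omega-shaped bud
(the positive, minority class). The evaluation suite builds confusion
matrices at a fixed threshold, precision-recall curves and the step-wise
area under them (AUPRC), and dense phase-map grids for plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.neighbors import KNeighborsClassifier

from membud.dataset import DatasetTable
from membud.nn import FeedForwardNet, train_network

__all__ = [
    "BoostedTreeConfig",
    "ClassifierNetConfig",
    "EvaluationReport",
    "resample_majority",
    "minority_weight",
    "train_knn",
    "train_gbt",
    "train_net",
    "confusion_at_threshold",
    "precision_recall_curve",
    "auprc",
    "evaluate_classifier",
    "phase_map",
    "KNNClassifier",
    "GBTClassifier",
    "NetClassifier",
]


@dataclass(frozen=True)
class BoostedTreeConfig:
    """Hand-tuned boosted-tree hyperparameters for the phase classifier."""

    objective: str = "binary:logistic"
    learning_rate: float = 0.01
    max_depth: int = 100
    min_child_weight: float = 10.0
    gamma: float = 1.0
    subsample: float = 0.2
    colsample_bytree: float = 0.9
    seed: int = 23
    n_estimators: int = 700

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass(frozen=True)
class ClassifierNetConfig:
    """Architecture and training protocol of the omega/hill network.

    The net is a 10/100/100/(50% dropout)/10/1 ReLU stack with a sigmoid
    head, trained with batches of 32 for up to 4000 epochs, early-stopped
    (patience 200) on the AUPRC of a seeded validation split carved from
    the 7:1-resampled training set, restoring the best checkpoint.
    """

    hidden_plan: tuple = (10, 100, 100, ("dropout", 0.5), 10)
    batch_size: int = 32
    max_epochs: int = 4000
    patience: int = 200
    resample_ratio: float = 7.0
    validation_fraction: float = 0.2
    learning_rate: float = 1.0e-3
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


# ----------------------------------------------------------------------
# imbalance handling
# ----------------------------------------------------------------------

def resample_majority(train: DatasetTable, ratio: float = 7.0,
                      seed: int = 0) -> DatasetTable:
    """Down-sample the majority (hill) class to ``ratio`` x the minority.

    Minority rows are all kept; majority rows are drawn without
    replacement. If the majority is already below the target ratio the
    table is returned unchanged.
    """
    y = train.labels()
    n_min = int((y == 1).sum())
    n_maj = int((y == 0).sum())
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present to resample")
    target = int(round(ratio * n_min))
    if n_maj <= target:
        return train
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(y == 0)
    keep_maj = np.sort(rng.choice(maj_idx, size=target, replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(y == 1), keep_maj]))
    meta = dict(train.metadata)
    out = DatasetTable(df=train.df.iloc[keep].reset_index(drop=True), metadata=meta)
    meta = dict(meta)
    meta["class_counts"] = out.class_counts()
    meta["resample_ratio"] = ratio
    out.metadata = meta
    return out


def minority_weight(train: DatasetTable) -> float:
    """Positive-class weight: (# hill) / (# omega) in the training set."""
    counts = train.class_counts()
    if counts["omega"] == 0:
        raise ValueError("training set has no omega samples")
    return counts["hill"] / counts["omega"]


# ----------------------------------------------------------------------
# models
# ----------------------------------------------------------------------

class KNNClassifier:
    """1-nearest-neighbour baseline under the normalized L1 metric.

    Features are mapped onto [0, 1] by their sampling ranges so the
    Manhattan distance is the dataset's normalized parameter-space
    distance; the predicted probability is the single nearest training
    label (0 or 1), ties broken toward the lowest training-row index.
    """

    def __init__(self, ranges: Dict[str, Tuple[float, float]],
                 feature_columns: Sequence[str]):
        self.feature_columns = list(feature_columns)
        self.lo = np.array([ranges[c][0] for c in self.feature_columns])
        self.hi = np.array([ranges[c][1] for c in self.feature_columns])
        self._knn = KNeighborsClassifier(n_neighbors=1, metric="manhattan",
                                         algorithm="brute")

    def _scale(self, X):
        return (np.asarray(X, dtype=float) - self.lo) / (self.hi - self.lo)

    def fit(self, X, y):
        self._y = np.asarray(y, dtype=int)
        self._knn.fit(self._scale(X), self._y)
        return self

    def predict_probability(self, X) -> np.ndarray:
        _, idx = self._knn.kneighbors(self._scale(X), n_neighbors=1)
        return self._y[idx[:, 0]].astype(float)


class GBTClassifier:
    """Gradient-boosted tree ensemble with minority-class weighting."""

    def __init__(self, config: BoostedTreeConfig, scale_pos_weight: float):
        self.config = config
        self.scale_pos_weight = float(scale_pos_weight)
        self._model = xgb.XGBClassifier(
            objective=config.objective,
            learning_rate=config.learning_rate,
            max_depth=config.max_depth,
            min_child_weight=config.min_child_weight,
            gamma=config.gamma,
            subsample=config.subsample,
            colsample_bytree=config.colsample_bytree,
            random_state=config.seed,
            n_estimators=config.n_estimators,
            scale_pos_weight=self.scale_pos_weight,
            n_jobs=1,
        )

    def fit(self, X, y):
        self._model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict_probability(self, X) -> np.ndarray:
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]


class NetClassifier:
    """Feed-forward omega/hill classifier with standardized inputs."""

    def __init__(self, net: FeedForwardNet, mean: np.ndarray, std: np.ndarray,
                 feature_columns: Sequence[str]):
        self.net = net
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.asarray(std, dtype=float)
        self.feature_columns = list(feature_columns)

    def predict_probability(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean) / self.std
        return self.net.predict(Xs)[:, 0]

    def to_json(self, path) -> None:
        payload = {
            "kind": "net_classifier",
            "feature_columns": self.feature_columns,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "net": self.net.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NetClassifier":
        d = json.loads(Path(path).read_text())
        return cls(FeedForwardNet.from_dict(d["net"]), np.array(d["mean"]),
                   np.array(d["std"]), d["feature_columns"])


def train_knn(train: DatasetTable) -> KNNClassifier:
    """Fit the 1-NN baseline on a training table."""
    if len(train.df) == 0:
        raise ValueError("empty training set")
    model = KNNClassifier(train.ranges, train.feature_columns)
    return model.fit(train.features(), train.labels())


def train_gbt(train: DatasetTable,
              config: Optional[BoostedTreeConfig] = None) -> GBTClassifier:
    """Fit the boosted-tree classifier; the positive-class weight is the
    hill/omega count ratio of the training set."""
    if len(train.df) == 0:
        raise ValueError("empty training set")
    cfg = config or BoostedTreeConfig()
    model = GBTClassifier(cfg, scale_pos_weight=minority_weight(train))
    return model.fit(train.features(), train.labels())


def train_net(train: DatasetTable,
              config: Optional[ClassifierNetConfig] = None) -> NetClassifier:
    """Train the network classifier on the 7:1 resampled training set.

    A seeded validation split (default 20%) is carved from the resampled
    set; training monitors its AUPRC and restores the best checkpoint.
    """
    if len(train.df) == 0:
        raise ValueError("empty training set")
    cfg = config or ClassifierNetConfig()
    resampled = resample_majority(train, cfg.resample_ratio, seed=cfg.seed)
    X = resampled.features()
    y = resampled.labels().astype(float)

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    # guard: both classes must appear in the validation fold for AUPRC
    if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
        order = np.argsort(y[perm], kind="stable")
        interleave = perm[order]
        val_idx = interleave[::int(np.ceil(n / n_val))][:n_val]
        tr_idx = np.setdiff1d(perm, val_idx)

    mean = X[tr_idx].mean(axis=0)
    std = X[tr_idx].std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    net = FeedForwardNet(X.shape[1], list(cfg.hidden_plan), 1,
                         output_activation="sigmoid", seed=cfg.seed)
    Xv, yv = Xs[val_idx], y[val_idx]

    def monitor(model: FeedForwardNet) -> float:
        return auprc_from_scores(model.predict(Xv)[:, 0], yv)

    train_network(
        net, Xs[tr_idx], y[tr_idx], loss="bce", monitor=monitor,
        higher_is_better=True, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs, patience=cfg.patience,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
    )
    return NetClassifier(net, mean, std, train.feature_columns)


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def confusion_at_threshold(probs, labels, tau: float = 0.5
                           ) -> Tuple[int, int, int, int]:
    """(TN, FP, FN, TP) with prediction = (prob > tau); omega is positive."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = probs > tau
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tn, fp, fn, tp


def precision_recall_curve(probs, labels) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision and recall at every distinct score threshold.

    Returns (precision, recall, thresholds) ordered by rising threshold,
    so recall is weakly decreasing along the arrays.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present")
    order = np.argsort(-probs, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = probs[order]
    tp_cum = np.cumsum(sorted_labels)
    pred_cum = np.arange(1, labels.size + 1)
    # keep the last entry of each tied-score block
    distinct = np.flatnonzero(np.diff(np.append(sorted_scores, -np.inf)))
    precision = tp_cum[distinct] / pred_cum[distinct]
    recall = tp_cum[distinct] / n_pos
    thresholds = sorted_scores[distinct]
    # ascending threshold order
    return precision[::-1], recall[::-1], thresholds[::-1]


def auprc_from_scores(probs, labels) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve:
    sum of (R_i - R_{i-1}) * P_i over descending thresholds."""
    precision, recall, _ = precision_recall_curve(probs, labels)
    p = precision[::-1]
    r = recall[::-1]
    r_prev = np.concatenate([[0.0], r[:-1]])
    return float(np.sum((r - r_prev) * p))


def auprc(prc: Tuple[np.ndarray, np.ndarray, np.ndarray]) -> float:
    """Step-wise area from a (precision, recall, thresholds) curve."""
    precision, recall = np.asarray(prc[0]), np.asarray(prc[1])
    p = precision[::-1]
    r = recall[::-1]
    r_prev = np.concatenate([[0.0], r[:-1]])
    return float(np.sum((r - r_prev) * p))


@dataclass
class EvaluationReport:
    """Classifier evaluation: confusion counts, PRC and its area."""

    tn: int
    fp: int
    fn: int
    tp: int
    threshold: float
    precision: float
    recall: float
    auprc: float
    prc_precision: List[float] = field(default_factory=list)
    prc_recall: List[float] = field(default_factory=list)
    dataset_id: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def evaluate_classifier(model, test: DatasetTable, threshold: float = 0.5,
                        dataset_id: str = "") -> EvaluationReport:
    """Score a model on a withheld table at the given decision threshold."""
    probs = model.predict_probability(test.features())
    labels = test.labels()
    tn, fp, fn, tp = confusion_at_threshold(probs, labels, threshold)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    p, r, _ = precision_recall_curve(probs, labels)
    return EvaluationReport(
        tn=tn, fp=fp, fn=fn, tp=tp, threshold=threshold,
        precision=prec, recall=rec, auprc=auprc((p, r, None)),
        prc_precision=p.tolist(), prc_recall=r.tolist(),
        dataset_id=dataset_id or test.metadata.get("space", ""),
    )


def phase_map(
    model,
    table: DatasetTable,
    fixed_radius_normalized: float,
    grid_spec: Optional[Dict[str, int]] = None,
    fixed_values: Optional[Dict[str, float]] = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Dense curvature x tension phase-map grid at a fixed patch radius.

    The radius is given normalized by its range maximum (the standard
    display slice); the fourth feature defaults to the midpoint of its
    range unless pinned in ``fixed_values``. Grid points outside the
    training ranges are allowed (the surrogate extrapolates) — they are
    flagged in the output, not rejected.
    """
    ranges = table.ranges
    cols = table.feature_columns
    grid_spec = grid_spec or {"curvature": 50, "tension": 50}
    fixed_values = dict(fixed_values or {})
    radius = fixed_radius_normalized * ranges["patch_radius"][1]
    fixed_values["patch_radius"] = radius
    other = [c for c in cols if c not in ("curvature", "tension", "patch_radius")]
    for c in other:
        fixed_values.setdefault(c, 0.5 * (ranges[c][0] + ranges[c][1]))

    cur = np.linspace(*ranges["curvature"], grid_spec["curvature"])
    ten = np.linspace(*ranges["tension"], grid_spec["tension"])
    CC, TT = np.meshgrid(cur, ten, indexing="ij")
    grid = pd.DataFrame({"curvature": CC.ravel(), "tension": TT.ravel()})
    for c in cols:
        if c not in grid.columns:
            grid[c] = fixed_values[c]
    probs = model.predict_probability(grid[cols].to_numpy(dtype=float))
    grid["probability"] = probs
    grid["prediction"] = (probs > threshold).astype(int)
    return grid
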