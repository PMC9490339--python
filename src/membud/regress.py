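"""Shape surrogate: a network regressing 50-point profile curves from
mechanical features, plus its two error metrics and the error-vs-distance
analysis.

The regressor predicts the raw (r, z) coordinates in nm (100 outputs: 50
radii then 50 heights). Errors are reported both as the plain MAE over
the 100 coordinates and as a scale-normalized minimum-distance error that
compares shapes irrespective of bud size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from membud.dataset import DatasetTable, normalized_l1_distance
from membud.nn import FeedForwardNet, train_network

__all__ = [
    "RegressorNetConfig",
    "RegressionReport",
    "NetRegressor",
    "train_regressor",
    "predict_curve",
    "mae_curve",
    "normalized_error",
    "error_distance_analysis",
    "evaluate_regressor",
]


@dataclass(frozen=True)
class RegressorNetConfig:
    """Architecture/training protocol of the curve-regression network:
    a 20/20/100/(25% dropout)/100/(25% dropout)/100/20 ReLU stack with a
    100-wide linear head, Adam at learning rate 0.001, batches of 64, MAE
    loss, early stopping (patience 200, max 4000 epochs) on validation
    MAE with best-checkpoint restore."""

    hidden_plan: tuple = (20, 20, 100, ("dropout", 0.25), 100,
                          ("dropout", 0.25), 100, 20)
    n_outputs: int = 100
    batch_size: int = 64
    max_epochs: int = 4000
    patience: int = 200
    learning_rate: float = 1.0e-3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_outputs != 100:
            raise ValueError("the curve head must have 100 outputs (50 r + 50 z)")


class NetRegressor:
    """Trained shape surrogate with standardized inputs."""

    def __init__(self, net: FeedForwardNet, mean, std, feature_columns):
        self.net = net
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.asarray(std, dtype=float)
        self.feature_columns = list(feature_columns)

    def predict_curve(self, features) -> np.ndarray:
        """Predict the (50, 2) profile curve for one feature vector, or
        (n, 50, 2) for a batch."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        out = self.net.predict((X - self.mean) / self.std)
        curves = np.stack([out[:, :50], out[:, 50:]], axis=-1)
        return curves[0] if np.asarray(features).ndim == 1 else curves

    def to_json(self, path) -> None:
        payload = {
            "kind": "net_regressor",
            "feature_columns": self.feature_columns,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "net": self.net.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NetRegressor":
        d = json.loads(Path(path).read_text())
        return cls(FeedForwardNet.from_dict(d["net"]), d["mean"], d["std"],
                   d["feature_columns"])


def train_regressor(train: DatasetTable,
                    config: Optional[RegressorNetConfig] = None) -> NetRegressor:
    """Train the curve-regression network on a training table.

    A seeded validation split monitors MAE; the best checkpoint is
    restored at the end.
    """
    if len(train.df) == 0:
        raise ValueError("empty training set")
    cfg = config or RegressorNetConfig()
    X = train.features()
    curves = train.curves()
    Y = np.concatenate([curves[:, :, 0], curves[:, :, 1]], axis=1)

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = val_idx

    mean = X[tr_idx].mean(axis=0)
    std = X[tr_idx].std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    Xv, Yv = Xs[val_idx], Y[val_idx]

    net = FeedForwardNet(X.shape[1], list(cfg.hidden_plan), cfg.n_outputs,
                         output_activation="linear", seed=cfg.seed)

    def monitor(model: FeedForwardNet) -> float:
        return float(np.mean(np.abs(model.predict(Xv) - Yv)))

    train_network(
        net, Xs[tr_idx], Y[tr_idx], loss="mae", monitor=monitor,
        higher_is_better=False, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs, patience=cfg.patience,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
    )
    return NetRegressor(net, mean, std, train.feature_columns)


def predict_curve(model: NetRegressor, features) -> np.ndarray:
    """Functional alias for :meth:`NetRegressor.predict_curve`."""
    return model.predict_curve(features)


def mae_curve(pred, true) -> float:
    """Mean absolute error over all 100 curve coordinates, nm."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("curves must have matching shape")
    return float(np.mean(np.abs(pred - true)))


def normalized_error(pred, true) -> float:
    """Scale-normalized minimum-distance error between two curves.

    Both curves are scaled per axis by the maxima of the *true* curve
    (|z| maxima for the height axis); each scaled predicted point is
    matched to its nearest scaled true point and the 50 minimum Euclidean
    distances are averaged. A flat true curve (max |z| = 0) falls back to
    scaling z by the true r maximum.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.ndim != 2 or pred.shape[1] != 2 or true.ndim != 2 or true.shape[1] != 2:
        raise ValueError("curves must be (n, 2) arrays")
    r_max = float(np.max(np.abs(true[:, 0])))
    z_max = float(np.max(np.abs(true[:, 1])))
    if r_max <= 0:
        raise ValueError("true curve has no radial extent")
    if z_max <= 0:
        z_max = r_max  # degenerate flat curve: scale z by the radial maximum
    scale = np.array([r_max, z_max])
    ps = pred / scale
    ts = true / scale
    d = np.linalg.norm(ps[:, None, :] - ts[None, :, :], axis=-1)
    return float(np.mean(d.min(axis=1)))


def error_distance_analysis(errors, distances) -> Tuple[float, float, float]:
    """OLS of error on parameter-space distance: (slope, intercept, R^2)."""
    errors = np.asarray(errors, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if errors.size != distances.size or errors.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(distances) == 0:
        raise ValueError("distances have zero variance")
    res = stats.linregress(distances, errors)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)  # constant errors
    return float(res.slope), float(res.intercept), r2


@dataclass
class RegressionReport:
    """Per-sample errors, nearest-train distances, and the R^2 of each
    error metric regressed on distance."""

    mae: List[float]
    normalized: List[float]
    distance_to_train: List[float]
    r2_mae_vs_distance: float
    r2_normalized_vs_distance: float
    n_negative_radius_predictions: int = 0
    dataset_id: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def evaluate_regressor(model: NetRegressor, train: DatasetTable,
                       test: DatasetTable) -> RegressionReport:
    """Score the surrogate on a withheld table.

    For every test row: curve MAE, normalized minimum-distance error, and
    the normalized L1 distance from its feature vector to the nearest
    training feature vector; then each error metric is regressed on that
    distance. Predictions wandering into negative radii are counted, not
    suppressed.
    """
    Xte = test.features()
    true_curves = test.curves()
    pred_curves = model.predict_curve(Xte)
    ranges = [test.ranges[c] for c in test.feature_columns]

    lo = np.array([r[0] for r in ranges])
    width = np.array([r[1] - r[0] for r in ranges])
    Xtr_s = (train.features() - lo) / width
    Xte_s = (Xte - lo) / width

    maes, norms, dists = [], [], []
    for i in range(Xte.shape[0]):
        maes.append(mae_curve(pred_curves[i], true_curves[i]))
        norms.append(normalized_error(pred_curves[i], true_curves[i]))
        dists.append(float(np.min(np.sum(np.abs(Xtr_s - Xte_s[i]), axis=1))))

    _, _, r2_mae = error_distance_analysis(maes, dists)
    _, _, r2_norm = error_distance_analysis(norms, dists)
    return RegressionReport(
        mae=maes, normalized=norms, distance_to_train=dists,
        r2_mae_vs_distance=r2_mae, r2_normalized_vs_distance=r2_norm,
        n_negative_radius_predictions=int(np.sum(pred_curves[:, :, 0].min(axis=1) < 0)),
        dataset_id=test.metadata.get("space", ""),
    )
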