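"""Voxel-wise pH prediction: features, standardization, training, attack.

Each masked voxel contributes one feature row: the B0-corrected Z-spectrum
(one value per saturation offset), the densely sampled APT-weighted
MTR_asym block at 3.0..4.0 ppm (11 values) and the quantitative T1 value —
61 dimensions for the default 49-offset schedule.  Features and targets
are standardized with statistics computed on the training split only and
then frozen; the probabilistic network returns a pH mean and a 1-sigma
uncertainty per voxel, destandardized back to pH units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .network import HeteroscedasticMLP, gnll_loss
from .processing import ZSpectrumVolume

__all__ = [
    "FeatureTable", "StandardizationStats", "NetConfig", "PredictionMap",
    "TrainResult", "assemble_features", "standardize", "train", "predict",
    "predict_rows", "t1_attack", "save_checkpoint", "load_checkpoint",
]


@dataclass
class FeatureTable:
    """Per-voxel feature rows plus the flat voxel indices they came from."""

    X: np.ndarray  # (n_voxels, n_features)
    voxel_index: np.ndarray  # flat indices into the masked grid
    grid_shape: tuple
    n_dropped: int = 0  # voxels removed for non-finite channels


@dataclass
class StandardizationStats:
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    target_mean: float
    target_sd: float

    def to_dict(self) -> dict:
        return {"feature_mean": self.feature_mean.tolist(),
                "feature_sd": self.feature_sd.tolist(),
                "target_mean": self.target_mean,
                "target_sd": self.target_sd}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationStats":
        return cls(np.asarray(d["feature_mean"]), np.asarray(d["feature_sd"]),
                   float(d["target_mean"]), float(d["target_sd"]))


@dataclass
class NetConfig:
    hidden_sizes: tuple = (10, 20, 10)
    activation: str = "relu"
    lr: float = 0.001
    batch_size: int = 256
    epochs: int = 1000
    split_fraction: float = 0.8
    seed: int = 0
    variance_floor: float = 1e-6
    checkpoint_best: bool = False  # opt-in best-validation checkpointing

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")


@dataclass
class PredictionMap:
    ph_mean: np.ndarray  # 3D, pH units, NaN outside mask
    ph_sigma: np.ndarray  # 3D, pH units, >= 0
    mask: np.ndarray


@dataclass
class TrainResult:
    model: HeteroscedasticMLP
    stats: StandardizationStats
    config: NetConfig
    history: dict  # per-epoch train/val GNLL, val RMSE/r/R2 (pH units)
    train_idx: np.ndarray
    val_idx: np.ndarray
    val_rmse: float
    val_r: float
    val_r2: float


def assemble_features(zvol: ZSpectrumVolume, asym_block: np.ndarray,
                      qt1: np.ndarray, mask: np.ndarray) -> FeatureTable:
    """Stack Z-block, MTR_asym block and qT1 into per-voxel rows.

    Row order is flattened (C-order) voxel index order.  Voxels with any
    non-finite channel are dropped and counted.
    """
    mask = np.asarray(mask, dtype=bool)
    if zvol.z.shape[:-1] != mask.shape or qt1.shape != mask.shape:
        raise ValueError("all inputs must live on the CEST grid")
    flat = np.flatnonzero(mask)
    rows = np.concatenate([
        zvol.z.reshape(-1, zvol.z.shape[-1])[flat],
        asym_block.reshape(-1, asym_block.shape[-1])[flat],
        qt1.reshape(-1, 1)[flat],
    ], axis=1)
    finite = np.isfinite(rows).all(axis=1)
    return FeatureTable(X=rows[finite], voxel_index=flat[finite],
                        grid_shape=mask.shape,
                        n_dropped=int(np.count_nonzero(~finite)))


def standardize(X: np.ndarray, y: np.ndarray | None = None,
                stats: StandardizationStats | None = None):
    """(x - mean)/sd per dimension; computes stats when none are given.

    Zero-variance dimensions are pinned to sd = 1 with a warning so they
    standardize to exact zeros.  Returns ``(Xs, ys, stats)`` (``ys`` is
    None when no targets are passed).
    """
    X = np.asarray(X, dtype=float)
    if stats is None:
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to compute statistics")
        fm = X.mean(axis=0)
        fs = X.std(axis=0)
        if np.any(fs == 0):
            warnings.warn("zero-variance feature dimension(s); sd pinned to 1")
            fs = np.where(fs == 0, 1.0, fs)
        tm, ts = 0.0, 1.0
        if y is not None:
            tm = float(np.mean(y))
            ts = float(np.std(y))
            if ts == 0:
                warnings.warn("constant target; sd pinned to 1")
                ts = 1.0
        stats = StandardizationStats(fm, fs, tm, ts)
    Xs = (X - stats.feature_mean) / stats.feature_sd
    ys = None if y is None else (np.asarray(y, dtype=float) - stats.target_mean) / stats.target_sd
    return Xs, ys, stats


def _regression_stats(pred, truth):
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    if np.std(pred) == 0 or np.std(truth) == 0:
        return rmse, np.nan, np.nan
    r = float(np.corrcoef(pred, truth)[0, 1])
    return rmse, r, r * r


def train(X: np.ndarray, y: np.ndarray, config: NetConfig | None = None) -> TrainResult:
    """Train the probabilistic pH network on raw (unstandardized) rows.

    The voxel rows are split 80/20 at random (config seed), the
    standardization statistics are computed on the training split only,
    and the network is optimized with Adam on the GNLL.  Per-epoch train
    and validation GNLL plus validation RMSE / Pearson r / R^2 (in
    destandardized pH units) are recorded.  Deterministic for a fixed
    seed: same seed, same weights and curves.
    """
    config = config or NetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = int(round(config.split_fraction * n))
    train_idx, val_idx = perm[:n_train], perm[n_train:]

    Xtr_raw, ytr_raw = X[train_idx], y[train_idx]
    Xtr, ytr, stats = standardize(Xtr_raw, ytr_raw)
    Xva, yva, _ = standardize(X[val_idx], y[val_idx], stats)

    net = HeteroscedasticMLP(X.shape[1], config.hidden_sizes,
                             config.variance_floor, seed=config.seed)
    hist = {"train_gnll": [], "val_gnll": [], "val_rmse": [],
            "val_r": [], "val_r2": []}
    best = (np.inf, None)
    for _epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n_train, config.batch_size):
            sel = order[start:start + config.batch_size]
            epoch_loss += net.adam_step(Xtr[sel], ytr[sel], lr=config.lr)
            n_batches += 1
        mu_v, s2_v = net.predict(Xva)
        val_gnll = gnll_loss(mu_v, s2_v, yva, config.variance_floor)
        pred_ph = mu_v * stats.target_sd + stats.target_mean
        truth_ph = yva * stats.target_sd + stats.target_mean
        rmse, r, r2 = _regression_stats(pred_ph, truth_ph)
        hist["train_gnll"].append(epoch_loss / max(n_batches, 1))
        hist["val_gnll"].append(val_gnll)
        hist["val_rmse"].append(rmse)
        hist["val_r"].append(r)
        hist["val_r2"].append(r2)
        if config.checkpoint_best and val_gnll < best[0]:
            best = (val_gnll, net.to_dict())
    if config.checkpoint_best and best[1] is not None:
        net = HeteroscedasticMLP.from_dict(best[1])
        mu_v, s2_v = net.predict(Xva)
        pred_ph = mu_v * stats.target_sd + stats.target_mean
        rmse, r, r2 = _regression_stats(pred_ph, truth_ph)
    return TrainResult(model=net, stats=stats, config=config, history=hist,
                       train_idx=train_idx, val_idx=val_idx,
                       val_rmse=hist["val_rmse"][-1] if not config.checkpoint_best else rmse,
                       val_r=hist["val_r"][-1] if not config.checkpoint_best else r,
                       val_r2=hist["val_r2"][-1] if not config.checkpoint_best else r2)


def predict_rows(model: HeteroscedasticMLP, stats: StandardizationStats,
                 X: np.ndarray):
    """Destandardized per-row prediction ``(ph_mean, ph_sigma)``."""
    Xs, _, _ = standardize(X, stats=stats)
    mu, s2 = model.predict(Xs)
    return (mu * stats.target_sd + stats.target_mean,
            np.sqrt(s2) * stats.target_sd)


def predict(model: HeteroscedasticMLP, stats: StandardizationStats,
            table: FeatureTable) -> PredictionMap:
    """Voxel-wise prediction map; voxels outside the table are NaN."""
    if table.X.shape[1] != model.n_features:
        raise ValueError("feature dimension does not match the trained model")
    mean_flat = np.full(int(np.prod(table.grid_shape)), np.nan)
    sig_flat = np.full_like(mean_flat, np.nan)
    ph, sig = predict_rows(model, stats, table.X)
    mean_flat[table.voxel_index] = ph
    sig_flat[table.voxel_index] = sig
    mask = np.zeros(table.grid_shape, dtype=bool)
    mask.reshape(-1)[table.voxel_index] = True
    return PredictionMap(mean_flat.reshape(table.grid_shape),
                         sig_flat.reshape(table.grid_shape), mask)


def t1_attack(model: HeteroscedasticMLP, stats: StandardizationStats,
              table: FeatureTable, roi_mask: np.ndarray, fake_t1: float) -> dict:
    """Replace qT1 with a fake value inside an ROI and re-predict.

    The CEST channels are untouched; only the last feature column (qT1)
    changes inside the ROI.  Because the model is purely voxel-wise,
    voxels outside the ROI are unchanged by construction.  Returns the
    per-voxel pH-mean and sigma changes inside the ROI together with
    summary medians, including the median predicted sigma of the attacked
    prediction for comparison.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != table.grid_shape:
        raise ValueError("ROI must live on the feature grid")
    roi_rows = roi.reshape(-1)[table.voxel_index]
    if not roi_rows.any():
        raise ValueError("ROI contains no masked voxels")
    ph0, sig0 = predict_rows(model, stats, table.X)
    X_att = table.X.copy()
    X_att[roi_rows, -1] = float(fake_t1)
    ph1, sig1 = predict_rows(model, stats, X_att)
    d_mean = ph1 - ph0
    d_sigma = sig1 - sig0
    inside, outside = roi_rows, ~roi_rows
    return {
        "delta_mean_roi": d_mean[inside],
        "delta_sigma_roi": d_sigma[inside],
        "median_abs_delta_roi": float(np.median(np.abs(d_mean[inside]))),
        "median_sigma_roi": float(np.median(sig1[inside])),
        "max_abs_delta_outside": float(np.max(np.abs(d_mean[outside]))) if outside.any() else 0.0,
        "n_roi": int(inside.sum()),
    }


def save_checkpoint(path, model: HeteroscedasticMLP,
                    stats: StandardizationStats, config: NetConfig,
                    schedule_hash: str = "") -> None:
    """Self-describing JSON checkpoint: weights + config + statistics."""
    payload = {"model": model.to_dict(), "stats": stats.to_dict(),
               "config": asdict(config), "schedule_hash": schedule_hash}
    payload["config"]["hidden_sizes"] = list(config.hidden_sizes)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path) as fh:
        d = json.load(fh)
    cfg = d["config"]
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    return (HeteroscedasticMLP.from_dict(d["model"]),
            StandardizationStats.from_dict(d["stats"]),
            NetConfig(**cfg), d.get("schedule_hash", ""))
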