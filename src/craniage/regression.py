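"""Stage two: 3D convolutional age regression on standardized ROI cubes.

The ROI crop of each volume is resampled trilinearly to an isotropic cube
(64³ by default, 32³ in the desk profile) with intensities rescaled to
[0, 1] by the fixed 0–255 range, so the absolute bone brightness — an
age-informative quantity — survives standardization.  A compact 3D CNN
(strided convolutions, global average pooling, one dense output) is
trained with Adam under cosine annealing to predict age in years; the
dataset is split 4:1 into training and test subsets, and training batches
can be augmented with axis-aligned 90° rotations, intensity inversion and
axis mirroring, all of which leave the age label unchanged.

The headline metric is the root-mean-squared prediction error in years
(mean absolute error is reported alongside).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nnet
from .phantom import GeometryError, Volume3D
from .roi import ROIBox

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressorConfig:
    """Training configuration of the 3D age regressor.

    Defaults follow the full-scale protocol (batch 16, Adam at 1e-3,
    cosine annealing, 150 epochs, 64³ input, 4:1 split, rotation /
    inversion / mirroring augmentations, no target normalization);
    ``desk_profile`` shrinks the cube and schedule for single-CPU runs.
    """

    batch_size: int = 16
    learning_rate: float = 0.001
    epochs: int = 150
    input_edge: int = 64
    augment_rotation: bool = True
    augment_inversion: bool = True
    augment_mirroring: bool = True
    split_ratio: tuple[int, int] = (4, 1)
    normalize_target: bool = False
    channels: tuple[int, ...] = (16, 32, 64, 128)
    restart_period: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.input_edge) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.split_ratio) <= 0:
            raise ValueError("split_ratio parts must be positive")

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "RegressorConfig":
        return cls(epochs=30, input_edge=32, channels=(8, 16, 32),
                   learning_rate=0.01, seed=seed)


def standardize_roi(volume: Volume3D, box: ROIBox, edge: int = 64) -> np.ndarray:
    """Crop the box out of the volume and resample to an edge³ cube in [0, 1]."""
    if edge <= 0:
        raise ValueError("edge must be positive")
    data = volume.intensities
    crop = data[box.x0 : box.x1, box.y0 : box.y1, box.z0 : box.z1]
    if crop.size == 0:
        raise GeometryError("ROI crop is empty")
    crop = np.asarray(crop, dtype=float)
    if crop.shape != (edge, edge, edge):
        factors = tuple(edge / s for s in crop.shape)
        crop = ndimage.zoom(crop, factors, order=1, grid_mode=True, mode="nearest")
    return np.clip(crop / 255.0, 0.0, 1.0)


def augment(cube: np.ndarray, config: RegressorConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomly rotate (axis-aligned 90° multiples), invert and mirror a cube."""
    out = cube
    if config.augment_rotation:
        axes = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
        out = np.rot90(out, k=int(rng.integers(4)), axes=axes)
    if config.augment_mirroring:
        for axis in range(3):
            if rng.uniform() < 0.5:
                out = np.flip(out, axis=axis)
    if config.augment_inversion and rng.uniform() < 0.5:
        out = 1.0 - out
    return np.ascontiguousarray(out)


def split_dataset(items: Sequence, ratio: tuple[int, int] = (4, 1), seed: int = 0
                  ) -> tuple[list, list]:
    """Random disjoint train/test split in the given ratio (nearest count)."""
    n = len(items)
    train_part, test_part = ratio
    n_test = int(round(n * test_part / (train_part + test_part)))
    n_test = min(max(n_test, 1), n - 1)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [items[i] for i in range(n) if i not in test_idx]
    test = [items[i] for i in range(n) if i in test_idx]
    return train, test


class TrainedRegressor:
    """A fitted 3D CNN age regressor with its configuration."""

    def __init__(self, config: RegressorConfig, net: nnet.Sequential | None = None,
                 target_mean: float = 0.0, target_sd: float = 1.0):
        self.config = config
        self.target_mean = target_mean
        self.target_sd = target_sd
        if net is None:
            rng = np.random.default_rng(config.seed)
            layers: list[nnet.Layer] = []
            c_in = 1
            for c_out in config.channels:
                layers += [nnet.Conv3D(c_in, c_out, kernel=3, stride=2, rng=rng),
                           nnet.ReLU()]
                c_in = c_out
            layers += [nnet.GlobalAvgPool(), nnet.Dense(c_in, 1, rng=rng)]
            net = nnet.Sequential(layers)
        self.net = net
        self.log: nnet.TrainLog | None = None

    def _prepare(self, cubes: Sequence[np.ndarray]) -> np.ndarray:
        x = np.stack([np.asarray(c, dtype=float) for c in cubes])
        return x[:, None, ...]

    def fit(self, cubes: Sequence[np.ndarray], ages: Sequence[float]) -> nnet.TrainLog:
        if len(cubes) < 2:
            raise ValueError("training requires at least 2 samples")
        cfg = self.config
        y = np.asarray(ages, dtype=float)
        if cfg.normalize_target:
            self.target_mean, self.target_sd = float(y.mean()), float(y.std() or 1.0)
        y_t = (y - self.target_mean) / self.target_sd
        x = self._prepare(cubes)

        aug = None
        if cfg.augment_rotation or cfg.augment_inversion or cfg.augment_mirroring:
            def aug(batch, rng):
                return np.stack([augment(c[0], cfg, rng) for c in batch])[:, None, ...]

        self.log = self.net.fit(
            x, y_t,
            epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.learning_rate,
            seed=cfg.seed, loss=nnet.mse_loss,
            schedule=nnet.cosine_annealing(cfg.learning_rate, cfg.epochs,
                                           restart_period=cfg.restart_period),
        )
        logger.info("age regressor trained: final loss %.4g", self.log.final_loss)
        return self.log

    def predict(self, cubes: Sequence[np.ndarray]) -> np.ndarray:
        z = self.net.predict(self._prepare(cubes)).ravel()
        return z * self.target_sd + self.target_mean

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        cfg["_target_mean"] = self.target_mean
        cfg["_target_sd"] = self.target_sd
        nnet.save_model(path, self.net, cfg)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedRegressor":
        cfg = nnet.load_model_config(path)
        tm = cfg.pop("_target_mean")
        ts = cfg.pop("_target_sd")
        for key in ("channels", "split_ratio"):
            cfg[key] = tuple(cfg[key])
        model = cls(RegressorConfig(**cfg), target_mean=tm, target_sd=ts)
        model.net.load_state_arrays(nnet.load_model_arrays(path))
        return model


def train_regressor(cubes: Sequence[np.ndarray], ages: Sequence[float],
                    config: RegressorConfig) -> TrainedRegressor:
    model = TrainedRegressor(config)
    model.fit(cubes, ages)
    return model


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalReport:
    """Per-sample predictions and the split-wise error summary in years."""

    records: pd.DataFrame  # columns: subject_id, split, true_age, predicted_age
    rmse_train: float
    rmse_test: float
    mae_train: float
    mae_test: float

    def summary(self) -> dict:
        return {
            "rmse_train_years": self.rmse_train,
            "rmse_test_years": self.rmse_test,
            "mae_train_years": self.mae_train,
            "mae_test_years": self.mae_test,
            "n_train": int((self.records["split"] == "train").sum()),
            "n_test": int((self.records["split"] == "test").sum()),
        }

    def write_scatter_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _rmse(err: np.ndarray) -> float:
    return float(np.sqrt((err**2).mean())) if err.size else float("nan")


def evaluate(
    model: TrainedRegressor,
    train_set: Sequence[tuple[str, np.ndarray, float]],
    test_set: Sequence[tuple[str, np.ndarray, float]],
) -> EvalReport:
    """Predict both splits and report RMSE / MAE in years plus a scatter table.

    Each set item is (subject_id, cube, true_age).
    """
    rows = []
    errors = {}
    for split, items in (("train", train_set), ("test", test_set)):
        if not items:
            raise ValueError(f"{split} set is empty")
        preds = model.predict([c for _, c, _ in items])
        truth = np.array([a for _, _, a in items], dtype=float)
        for (sid, _, age), p in zip(items, preds):
            rows.append({"subject_id": sid, "split": split,
                         "true_age": age, "predicted_age": float(p)})
        errors[split] = preds - truth
    records = pd.DataFrame(rows)
    return EvalReport(
        records=records,
        rmse_train=_rmse(errors["train"]),
        rmse_test=_rmse(errors["test"]),
        mae_train=float(np.abs(errors["train"]).mean()),
        mae_test=float(np.abs(errors["test"]).mean()),
    )
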