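"""Stage one: ROI localisation by 2D slice classification.

A single compact CNN classifies every 2D slice of a volume in all three
projections — axial (XY, indexed by Z), sagittal (ZY, indexed by X) and
coronal (ZX, indexed by Y) — as crossing (1) or not crossing (0) the
craniovertebral region of interest.  Positive labels are then aggregated:
Zm, Xm, Ym are the mean positive-slice indices per projection and the ROI
box is [Xm−w, Xm+w) × [Ym−w, Ym+w) × [Zm−STD, Zm+STD), where STD is the
population standard deviation of the positive axial indices.  When
landmark annotations are available the box can instead be built directly
as [X0−w, X0+w) × [Y0−w, Y0+w) × [Zmin, Zmax).

The aggregation step exists because a slice classifier with high recall
but low positive precision (the operating point this stage is driven to)
still yields accurate positive-index means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from . import nnet
from .phantom import GeometryError, LandmarkAnnotation, Volume3D

logger = logging.getLogger(__name__)

PROJECTIONS = ("axial", "sagittal", "coronal")
#: Volume axis indexed by each projection: axial slices stack along Z, etc.
_PROJECTION_AXIS = {"axial": 2, "sagittal": 0, "coronal": 1}


@dataclass(frozen=True)
class ROIBox:
    """Half-open voxel box [x0, x1) x [y0, y1) x [z0, z1)."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1 and self.z0 < self.z1):
            raise GeometryError(f"degenerate ROI box {self}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ROIBox":
        return cls(**{k: int(v) for k, v in d.items()})

    def axis_extent(self, axis: int) -> tuple[int, int]:
        return ((self.x0, self.x1), (self.y0, self.y1), (self.z0, self.z1))[axis]


def clip_box(x0, x1, y0, y1, z0, z1, shape) -> ROIBox:
    cx0, cy0, cz0 = max(x0, 0), max(y0, 0), max(z0, 0)
    cx1, cy1, cz1 = min(x1, shape[0]), min(y1, shape[1]), min(z1, shape[2])
    if (cx0, cy0, cz0, cx1, cy1, cz1) != (x0, y0, z0, x1, y1, z1):
        logger.warning("ROI box clipped to volume bounds %s", shape)
    if not (cx0 < cx1 and cy0 < cy1 and cz0 < cz1):
        raise GeometryError("ROI box empty after clipping to volume bounds")
    return ROIBox(cx0, cx1, cy0, cy1, cz0, cz1)


def landmark_roi(ann: LandmarkAnnotation, volume_shape: tuple[int, int, int],
                 half_width: int = 64) -> ROIBox:
    """ROI box from the three landmark points:
    [X0−w, X0+w) × [Y0−w, Y0+w) × [Zmin, Zmax), clipped to the volume."""
    if half_width <= 0:
        raise GeometryError("half_width must be positive")
    x0c, y0c, _ = ann.dens_apex
    return clip_box(
        x0c - half_width, x0c + half_width,
        y0c - half_width, y0c + half_width,
        ann.atlas_z_min, ann.atlas_z_max,
        volume_shape,
    )


@dataclass
class SliceSample:
    """One 2D slice with its projection, stack index and ROI-crossing label."""

    image: np.ndarray
    projection: str
    index: int
    label: int


def make_slice_dataset(volume: Volume3D, truth: ROIBox) -> list[SliceSample]:
    """All nx+ny+nz slices of the volume, labelled 1 iff the slice plane
    falls inside the truth box's extent along its projection axis."""
    data = volume.intensities
    samples: list[SliceSample] = []
    for proj in PROJECTIONS:
        axis = _PROJECTION_AXIS[proj]
        lo, hi = truth.axis_extent(axis)
        for idx in range(data.shape[axis]):
            sl = np.take(data, idx, axis=axis)
            samples.append(SliceSample(sl, proj, idx, int(lo <= idx < hi)))
    return samples


# ---------------------------------------------------------------------------
# Classifier


@dataclass(frozen=True)
class SliceClassifierConfig:
    """Training configuration for the slice classifier.

    The printed defaults (batch 128, resize 128, Adam at 1e-6, cosine
    annealing, 10 epochs) suit a large pretrained backbone;
    ``desk_profile`` scales to the compact from-scratch CNN used here.
    """

    batch_size: int = 128
    input_resize: int = 128
    learning_rate: float = 1e-6
    epochs: int = 10
    channels: tuple[int, ...] = (8, 16, 32)
    #: Loss weight on the positive (ROI-crossing) class.  The stage is
    #: deliberately recall-heavy: the downstream mean/SD aggregation
    #: tolerates false positives but not missed ROI slices.
    positive_weight: float = 3.0
    restart_period: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.input_resize, self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "SliceClassifierConfig":
        return cls(input_resize=32, learning_rate=0.01, epochs=10, seed=seed)


def _resize2d(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return np.asarray(img, dtype=float)
    factors = (size / img.shape[0], size / img.shape[1])
    return ndimage.zoom(np.asarray(img, dtype=float), factors, order=1,
                        grid_mode=True, mode="nearest")


class SliceClassifier:
    """Compact 2D CNN mapping a resized slice to an ROI-crossing label.

    One model serves all three projections; the projection identity is not
    an input.  The backbone is pluggable: any object with ``predict`` over
    (N, 1, H, W) arrays can stand in via ``backbone``.
    """

    def __init__(self, config: SliceClassifierConfig, backbone: nnet.Sequential | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if backbone is None:
            layers: list[nnet.Layer] = []
            c_in = 1
            for c_out in config.channels:
                layers += [nnet.Conv2D(c_in, c_out, kernel=3, stride=2, rng=rng),
                           nnet.ReLU()]
                c_in = c_out
            layers += [nnet.GlobalAvgPool(), nnet.Dense(c_in, 1, rng=rng)]
            backbone = nnet.Sequential(layers)
        self.net = backbone
        self.log: nnet.TrainLog | None = None

    def _prepare(self, images: Iterable[np.ndarray]) -> np.ndarray:
        size = self.config.input_resize
        arr = np.stack([_resize2d(im, size) for im in images])
        return (arr / 255.0)[:, None, :, :]

    def fit(self, samples: Sequence[SliceSample]) -> nnet.TrainLog:
        labels = np.array([s.label for s in samples], dtype=float)
        if len(set(labels.tolist())) < 2:
            raise ValueError("training requires both slice classes present")
        x = self._prepare([s.image for s in samples])
        cfg = self.config
        def loss(z, y):
            return nnet.bce_with_logits(z, y, positive_weight=cfg.positive_weight)

        self.log = self.net.fit(
            x, labels,
            epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.learning_rate,
            seed=cfg.seed, loss=loss,
            schedule=nnet.cosine_annealing(cfg.learning_rate, cfg.epochs,
                                           restart_period=cfg.restart_period),
        )
        logger.info("slice classifier trained: final loss %.4g", self.log.final_loss)
        return self.log

    def predict_proba(self, images: Sequence[np.ndarray]) -> np.ndarray:
        z = self.net.predict(self._prepare(images)).ravel()
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, images: Sequence[np.ndarray], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(images) >= threshold).astype(int)


def train_slice_classifier(samples: Sequence[SliceSample],
                           config: SliceClassifierConfig) -> SliceClassifier:
    clf = SliceClassifier(config)
    clf.fit(samples)
    return clf


# ---------------------------------------------------------------------------
# Aggregation


class AggregationError(ValueError):
    """Too few positive slices in some projection to aggregate an ROI.

    Callers holding landmark annotations should fall back to
    :func:`landmark_roi`.
    """

    def __init__(self, projection: str):
        self.projection = projection
        super().__init__(
            f"insufficient positive slices in the {projection} projection")


@dataclass
class SliceLabelSummary:
    """Positive-slice index means per projection and the axial-index SD."""

    Zm: float
    Xm: float
    Ym: float
    z_std: float


def aggregate_roi(
    per_slice_labels: Sequence[SliceSample] | Sequence[tuple[str, int, int]],
    volume_shape: tuple[int, int, int],
    half_width: int = 64,
) -> tuple[SliceLabelSummary, ROIBox]:
    """Aggregate positive slice labels into the ROI box.

    Accepts SliceSamples or (projection, index, label) triples.  Requires
    at least two positive axial slices (the Z band is ±1 population SD
    around their mean) and one positive slice in each other projection.
    """
    if half_width <= 0:
        raise GeometryError("half_width must be positive")
    triples = [
        (s.projection, s.index, s.label) if isinstance(s, SliceSample) else tuple(s)
        for s in per_slice_labels
    ]
    pos: dict[str, list[int]] = {p: [] for p in PROJECTIONS}
    for proj, idx, label in triples:
        if proj not in pos:
            raise ValueError(f"unknown projection {proj!r}")
        if label:
            pos[proj].append(int(idx))
    if len(pos["axial"]) < 2:
        raise AggregationError("axial")
    for proj in ("sagittal", "coronal"):
        if not pos[proj]:
            raise AggregationError(proj)

    z_idx = np.array(pos["axial"], dtype=float)
    summary = SliceLabelSummary(
        Zm=float(z_idx.mean()),
        Xm=float(np.mean(pos["sagittal"])),
        Ym=float(np.mean(pos["coronal"])),
        z_std=float(z_idx.std()),  # population SD
    )
    xm, ym = int(round(summary.Xm)), int(round(summary.Ym))
    z0 = int(round(summary.Zm - summary.z_std))
    z1 = int(round(summary.Zm + summary.z_std))
    if z1 == z0:
        z1 += 1  # zero-width SD band still yields a one-slice box
    box = clip_box(xm - half_width, xm + half_width,
                   ym - half_width, ym + half_width,
                   z0, z1, volume_shape)
    return summary, box


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_labels: Sequence[int], true_labels: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth label sequences differ in length")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )


def precision_recall(cm: ConfusionMatrix, positive_class: int = 1) -> tuple[float, float]:
    """(precision, recall) for the requested class; NaN when undefined."""
    if positive_class == 1:
        tp, fp, fn = cm.tp, cm.fp, cm.fn
    else:
        tp, fp, fn = cm.tn, cm.fn, cm.fp
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return precision, recall
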