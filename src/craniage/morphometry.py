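"""The 26-feature craniometric scheme.

Features 1–17 are geometric descriptors of the frontal- and
sphenoid-sinus region masks on the sagittal scanogram ("dots" are mask
pixels): pixel counts, dispersion of pixels around the region centroid,
maximum pairwise extent, elongation direction and ratio from second-moment
eigen-analysis, centroid offsets between the two sinuses, and the
frontal/sphenoid area ratio.  Features 18–25 are grey-value moment
statistics of the bone texture in the clivus / clinoid-plate region,
computed as population (divide-by-n) central moments of the 0–255 pixel
intensities.  Feature 26 is the atlantoaxial involution grade.

Degenerate inputs never abort batch extraction: ratios undefined on a
constant region are reported as NaN sentinels, and a collinear mask gets an
infinite elongation ratio with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, distance

from .involution import InvolutionGrade

#: Above this mask size the max pairwise distance switches from the exact
#: all-pairs computation to the (still exact) convex-hull reduction.
_MAX_DIST_EXACT_LIMIT = 10_000

#: Registry of the 26 features: (index, short name).
FEATURE_REGISTRY: tuple[tuple[int, str], ...] = (
    (1, "frontal_dot_count"),
    (2, "frontal_mean_sq_dist"),
    (3, "frontal_max_dist"),
    (4, "frontal_elongation_direction"),
    (5, "sphenoid_dot_count"),
    (6, "sphenoid_mean_sq_dist"),
    (7, "sphenoid_max_dist"),
    (8, "sphenoid_elongation_direction"),
    (9, "delta_x_centers"),
    (10, "delta_y_centers"),
    (11, "frontal_avg_size"),
    (12, "frontal_elongation_mean"),
    (13, "frontal_elongation_max"),
    (14, "sphenoid_avg_size"),
    (15, "sphenoid_elongation_mean"),
    (16, "sphenoid_elongation_max"),
    (17, "area_ratio_frontal_sphenoid"),
    (18, "clivus_brightness_mean"),
    (19, "clivus_brightness_variance"),
    (20, "clivus_brightness_sd"),
    (21, "clivus_brightness_cv"),
    (22, "clivus_brightness_m3"),
    (23, "clivus_brightness_skewness"),
    (24, "clivus_brightness_m4"),
    (25, "clivus_brightness_excess_kurtosis"),
    (26, "involution_grade"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for _, name in FEATURE_REGISTRY)


class RegionMask:
    """A set of (x, y) pixel coordinates selected on a source image."""

    def __init__(self, pixels: np.ndarray | Iterable[tuple[int, int]],
                 image_shape: tuple[int, int] | None = None):
        pts = np.asarray(list(pixels) if not isinstance(pixels, np.ndarray) else pixels,
                         dtype=float)
        if pts.size == 0:
            raise ValueError("region mask must be non-empty")
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of (x, y) coordinates")
        if image_shape is not None:
            if (pts < 0).any() or (pts[:, 0] >= image_shape[0]).any() or (
                    pts[:, 1] >= image_shape[1]).any():
                raise ValueError("mask pixels fall outside the image bounds")
        self.pixels = pts
        self.image_shape = image_shape

    @classmethod
    def from_bool_image(cls, mask: np.ndarray) -> "RegionMask":
        """Build from a boolean image indexed [x, y] (or [row=x, col=y])."""
        xs, ys = np.nonzero(mask)
        return cls(np.column_stack([xs, ys]).astype(float), image_shape=mask.shape)

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


def dot_stats(mask: RegionMask) -> tuple[int, float, float]:
    """(pixel count, mean squared distance to centroid, max pairwise distance)."""
    pts = mask.pixels
    n = pts.shape[0]
    d = pts - pts.mean(axis=0)
    mean_sq = float((d**2).sum(axis=1).mean())
    if n == 1:
        return 1, 0.0, 0.0
    if n > _MAX_DIST_EXACT_LIMIT:
        try:
            hull = ConvexHull(pts)
            cand = pts[hull.vertices]
        except Exception:  # collinear degenerate hull
            cand = pts
    else:
        cand = pts
    max_d = float(distance.pdist(cand).max())
    return n, mean_sq, max_d


def elongation(mask: RegionMask) -> tuple[float, float]:
    """Elongation direction (degrees from the image X axis, in (-90, 90])
    and the dimensionless elongation ratio sqrt(lambda_major / lambda_minor).

    Uses the eigen-decomposition of the 2x2 second central moment matrix of
    the mask's pixel coordinates.  A collinear mask has a zero minor
    eigenvalue; the ratio is reported as +inf with a warning.
    """
    pts = mask.pixels
    if pts.shape[0] < 2:
        raise ValueError("elongation requires at least 2 pixels")
    d = pts - pts.mean(axis=0)
    cov = d.T @ d / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    major = evecs[:, 1]
    angle = math.degrees(math.atan2(major[1], major[0]))
    # fold into (-90, 90]
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    if lam_minor <= 1e-12 * max(lam_major, 1.0):
        warnings.warn("degenerate (collinear) mask: elongation ratio is infinite")
        return angle, math.inf
    return angle, math.sqrt(lam_major / lam_minor)


def avg_size(mask: RegionMask) -> float:
    """Mean Euclidean distance of the mask's pixels from its centroid."""
    d = mask.pixels - mask.centroid
    return float(np.hypot(d[:, 0], d[:, 1]).mean())


def sinus_pair_features(frontal: RegionMask, sphenoid: RegionMask
                        ) -> tuple[float, float, float, float, float]:
    """(delta_X, delta_Y, avg_size_frontal, avg_size_sphenoid, area_ratio).

    Centroid differences are signed, frontal minus sphenoid; the area ratio
    is the pixel-count ratio |frontal| / |sphenoid|.
    """
    cf, cs = frontal.centroid, sphenoid.centroid
    return (
        float(cf[0] - cs[0]),
        float(cf[1] - cs[1]),
        avg_size(frontal),
        avg_size(sphenoid),
        len(frontal) / len(sphenoid),
    )


def brightness_stats(values: Sequence[float] | np.ndarray
                     ) -> tuple[float, float, float, float, float, float, float, float]:
    """Population moment statistics of a grey-value sample.

    Returns (mean, variance, sd, cv, m3, skewness, m4, excess kurtosis)
    with divide-by-n central moments; the scale-free ratios are NaN when
    the sample is constant (sd == 0).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("brightness statistics require at least 2 values")
    mean = float(v.mean())
    d = v - mean
    m2 = float((d**2).mean())
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    sd = math.sqrt(m2)
    if sd == 0.0:
        return mean, 0.0, 0.0, math.nan, 0.0, math.nan, 0.0, math.nan
    cv = sd / mean if mean != 0 else math.nan
    skew = m3 / sd**3
    excess = m4 / sd**4 - 3.0
    return mean, m2, sd, cv, m3, skew, m4, excess


def _connected_components(mask: RegionMask) -> list[RegionMask]:
    """Split a mask into 8-connected components (rasterized internally)."""
    pts = mask.pixels.astype(int)
    x0, y0 = pts.min(axis=0)
    grid = np.zeros(tuple(pts.max(axis=0) - (x0, y0) + 1), dtype=bool)
    grid[pts[:, 0] - x0, pts[:, 1] - y0] = True
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    comps = []
    for k in range(1, n + 1):
        xs, ys = np.nonzero(labels == k)
        comps.append(RegionMask(np.column_stack([xs + x0, ys + y0]).astype(float)))
    return comps


def component_elongations(mask: RegionMask) -> tuple[float, float]:
    """(mean, max) elongation ratio across the mask's connected components.

    Single-pixel components carry no elongation and are skipped; if every
    component is degenerate the whole-mask elongation ratio is used.
    """
    ratios = []
    for comp in _connected_components(mask):
        if len(comp) < 2:
            continue
        _, ratio = elongation(comp)
        if math.isfinite(ratio):
            ratios.append(ratio)
    if not ratios:
        whole = elongation(mask)[1]
        return whole, whole
    return float(np.mean(ratios)), float(np.max(ratios))


@dataclass
class FeatureVector:
    """The 26 features of one subject, keyed by registry name."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector missing entries: {sorted(missing)}")

    def __getitem__(self, key: str | int) -> float:
        if isinstance(key, int):
            key = FEATURE_NAMES[key - 1]
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


def extract_features(scanogram, grade: InvolutionGrade | int) -> FeatureVector:
    """Assemble the full 26-feature vector from a scanogram's region masks.

    ``scanogram`` must expose ``image`` (2D 0–255 array) and ``masks``, a
    mapping with entries ``frontal_sinus``, ``sphenoid_sinus`` and
    ``clivus`` (boolean arrays or :class:`RegionMask`).
    """
    masks: Mapping = scanogram.masks
    needed = ("frontal_sinus", "sphenoid_sinus", "clivus")
    for key in needed:
        if key not in masks:
            raise KeyError(f"scanogram is missing required mask {key!r}")

    def as_mask(m) -> RegionMask:
        return m if isinstance(m, RegionMask) else RegionMask.from_bool_image(np.asarray(m))

    frontal = as_mask(masks["frontal_sinus"])
    sphenoid = as_mask(masks["sphenoid_sinus"])
    clivus = as_mask(masks["clivus"])

    f1, f2, f3 = dot_stats(frontal)
    f4, _ = elongation(frontal)
    f5, f6, f7 = dot_stats(sphenoid)
    f8, _ = elongation(sphenoid)
    f9, f10, f11, f14, f17 = sinus_pair_features(frontal, sphenoid)
    f12, f13 = component_elongations(frontal)
    f15, f16 = component_elongations(sphenoid)

    img = np.asarray(scanogram.image, dtype=float)
    idx = clivus.pixels.astype(int)
    intensities = img[idx[:, 0], idx[:, 1]]
    f18, f19, f20, f21, f22, f23, f24, f25 = brightness_stats(intensities)

    names = FEATURE_NAMES
    vals = [f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13, f14,
            f15, f16, f17, f18, f19, f20, f21, f22, f23, f24, f25,
            float(int(grade))]
    return FeatureVector(dict(zip(names, (float(v) for v in vals))))
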