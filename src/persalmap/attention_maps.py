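"""Saliency-map construction, comparison and serialization.

A *personalized saliency map* (PSM) is the attention map of one person for
one image, built here by Gaussian kernel density estimation over that
person's gaze fixations.  The *universal saliency map* (USM) is the
person-agnostic pixel-wise average of many persons' PSMs.  The residual a
person-specific model learns is the *difference map* PSM − USM.

Metrics follow the conventions of the public saliency benchmarks:

* ``metric_cc`` — Pearson correlation over flattened pixels (invariant to
  affine rescaling, so maps are compared raw);
* ``metric_kldiv`` — KL divergence between the two maps normalized to
  probability distributions, with the ground truth in the numerator of the
  log, i.e. ``kldiv(prediction, truth) = Σ truth·ln(truth/prediction)``;
* ``metric_sim`` — histogram intersection ``Σ min(a, b)`` of unit-sum maps.

Coordinates are 0-based ``(row, col)``; boxes are half-open.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger("persalmap")

#: Pixel-mass floor used when forming probability distributions for KLdiv.
KLDIV_EPS = 1e-12

#: Default fixation-smoothing bandwidth as a fraction of image height
#: (roughly one degree of visual angle on a typical free-viewing setup).
DEFAULT_SIGMA_FRACTION = 1.0 / 16.0


class ShapeMismatchError(ValueError):
    """Two maps that must share dimensions do not."""


class ConstantMapError(ValueError):
    """Pearson correlation requested for a constant (zero-variance) map."""


class NormalizationError(ValueError):
    """A map that must carry mass is all-zero."""


class FixationBoundsError(ValueError):
    """A fixation point lies outside the image."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageRecord:
    """An image as a float array with values in [0, 1].

    ``pixels`` has shape (height, width) or (height, width, channels) with
    1 or 3 channels.
    """

    image_id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(
                f"image {self.image_id!r}: expected HxW or HxWx{{1,3}} pixels, "
                f"got shape {np.shape(self.pixels)}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image {self.image_id!r}: empty image")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class FixationSet:
    """Gaze fixations of one person on one image.

    ``points`` is a sequence of ``(col, row)`` pixel positions (x, y order,
    matching eye-tracker exports).  May be empty.
    """

    person_id: str
    image_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "points", tuple((float(x), float(y)) for x, y in self.points)
        )


@dataclass(frozen=True)
class SaliencyMap:
    """A non-negative attention grid over image pixels."""

    image_id: str
    values: np.ndarray
    norm_mode: str = "raw"  # raw | unit_sum | unit_max

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"saliency map must be 2-D, got shape {vals.shape}")
        if np.any(vals < 0):
            raise ValueError("saliency map has negative values")
        if self.norm_mode not in ("raw", "unit_sum", "unit_max"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if self.norm_mode == "unit_sum" and abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("unit_sum map does not sum to 1")
        if self.norm_mode == "unit_max" and vals.max() > 0 and abs(vals.max() - 1.0) > 1e-9:
            raise ValueError("unit_max map does not peak at 1")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class DifferenceMap:
    """Signed residual PSM − USM for one person and image."""

    image_id: str
    person_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("difference map must be 2-D")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# Normalization helpers
# ---------------------------------------------------------------------------

def normalize_map(m: SaliencyMap, mode: str) -> SaliencyMap:
    """Return ``m`` rescaled to ``mode`` (raw / unit_sum / unit_max).

    An all-zero map is returned unchanged except for unit_sum, which needs
    mass and raises :class:`NormalizationError`.
    """
    v = m.values
    if mode == "raw":
        return dataclasses.replace(m, norm_mode="raw")
    if mode == "unit_sum":
        s = v.sum()
        if s <= 0:
            raise NormalizationError(f"map {m.image_id!r} is all-zero; cannot unit_sum")
        return SaliencyMap(m.image_id, v / s, "unit_sum")
    if mode == "unit_max":
        mx = v.max()
        if mx <= 0:
            return dataclasses.replace(m, norm_mode="unit_max")
        return SaliencyMap(m.image_id, v / mx, "unit_max")
    raise ValueError(f"unknown norm mode {mode!r}")


def _check_same_shape(a: SaliencyMap, b: SaliencyMap) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"map shapes differ: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

def fixations_to_map(
    fixations: FixationSet, height: int, width: int, sigma: float | None = None
) -> SaliencyMap:
    """Smooth gaze fixations into a saliency map.

    Each fixation contributes an isotropic Gaussian kernel of standard
    deviation ``sigma`` pixels, evaluated exactly on the pixel grid; the sum
    is rescaled to peak at 1 (unit_max).  An empty fixation set yields the
    all-zero raw map — free-viewing data can legitimately miss an image, and
    downstream metrics raise on constant maps, which is the correct failure
    point.

    Parameters
    ----------
    sigma
        Kernel bandwidth in pixels; defaults to ``height / 16``.
    """
    if height < 1 or width < 1:
        raise ValueError("map dimensions must be positive")
    if sigma is None:
        sigma = height * DEFAULT_SIGMA_FRACTION
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    for x, y in fixations.points:
        if not (0 <= x < width and 0 <= y < height):
            raise FixationBoundsError(
                f"fixation (x={x}, y={y}) outside {height}x{width} image "
                f"{fixations.image_id!r}"
            )

    if not fixations.points:
        return SaliencyMap(fixations.image_id, np.zeros((height, width)), "raw")

    rows = np.arange(height)[:, None]  # (H, 1)
    cols = np.arange(width)[None, :]  # (1, W)
    acc = np.zeros((height, width))
    inv = 1.0 / (2.0 * sigma * sigma)
    for x, y in fixations.points:
        # separable exact evaluation: exp(-(dr^2+dc^2)/2s^2)
        kr = np.exp(-((rows - y) ** 2) * inv)
        kc = np.exp(-((cols - x) ** 2) * inv)
        acc += kr * kc
    acc /= acc.max()
    return SaliencyMap(fixations.image_id, acc, "unit_max")


def compute_usm(maps: list[SaliencyMap]) -> SaliencyMap:
    """Pixel-wise mean of one map per person — the universal saliency map."""
    if not maps:
        raise ValueError("need at least one map to average")
    first = maps[0]
    for m in maps[1:]:
        _check_same_shape(first, m)
        if m.image_id != first.image_id:
            raise ValueError(
                f"maps belong to different images: {first.image_id!r} vs {m.image_id!r}"
            )
    mean = np.mean([m.values for m in maps], axis=0)
    return SaliencyMap(first.image_id, mean, "raw")


def difference_map(psm: SaliencyMap, usm: SaliencyMap, person_index: int = 0) -> DifferenceMap:
    """Signed residual ``psm − usm``; adding it back to ``usm`` recovers ``psm``."""
    _check_same_shape(psm, usm)
    return DifferenceMap(psm.image_id, person_index, psm.values - usm.values)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def metric_cc(a: SaliencyMap, b: SaliencyMap) -> float:
    """Pearson correlation of the two maps' flattened pixel vectors."""
    _check_same_shape(a, b)
    av = a.values.ravel()
    bv = b.values.ravel()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ConstantMapError("correlation undefined for a constant map")
    ac = av - av.mean()
    bc = bv - bv.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def _as_distribution(m: SaliencyMap, eps: float) -> np.ndarray:
    v = m.values
    s = v.sum()
    p = v / s if s > 0 else np.zeros_like(v)
    p = p + eps
    return p / p.sum()


def metric_kldiv(prediction: SaliencyMap, truth: SaliencyMap, eps: float = KLDIV_EPS) -> float:
    """KL divergence of the prediction from the ground truth, in nats.

    Both maps are normalized to unit sum with an ``eps`` floor per pixel;
    returns ``Σ t·ln(t/p)`` with the truth in the numerator.  Asymmetric.
    """
    _check_same_shape(prediction, truth)
    p = _as_distribution(prediction, eps)
    t = _as_distribution(truth, eps)
    return float(np.sum(t * np.log(t / p)))


def metric_sim(a: SaliencyMap, b: SaliencyMap) -> float:
    """Histogram intersection ``Σ min(a, b)`` of the unit-sum maps; in [0, 1]."""
    _check_same_shape(a, b)
    av = normalize_map(a, "unit_sum").values
    bv = normalize_map(b, "unit_sum").values
    return float(np.minimum(av, bv).sum())


# ---------------------------------------------------------------------------
# I/O: fixation CSV, PNG, NPZ
# ---------------------------------------------------------------------------

def read_fixation_csv(path) -> list[FixationSet]:
    """Read a fixation table (columns person_id,image_id,x,y; 0-based x=col).

    Returns one :class:`FixationSet` per (person, image) pair, in file order.
    """
    df = pd.read_csv(path)
    required = {"person_id", "image_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation CSV missing columns: {sorted(missing)}")
    out: list[FixationSet] = []
    for (pid, iid), grp in df.groupby(["person_id", "image_id"], sort=False):
        pts = tuple(zip(grp["x"].astype(float), grp["y"].astype(float)))
        out.append(FixationSet(str(pid), str(iid), pts))
    return out


def write_fixation_csv(path, fixation_sets: list[FixationSet]) -> None:
    rows = [
        {"person_id": fs.person_id, "image_id": fs.image_id, "x": x, "y": y}
        for fs in fixation_sets
        for x, y in fs.points
    ]
    pd.DataFrame(rows, columns=["person_id", "image_id", "x", "y"]).to_csv(path, index=False)


def save_map_png(path, m: SaliencyMap) -> None:
    """Write a 16-bit grayscale PNG, scaled so the peak maps to 65535."""
    v = m.values
    mx = v.max()
    scaled = (v / mx * 65535.0).round() if mx > 0 else np.zeros_like(v)
    iio.imwrite(path, scaled.astype(np.uint16), extension=".png")


def load_map_png(path, image_id: str = "") -> SaliencyMap:
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    mx = arr.max()
    vals = arr / mx if mx > 0 else arr
    return SaliencyMap(image_id or str(path), vals, "unit_max")


def save_map_npz(path, m: SaliencyMap) -> None:
    np.savez(path, image_id=np.array(m.image_id), values=m.values)


def load_map_npz(path) -> SaliencyMap:
    with np.load(path, allow_pickle=False) as z:
        return SaliencyMap(str(z["image_id"]), z["values"], "raw")
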