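"""Adaptive image selection (AIS) and baseline selection strategies.

A new person should have to view as few panel images as possible before
their attention can be predicted.  AIS scores every candidate image by how
strongly the panel *disagrees* about the objects it contains: for each
detected object box, the across-person population variance of the panel's
attention maps is averaged over the box's pixels; per image, each object
category contributes its largest instance, absent categories contribute
zero, and the image score is the sum over categories.  The C highest-
scoring images are selected — they contain many kinds of objects on which
people differ, which is exactly where person similarity is informative.

Also provided: ISPSM (rank by whole-frame attention variance), a
feature-diversity strategy in the spirit of ISVF (rank by dissimilarity of
visual features to the rest of the set, with a pluggable feature
extractor), and seeded random selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .attention_maps import ImageRecord, SaliencyMap, normalize_map

logger = logging.getLogger("persalmap")

#: Detector boxes below this confidence are dropped before scoring.
DEFAULT_CONFIDENCE_THRESHOLD = 0.5


class InsufficientPersonsError(ValueError):
    """Across-person variance needs at least two persons."""


@dataclass(frozen=True)
class ObjectBox:
    """A labeled detection: category in [1..M], half-open pixel box, confidence."""

    image_id: str
    category: int
    row0: int
    col0: int
    height: int
    width: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"degenerate box on {self.image_id!r}: {self.height}x{self.width}")
        if self.category < 1:
            raise ValueError("categories are 1-based positive integers")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    def slice(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass(frozen=True)
class VarianceTable:
    """Per-image, per-category object variances v(n,m) and row sums v̄_n."""

    v: np.ndarray  # (N, M)
    v_bar: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        vb = np.asarray(self.v_bar, dtype=float)
        if v.ndim != 2 or vb.shape != (v.shape[0],):
            raise ValueError("v must be (N, M) and v_bar length N")
        if np.any(v < -1e-15):
            raise ValueError("variances must be non-negative")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "v_bar", vb)


@dataclass(frozen=True)
class SelectionResult:
    strategy: str
    indices: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be distinct")
        if any(
            self.scores[i] < self.scores[i + 1] - 1e-12 for i in range(len(self.scores) - 1)
        ):
            raise ValueError("selection scores must be non-increasing")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))


class Detector(Protocol):
    """Object-detector contract: image → list of (category, (row0, col0, h, w), confidence)."""

    def __call__(self, image: ImageRecord) -> list[tuple[int, tuple[int, int, int, int], float]]:
        ...


class FixtureDetector:
    """Detector backed by known ground-truth boxes, for testing and synthesis."""

    def __init__(self, boxes_by_image: dict[str, list[ObjectBox]]):
        self._boxes = boxes_by_image

    def __call__(self, image: ImageRecord):
        return [
            (b.category, (b.row0, b.col0, b.height, b.width), b.score)
            for b in self._boxes.get(image.image_id, [])
        ]


# ---------------------------------------------------------------------------
# Detection and variance scoring
# ---------------------------------------------------------------------------

def detect_objects(
    image: ImageRecord,
    detector: Detector,
    min_confidence: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[ObjectBox]:
    """Run a detector and validate its boxes against the image bounds.

    Out-of-bounds boxes are clipped (with a warning); boxes below
    ``min_confidence`` are dropped.
    """
    out: list[ObjectBox] = []
    H, W = image.height, image.width
    for category, (r0, c0, h, w), conf in detector(image):
        if conf < min_confidence:
            continue
        r0c, c0c = max(0, int(r0)), max(0, int(c0))
        r1c, c1c = min(H, int(r0) + int(h)), min(W, int(c0) + int(w))
        if (r0c, c0c, r1c - r0c, c1c - c0c) != (r0, c0, h, w):
            logger.warning(
                "box %s on image %s clipped to image bounds %dx%d",
                (r0, c0, h, w), image.image_id, H, W,
            )
        if r1c <= r0c or c1c <= c0c:
            logger.warning("box %s on image %s lies fully outside; dropped", (r0, c0, h, w), image.image_id)
            continue
        out.append(ObjectBox(image.image_id, int(category), r0c, c0c, r1c - r0c, c1c - c0c, float(conf)))
    return out


def object_variance(person_maps: Sequence[SaliencyMap], box: ObjectBox) -> float:
    """Across-person attention variance inside one object box.

    For each pixel (j,k) of the box, the population variance (divisor P) of
    the P persons' map values is taken; the result is the mean over the
    box's pixels.  Zero iff all persons agree inside the box.
    """
    if len(person_maps) < 2:
        raise InsufficientPersonsError("object variance needs at least 2 persons")
    rs, cs = box.slice()
    stack = np.asarray([m.values[rs, cs] for m in person_maps])  # (P, h, w)
    if stack.shape[1:] != (box.height, box.width):
        raise ValueError(f"box {box} exceeds map bounds {person_maps[0].shape}")
    return float(stack.var(axis=0, ddof=0).mean())


def image_variance_row(
    boxes: Sequence[ObjectBox],
    person_maps: Sequence[SaliencyMap],
    num_categories: int,
) -> np.ndarray:
    """Length-M vector of per-category variances for one image.

    Category m's entry is the largest object variance over that category's
    instances in the image, and 0 if the category is absent.
    """
    row = np.zeros(num_categories)
    for box in boxes:
        if box.category > num_categories:
            raise ValueError(f"category {box.category} exceeds vocabulary size {num_categories}")
        val = object_variance(person_maps, box)
        row[box.category - 1] = max(row[box.category - 1], val)
    return row


def compute_variance_table(
    boxes_by_image: Sequence[Sequence[ObjectBox]],
    maps_by_image: Sequence[Sequence[SaliencyMap]],
    num_categories: int,
    normalize: str | None = "unit_sum",
) -> VarianceTable:
    """Build the full (N, M) object-variance table and its row sums.

    Person maps are normalized to unit sum per person per image by
    default, so each person contributes the same total attention mass and
    the variance reflects *where* people look rather than how concentrated
    or how strongly scaled their maps are; pass ``normalize=None`` to score
    raw maps.
    """
    rows = []
    for boxes, maps in zip(boxes_by_image, maps_by_image):
        if normalize is not None:
            maps = [normalize_map(m, normalize) for m in maps]
        rows.append(image_variance_row(boxes, maps, num_categories))
    v = np.asarray(rows)
    return VarianceTable(v=v, v_bar=v.sum(axis=1))


# ---------------------------------------------------------------------------
# Selection strategies
# ---------------------------------------------------------------------------

def _top_c(scores: np.ndarray, C: int, strategy: str) -> SelectionResult:
    N = len(scores)
    if not (1 <= C <= N):
        raise ValueError(f"C={C} out of range [1, {N}]")
    # stable sort on (-score, index): ties broken by lower image index
    order = np.lexsort((np.arange(N), -scores))[:C]
    return SelectionResult(strategy, tuple(order), tuple(scores[order]))


def select_images(variance_table: VarianceTable, C: int) -> SelectionResult:
    """AIS: the C images with the largest summed object variance v̄_n."""
    return _top_c(variance_table.v_bar, C, "AIS")


def select_images_ispsm(
    maps_by_image: Sequence[Sequence[SaliencyMap]],
    C: int,
    normalize: str | None = "unit_sum",
) -> SelectionResult:
    """ISPSM baseline: rank images by whole-frame across-person variance."""
    scores = []
    for maps in maps_by_image:
        if len(maps) < 2:
            raise InsufficientPersonsError("ISPSM needs at least 2 persons")
        if normalize is not None:
            maps = [normalize_map(m, normalize) for m in maps]
        stack = np.asarray([m.values for m in maps])
        scores.append(float(stack.var(axis=0, ddof=0).mean()))
    return _top_c(np.asarray(scores), C, "ISPSM")


def color_histogram_features(image: ImageRecord, bins: int = 8) -> np.ndarray:
    """Default visual features: per-channel intensity histograms (unit sum)."""
    feats = []
    for ch in range(image.pixels.shape[2]):
        h, _ = np.histogram(image.pixels[:, :, ch], bins=bins, range=(0.0, 1.0))
        feats.append(h)
    f = np.concatenate(feats).astype(float)
    return f / f.sum()


def select_images_isvf(
    images: Sequence[ImageRecord],
    C: int,
    feature_extractor: Callable[[ImageRecord], np.ndarray] = color_histogram_features,
) -> SelectionResult:
    """Feature-diversity baseline: select images least similar to the rest.

    Each image's score is the negated mean cosine similarity of its feature
    vector to every other image's; the C highest (most dissimilar) win.
    The default extractor is a channel-wise color histogram — a deliberately
    lightweight stand-in for a deep feature backbone, exposed so callers
    can plug in any ``image -> vector`` function.
    """
    feats = np.asarray([feature_extractor(img) for img in images])
    norms = np.linalg.norm(feats, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = feats / norms
    sim = unit @ unit.T
    np.fill_diagonal(sim, 0.0)
    mean_sim = sim.sum(axis=1) / max(len(images) - 1, 1)
    return _top_c(-mean_sim, C, "ISVF")


def select_images_random(n_images: int, C: int, seed: int = 0) -> SelectionResult:
    """Seeded uniform random selection (control strategy)."""
    rng = np.random.default_rng(seed)
    if not (1 <= C <= n_images):
        raise ValueError(f"C={C} out of range [1, {n_images}]")
    idx = rng.permutation(n_images)[:C]
    return SelectionResult("random", tuple(int(i) for i in idx), tuple(0.0 for _ in idx))


# ---------------------------------------------------------------------------
# Box I/O: COCO-style JSON and flat TSV
# ---------------------------------------------------------------------------

def read_boxes_json(path) -> dict[str, list[ObjectBox]]:
    """Read COCO-style JSON (images/annotations/categories, bbox=[x,y,w,h])."""
    with open(path) as fh:
        doc = json.load(fh)
    id_to_name = {img["id"]: img["file_name"] for img in doc.get("images", [])}
    out: dict[str, list[ObjectBox]] = {name: [] for name in id_to_name.values()}
    for ann in doc.get("annotations", []):
        x, y, w, h = ann["bbox"]
        image_id = id_to_name[ann["image_id"]]
        out.setdefault(image_id, []).append(
            ObjectBox(
                image_id=image_id,
                category=int(ann["category_id"]),
                row0=int(round(y)),
                col0=int(round(x)),
                height=int(round(h)),
                width=int(round(w)),
                score=float(ann.get("score", 1.0)),
            )
        )
    return out


def write_boxes_json(path, boxes_by_image: dict[str, list[ObjectBox]]) -> None:
    images = [{"id": i, "file_name": name} for i, name in enumerate(boxes_by_image)]
    name_to_id = {img["file_name"]: img["id"] for img in images}
    cats = sorted({b.category for boxes in boxes_by_image.values() for b in boxes})
    annotations = [
        {
            "id": k,
            "image_id": name_to_id[b.image_id],
            "category_id": b.category,
            "bbox": [b.col0, b.row0, b.width, b.height],
            "score": b.score,
        }
        for k, b in enumerate(b for boxes in boxes_by_image.values() for b in boxes)
    ]
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": c, "name": f"category_{c}"} for c in cats],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_boxes_tsv(path) -> dict[str, list[ObjectBox]]:
    """Flat TSV dialect: image_id, category, row0, col0, height, width, score."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ObjectBox]] = {}
    for rec in df.itertuples(index=False):
        box = ObjectBox(
            image_id=str(rec.image_id),
            category=int(rec.category),
            row0=int(rec.row0),
            col0=int(rec.col0),
            height=int(rec.height),
            width=int(rec.width),
            score=float(rec.score),
        )
        out.setdefault(box.image_id, []).append(box)
    return out


def write_boxes_tsv(path, boxes_by_image: dict[str, list[ObjectBox]]) -> None:
    rows = [
        {
            "image_id": b.image_id,
            "category": b.category,
            "row0": b.row0,
            "col0": b.col0,
            "height": b.height,
            "width": b.width,
            "score": b.score,
        }
        for boxes in boxes_by_image.values()
        for b in boxes
    ]
    pd.DataFrame(
        rows, columns=["image_id", "category", "row0", "col0", "height", "width", "score"]
    ).to_csv(path, sep="\t", index=False)
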