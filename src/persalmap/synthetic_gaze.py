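"""Synthetic analogue of a personalized-saliency gaze dataset.

Real personalized-saliency datasets pair free-viewing gaze from a panel of
persons with natural images containing detectable objects.  That structure
— not photorealism — is what the rest of the package needs for testing, so
the generator builds:

* scenes: a smooth textured background with colored rectangle/ellipse
  objects whose bounding boxes and category labels are exact ground truth;
* persons: latent per-category preference vectors, organized into clusters
  (clusters model groups of people with shared interests);
* attention maps: an additive model per person and image,

      PSM ∝ clip( b · base(X) + (1 − b) · Σ_boxes pref[cat] · bump(box) + ε, 0 ),

  where ``base`` is a shared center-bias plus object-presence map (the USM
  limit), ``bump`` is a Gaussian centered on a box, and ε is per-pixel
  Gaussian idiosyncrasy noise.  The additive form mirrors the
  PSM = USM + Δ decomposition the residual network learns, so the
  synthetic task is well-posed for every downstream module.

Everything is driven by ``numpy.random.SeedSequence``: the same seed
reproduces every pixel, box and profile bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention_maps import ImageRecord, SaliencyMap
from .adaptive_selection import ObjectBox

_BOX_RETRY_LIMIT = 100

#: Distinct base colors for object categories (cycled when M > 8).
_CATEGORY_COLORS = np.array(
    [
        [0.85, 0.2, 0.2],
        [0.2, 0.7, 0.25],
        [0.2, 0.35, 0.85],
        [0.9, 0.75, 0.15],
        [0.7, 0.25, 0.75],
        [0.15, 0.7, 0.7],
        [0.9, 0.5, 0.2],
        [0.55, 0.55, 0.55],
    ]
)


@dataclass(frozen=True)
class PersonProfile:
    """Latent viewer: per-category preference in [0,1] plus idiosyncrasy noise."""

    person_id: str
    preference: np.ndarray
    idiosyncrasy_noise: float = 0.03

    def __post_init__(self) -> None:
        pref = np.asarray(self.preference, dtype=float)
        if np.any(pref < 0) or np.any(pref > 1):
            raise ValueError("preferences must lie in [0, 1]")
        if self.idiosyncrasy_noise < 0:
            raise ValueError("noise level must be non-negative")
        object.__setattr__(self, "preference", pref)


@dataclass(frozen=True)
class ClusterSpec:
    """How panel persons group into preference clusters.

    ``active_categories`` lists the 1-based categories whose preference
    differs between clusters (None: all categories are cluster-specific);
    the rest share one panel-wide value.  ``jitter`` is the std of the
    within-cluster perturbation around the cluster prototype; ``min_sep``
    is the smallest allowed Euclidean distance between cluster prototypes
    (resampled until satisfied).
    """

    n_clusters: int = 3
    jitter: float = 0.05
    active_categories: tuple[int, ...] | None = None
    min_sep: float = 0.6

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass
class SyntheticDataset:
    """A complete synthetic panel: scenes, boxes, profiles and attention maps."""

    images: list[ImageRecord]
    boxes: dict[str, list[ObjectBox]]
    profiles: list[PersonProfile]
    psms: list[list[SaliencyMap]]  # [person][image]
    cluster_labels: tuple[int, ...]
    cluster_prototypes: np.ndarray  # (n_clusters, M)
    num_categories: int
    seed: int

    @property
    def num_persons(self) -> int:
        return len(self.profiles)

    @property
    def num_images(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

def _smooth_background(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency texture: a coarse random grid, bilinearly upsampled."""
    coarse = rng.uniform(0.25, 0.45, size=(4, 4, 3))
    rows = np.linspace(0, 3, height)
    cols = np.linspace(0, 3, width)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, 3)
    c1 = np.minimum(c0 + 1, 3)
    fr = (rows - r0)[:, None, None]
    fc = (cols - c0)[None, :, None]
    top = coarse[r0][:, c0] * (1 - fc) + coarse[r0][:, c1] * fc
    bot = coarse[r1][:, c0] * (1 - fc) + coarse[r1][:, c1] * fc
    return top * (1 - fr) + bot * fr


def generate_scene(
    height: int,
    width: int,
    n_objects: int,
    n_categories: int,
    seed: int | np.random.SeedSequence,
) -> tuple[ImageRecord, list[ObjectBox]]:
    """Draw a textured scene with ``n_objects`` labeled rectangle/ellipse objects.

    Boxes are exact ground truth; categories are uniform over 1..M.  Object
    sizes span roughly 1/8 to 1/3 of each image dimension; a box that
    cannot be placed in bounds after a bounded number of retries raises.
    """
    rng = np.random.default_rng(seed)
    img = _smooth_background(height, width, rng)
    image_id = f"scene_{rng.integers(0, 2**31):08x}"
    boxes: list[ObjectBox] = []
    for _ in range(n_objects):
        for _attempt in range(_BOX_RETRY_LIMIT):
            h = int(rng.integers(max(2, height // 8), max(3, height // 3)))
            w = int(rng.integers(max(2, width // 8), max(3, width // 3)))
            if h <= height and w <= width:
                r0 = int(rng.integers(0, height - h + 1))
                c0 = int(rng.integers(0, width - w + 1))
                break
        else:
            raise RuntimeError(f"could not place a {n_objects}-object scene in {height}x{width}")
        category = int(rng.integers(1, n_categories + 1))
        color = _CATEGORY_COLORS[(category - 1) % len(_CATEGORY_COLORS)]
        shade = color * rng.uniform(0.8, 1.0)
        if rng.random() < 0.5:  # rectangle
            img[r0:r0 + h, c0:c0 + w] = shade
        else:  # ellipse inscribed in the box
            rr = (np.arange(height)[:, None] - (r0 + (h - 1) / 2)) / (h / 2)
            cc = (np.arange(width)[None, :] - (c0 + (w - 1) / 2)) / (w / 2)
            img[rr**2 + cc**2 <= 1.0] = shade
        boxes.append(ObjectBox(image_id, category, r0, c0, h, w, score=1.0))
    return ImageRecord(image_id, np.clip(img, 0.0, 1.0)), boxes


# ---------------------------------------------------------------------------
# Attention maps
# ---------------------------------------------------------------------------

def _gaussian_bump(height: int, width: int, box: ObjectBox, sigma: float) -> np.ndarray:
    """Unit-peak Gaussian centered on the box; widths scale with box size."""
    rc = box.row0 + (box.height - 1) / 2
    cc = box.col0 + (box.width - 1) / 2
    sr = max(sigma * box.height, 0.5)
    sc = max(sigma * box.width, 0.5)
    dr = (np.arange(height)[:, None] - rc) / sr
    dc = (np.arange(width)[None, :] - cc) / sc
    return np.exp(-0.5 * (dr**2 + dc**2))


def shared_base_map(scene: ImageRecord, boxes: list[ObjectBox], sigma: float = 0.15) -> np.ndarray:
    """Person-agnostic attention: center bias + uniform object presence.

    Deterministic in the scene, so every person shares it — this is the
    synthetic USM limit when preferences and noise vanish.
    """
    H, W = scene.height, scene.width
    dr = (np.arange(H)[:, None] - (H - 1) / 2) / (H / 4)
    dc = (np.arange(W)[None, :] - (W - 1) / 2) / (W / 4)
    base = np.exp(-0.5 * (dr**2 + dc**2))
    for box in boxes:
        base += 0.5 * _gaussian_bump(H, W, box, sigma)
    return base / base.max()


def generate_psm(
    scene: ImageRecord,
    boxes: list[ObjectBox],
    profile: PersonProfile,
    base_weight: float = 0.15,
    sigma: float = 0.15,
    seed: int | np.random.SeedSequence = 0,
) -> SaliencyMap:
    """One person's attention map for one scene.

    ``base_weight`` ∈ [0,1] balances the shared base map against the
    person's preference-weighted object bumps; ``sigma`` scales bump widths
    relative to box size.  Truncated Gaussian pixel noise with std
    ``profile.idiosyncrasy_noise`` is added before clipping at zero and
    unit-max normalization.
    """
    if not (0.0 <= base_weight <= 1.0):
        raise ValueError("base_weight must lie in [0, 1]")
    H, W = scene.height, scene.width
    rng = np.random.default_rng(seed)
    base = shared_base_map(scene, boxes, sigma)
    pref = np.zeros((H, W))
    for box in boxes:
        pref += profile.preference[box.category - 1] * _gaussian_bump(H, W, box, sigma)
    vals = base_weight * base + (1.0 - base_weight) * pref
    if profile.idiosyncrasy_noise > 0:
        vals = vals + rng.normal(0.0, profile.idiosyncrasy_noise, size=(H, W))
    vals = np.clip(vals, 0.0, None)
    mx = vals.max()
    if mx > 0:
        vals = vals / mx
    return SaliencyMap(scene.image_id, vals, "unit_max")


# ---------------------------------------------------------------------------
# Panels and datasets
# ---------------------------------------------------------------------------

def sample_cluster_prototypes(
    M: int, spec: ClusterSpec, rng: np.random.Generator
) -> np.ndarray:
    """(n_clusters, M) preference prototypes, resampled until separated.

    Preferences are sparse: each cluster attends strongly (0.7–1.0) to
    roughly a third of the active categories and weakly (≤ 0.15) to the
    rest — viewers fixate the object kinds they care about and largely
    ignore others, which is what makes person similarity informative.
    """
    active = (
        np.arange(1, M + 1) if spec.active_categories is None
        else np.asarray(spec.active_categories)
    )
    shared = rng.uniform(0.0, 0.15, size=M)
    for _ in range(_BOX_RETRY_LIMIT):
        protos = np.tile(shared, (spec.n_clusters, 1))
        for k in range(spec.n_clusters):
            n_pref = max(1, len(active) // 3)
            chosen = rng.choice(active, size=n_pref, replace=False)
            protos[k, chosen - 1] = rng.uniform(0.7, 1.0, size=n_pref)
        if spec.n_clusters == 1:
            return protos
        dists = [
            np.linalg.norm(protos[i] - protos[j])
            for i in range(spec.n_clusters)
            for j in range(i + 1, spec.n_clusters)
        ]
        if min(dists) >= spec.min_sep:
            return protos
    return protos  # best effort when the separation demand is infeasible


def profile_from_prototype(
    person_id: str,
    prototype: np.ndarray,
    jitter: float,
    rng: np.random.Generator,
    idiosyncrasy_noise: float = 0.03,
) -> PersonProfile:
    """Perturb a cluster prototype into one person's preference vector."""
    pref = np.clip(prototype + rng.normal(0.0, jitter, size=len(prototype)), 0.0, 1.0)
    return PersonProfile(person_id, pref, idiosyncrasy_noise)


def generate_dataset(
    P: int,
    N: int,
    M: int,
    cluster_spec: ClusterSpec | None = None,
    seed: int = 0,
    height: int = 64,
    width: int = 64,
    objects_per_image: tuple[int, int] = (2, 5),
    base_weight: float = 0.15,
    idiosyncrasy_noise: float = 0.03,
    sigma: float = 0.15,
) -> SyntheticDataset:
    """Build a full synthetic panel dataset.

    Persons are assigned to clusters round-robin; ground-truth cluster
    labels and prototypes are retained so recovery experiments can check
    themselves.  The same ``seed`` reproduces every field bit-exactly.
    """
    spec = cluster_spec or ClusterSpec()
    ss = np.random.SeedSequence(seed)
    ss_proto, ss_profiles, ss_scenes, ss_noise = ss.spawn(4)

    rng_proto = np.random.default_rng(ss_proto)
    prototypes = sample_cluster_prototypes(M, spec, rng_proto)
    labels = tuple(i % spec.n_clusters for i in range(P))

    rng_prof = np.random.default_rng(ss_profiles)
    profiles = [
        profile_from_prototype(
            f"person_{i:02d}", prototypes[labels[i]], spec.jitter, rng_prof, idiosyncrasy_noise
        )
        for i in range(P)
    ]

    images: list[ImageRecord] = []
    boxes: dict[str, list[ObjectBox]] = {}
    scene_seeds = ss_scenes.spawn(N)
    for n in range(N):
        rng_n = np.random.default_rng(scene_seeds[n])
        n_obj = int(rng_n.integers(objects_per_image[0], objects_per_image[1] + 1))
        img, bx = generate_scene(height, width, n_obj, M, scene_seeds[n].spawn(1)[0])
        images.append(img)
        boxes[img.image_id] = bx

    noise_seeds = ss_noise.spawn(P * N)
    psms = [
        [
            generate_psm(
                images[n], boxes[images[n].image_id], profiles[p],
                base_weight=base_weight, sigma=sigma, seed=noise_seeds[p * N + n],
            )
            for n in range(N)
        ]
        for p in range(P)
    ]
    return SyntheticDataset(
        images=images,
        boxes=boxes,
        profiles=profiles,
        psms=psms,
        cluster_labels=labels,
        cluster_prototypes=prototypes,
        num_categories=M,
        seed=seed,
    )


def generate_target_person(
    dataset: SyntheticDataset,
    cluster_index: int,
    jitter: float,
    seed: int | np.random.SeedSequence,
    person_id: str = "target",
    idiosyncrasy_noise: float = 0.03,
) -> PersonProfile:
    """Sample a held-out person from one of the dataset's clusters."""
    rng = np.random.default_rng(seed)
    return profile_from_prototype(
        person_id, dataset.cluster_prototypes[cluster_index], jitter, rng, idiosyncrasy_noise
    )


def target_psms(
    dataset: SyntheticDataset,
    profile: PersonProfile,
    image_indices,
    seed: int | np.random.SeedSequence,
    base_weight: float = 0.15,
    sigma: float = 0.15,
) -> list[SaliencyMap]:
    """The held-out person's attention maps on a subset of the dataset's images."""
    indices = list(image_indices)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(indices))
    out = []
    for s, n in zip(seeds, indices):
        img = dataset.images[n]
        out.append(
            generate_psm(img, dataset.boxes[img.image_id], profile, base_weight, sigma, s)
        )
    return out
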