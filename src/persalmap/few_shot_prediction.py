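"""Few-shot personalized saliency prediction (FPSP).

A new person views only the C selected images.  Their attention maps on
those images are correlated with each panel member's *predicted* maps to
give a similarity score β_p (mean per-image Pearson correlation); panel
members with β_p above a threshold τ are kept (strict inequality, so
β_p = τ is rejected), scores are normalized into convex weights

    w_p = a_p β_p / Σ_{p'} a_{p'} β_{p'},   a_p = 1[β_p > τ],

and the new person's map for an unseen image is the weighted combination
Σ_p w_p S_out(p, X_tgt) of panel predictions.  If nobody clears τ, the
prediction falls back to the person-agnostic USM — the method's own limit
when no similar person exists.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .attention_maps import SaliencyMap, metric_cc, ConstantMapError, ShapeMismatchError

logger = logging.getLogger("persalmap")

DEFAULT_TAU = 0.7


@dataclass(frozen=True)
class SimilarityProfile:
    """Similarity of one target person to each of the P panel members."""

    target_person_id: str
    beta: np.ndarray  # (P,) mean correlations in [-1, 1]
    a: np.ndarray  # (P,) 0/1 selection coefficients
    w: np.ndarray  # (P,) convex weights (all zero when nobody clears tau)
    tau: float

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        a = np.asarray(self.a, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if not (beta.shape == a.shape == w.shape):
            raise ValueError("beta, a, w must share length P")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "w", w)

    @property
    def any_similar(self) -> bool:
        return bool(self.a.any())

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_person_id": self.target_person_id,
                "tau": self.tau,
                "beta": [None if np.isnan(b) else b for b in self.beta.tolist()],
                "a": self.a.astype(int).tolist(),
                "w": self.w.tolist(),
            },
            indent=1,
        )


def _corr(a: SaliencyMap, b: SaliencyMap, mode: str) -> float:
    if mode == "pearson":
        return metric_cc(a, b)
    if mode == "cross":
        # unnormalized cross-correlation, rescaled by map energies
        av, bv = a.values.ravel(), b.values.ravel()
        denom = np.linalg.norm(av) * np.linalg.norm(bv)
        if denom == 0:
            raise ConstantMapError("cross-correlation undefined for an all-zero map")
        return float(av @ bv / denom)
    raise ValueError(f"unknown correlation mode {mode!r}")


def similarity_scores(
    target_maps: Sequence[SaliencyMap],
    panel_predictions: Sequence[Sequence[SaliencyMap]],
    corr_mode: str = "pearson",
) -> np.ndarray:
    """Mean per-image correlation of the target's maps with each panel member's.

    ``target_maps`` holds the target person's maps on the C selected
    images; ``panel_predictions[p]`` holds person p's predicted maps on the
    same C images in the same order.  A constant map in any pair makes that
    image's term undefined; it is skipped (with a warning) and the mean is
    taken over the remaining images.  A person with no valid term gets NaN.
    """
    C = len(target_maps)
    if C < 1:
        raise ValueError("need at least one selected image")
    betas = []
    for p, preds in enumerate(panel_predictions):
        if len(preds) != C:
            raise ValueError(f"panel member {p} has {len(preds)} maps, expected {C}")
        terms = []
        for c, (tm, pm) in enumerate(zip(target_maps, preds)):
            try:
                terms.append(_corr(tm, pm, corr_mode))
            except ConstantMapError:
                logger.warning(
                    "constant map for panel member %d on selected image %d; term skipped", p, c
                )
        betas.append(float(np.mean(terms)) if terms else float("nan"))
    return np.asarray(betas)


def selection_coefficients(beta: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """0/1 mask of panel members strictly above the similarity threshold."""
    beta = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        return (beta > tau).astype(float)  # NaN compares False: dissimilar


def person_weights(beta: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Normalize the thresholded similarities into convex weights.

    Negative contributions (possible only for a user-set τ < 0) are clamped
    at zero before normalization so the final combination stays convex.
    Returns the all-zero vector when no panel member is selected; callers
    treat that as the USM-fallback condition.
    """
    beta = np.asarray(beta, dtype=float)
    a = np.asarray(a, dtype=float)
    contrib = np.where(np.isnan(beta), 0.0, a * beta)
    contrib = np.clip(contrib, 0.0, None)
    total = contrib.sum()
    if total <= 0:
        logger.warning("no panel member above threshold; weights are zero (USM fallback)")
        return np.zeros_like(contrib)
    return contrib / total


def build_similarity_profile(
    target_person_id: str,
    target_maps: Sequence[SaliencyMap],
    panel_predictions: Sequence[Sequence[SaliencyMap]],
    tau: float = DEFAULT_TAU,
    corr_mode: str = "pearson",
) -> SimilarityProfile:
    """Full β → a → w chain for one target person."""
    beta = similarity_scores(target_maps, panel_predictions, corr_mode)
    a = selection_coefficients(beta, tau)
    w = person_weights(beta, a)
    return SimilarityProfile(target_person_id, beta, a, w, tau)


def predict_fpsp(
    weights: np.ndarray, panel_maps_for_target: Sequence[SaliencyMap]
) -> SaliencyMap:
    """Convex combination Σ_p w_p S_out(p, X_tgt) of panel predictions."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(panel_maps_for_target):
        raise ValueError("one weight per panel map required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1 (USM fallback is handled by the caller)")
    first = panel_maps_for_target[0]
    for m in panel_maps_for_target[1:]:
        if m.shape != first.shape:
            raise ShapeMismatchError(f"panel map shapes differ: {first.shape} vs {m.shape}")
    acc = np.zeros(first.shape)
    for wp, m in zip(weights, panel_maps_for_target):
        if wp:
            acc += wp * m.values
    return SaliencyMap(first.image_id, np.clip(acc, 0.0, None), "raw")


def predict_for_person(
    profile: SimilarityProfile,
    panel_maps_for_target: Sequence[SaliencyMap],
    usm: SaliencyMap,
) -> SaliencyMap:
    """FPSP prediction with the all-dissimilar fallback to the USM."""
    if not profile.any_similar or profile.w.sum() <= 0:
        logger.info(
            "target %s: no similar panel member (tau=%.3g); returning USM",
            profile.target_person_id, profile.tau,
        )
        return dataclasses.replace(usm, norm_mode="raw")
    return predict_fpsp(profile.w, panel_maps_for_target)
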