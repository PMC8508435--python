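"""Seeded rotation/flip/crop augmentation, balancing, and soft-vote TTA.

Three pieces of the experimental protocol live here:

* random augmentation (rotation, horizontal/vertical flip, crop with
  resize-back) used to enlarge training data;
* class balancing — the minority class is oversampled with freshly
  augmented copies until the class counts are approximately equal;
* test-time augmentation (TTA) — each test image is augmented 10 times,
  every replicate stays linked to its source image, and the per-view class
  probabilities are combined by soft voting (element-wise mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate

from .data import LabeledImageSet

__all__ = [
    "AugmentationPolicy",
    "TTABundle",
    "augment_image",
    "balance_by_augmentation",
    "expand_test_image",
    "lengths_to_probabilities",
    "soft_vote",
]

#: Replicates per test image in the TTA protocol.
TTA_REPLICATES = 10


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ranges from which each augmentation draw is sampled.

    ``rotation_degrees`` is a closed interval in [-180, 180];
    ``crop_fraction`` the interval of the retained side fraction (the crop
    is resized back to the original size).  ``seed`` roots every stream of
    draws; combined with a per-image draw seed it makes augmentation fully
    reproducible.
    """

    rotation_degrees: tuple[float, float] = (-180.0, 180.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    crop_fraction: tuple[float, float] = (0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_degrees
        if not (-180.0 <= lo <= hi <= 180.0):
            raise ValueError(f"rotation range {self.rotation_degrees} outside [-180, 180]")
        lo, hi = self.crop_fraction
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"crop_fraction {self.crop_fraction} must lie in (0, 1]")

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentationPolicy":
        return cls((0.0, 0.0), False, False, (1.0, 1.0), seed)


@dataclass
class TTABundle:
    """The augmented views of one test image, linked to their source."""

    source_id: str
    original: np.ndarray
    replicates: list[np.ndarray] = field(default_factory=list)

    @property
    def replicate_count(self) -> int:
        return len(self.replicates)

    def views(self, include_original: bool = True) -> list[np.ndarray]:
        return ([self.original] if include_original else []) + list(self.replicates)


def _rng_for(policy: AugmentationPolicy, draw_seed: int) -> np.random.Generator:
    return np.random.default_rng([policy.seed & 0x7FFFFFFF, draw_seed & 0x7FFFFFFF])


def augment_image(
    image: np.ndarray, policy: AugmentationPolicy, draw_seed: int = 0
) -> np.ndarray:
    """One random rotation + flip decision(s) + crop, resized back.

    Rotation uses reflect padding at the borders (keeps skin texture,
    avoids black corners).  The identity policy returns the input
    unchanged, bit for bit.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (h, w, 3) image, got shape {image.shape}")
    rng = _rng_for(policy, draw_seed)
    h, w = image.shape[:2]
    out = image

    angle = rng.uniform(*policy.rotation_degrees)
    if angle != 0.0:
        out = rotate(out, angle, mode="reflect", order=1, preserve_range=True)

    if policy.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if policy.vertical_flip and rng.random() < 0.5:
        out = out[::-1]

    frac = rng.uniform(*policy.crop_fraction)
    ch, cw = max(1, round(h * frac)), max(1, round(w * frac))
    if (ch, cw) != (h, w):
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        out = resize(out[top : top + ch, left : left + cw], (h, w), order=1,
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def balance_by_augmentation(
    data: LabeledImageSet, policy: AugmentationPolicy
) -> LabeledImageSet:
    """Oversample the minority class with augmented copies.

    New images are created from uniformly drawn (with replacement)
    minority-class sources until the class counts differ by at most one;
    the majority class is untouched and no original image is ever removed.
    Each new image's ``origin_id`` names its source.
    """
    n0, n1 = data.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("cannot balance: one class has no images")
    minority = 1 if n1 < n0 else 0
    deficit = abs(n0 - n1)
    if deficit <= 1:
        return data
    src_idx = np.flatnonzero(data.labels == minority)
    rng = np.random.default_rng(policy.seed)
    images = list(data.images)
    labels = list(data.labels)
    ids = list(data.ids)
    origin_ids = list(data.origin_ids)
    for k in range(deficit):
        i = int(rng.choice(src_idx))
        draw = int(rng.integers(0, 2**31 - 1))
        images.append(augment_image(data.images[i], policy, draw))
        labels.append(minority)
        ids.append(f"{data.ids[i]}#bal{k:04d}")
        origin_ids.append(data.ids[i])
    return LabeledImageSet(images=images, labels=np.asarray(labels), ids=ids, origin_ids=origin_ids)


def expand_test_image(
    image: np.ndarray,
    policy: AugmentationPolicy,
    source_id: str,
    n_replicates: int = TTA_REPLICATES,
) -> TTABundle:
    """Build the TTA bundle: the original plus ``n_replicates`` augmented copies.

    Replicate draws are keyed on (policy seed, source id, replicate index),
    so the full bundle is reproducible from its inputs.
    """
    image = np.asarray(image, dtype=float)
    base = abs(hash(("tta", source_id))) % (2**31 - 1)
    reps = [augment_image(image, policy, base + r) for r in range(n_replicates)]
    return TTABundle(source_id=source_id, original=image, replicates=reps)


def lengths_to_probabilities(lengths: np.ndarray) -> np.ndarray:
    """Normalise class-capsule lengths to probabilities by their sum.

    Capsule lengths do not sum to one, so each row is divided by its sum;
    an all-zero row falls back to the uninformative (0.5, 0.5).
    """
    lengths = np.atleast_2d(np.asarray(lengths, dtype=float))
    tot = lengths.sum(axis=1, keepdims=True)
    out = np.where(tot > 0, lengths / np.maximum(tot, 1e-300), 1.0 / lengths.shape[1])
    return out


def soft_vote(probabilities) -> tuple[int, np.ndarray]:
    """Average per-view class probabilities and take the argmax.

    An exact tie goes to class 0 (nevus).  Each input pair must already be
    normalised (sum to one within 1e-6).
    """
    probs = np.asarray(list(probabilities), dtype=float)
    if probs.size == 0:
        raise ValueError("soft_vote needs at least one probability pair")
    if probs.ndim != 2:
        raise ValueError(f"expected a list of per-class probability rows, got {probs.shape}")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each probability pair must sum to 1 within 1e-6")
    mean = probs.mean(axis=0)
    label = int(np.argmax(mean))
    # argmax takes the first maximum, so an exact tie already yields 0
    return label, mean
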