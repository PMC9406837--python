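"""Stratified splitting and deterministic training-set augmentation.

The split follows an 80/20 then 80/20 rule applied per class with floor
rounding at both levels: first 20% of each class is held out for testing,
then the remaining 80% is split again into training (80%) and validation
(20%). For the two-class slide collection of 2494 normal / 2698 malignant
images this yields exactly 1596/399/499 and 1726/432/540
train/val/test counts.

Augmentation multiplies every *training* image by a fixed menu of 12
deterministic geometric variants (rotations, flips, 10% shifts, and
rotations of the horizontal flip); validation and test images are never
augmented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .synthetic import LabeledImageSet

__all__ = [
    "SplitAssignment",
    "AugmentedSet",
    "split_counts",
    "stratified_split",
    "TRANSFORM_NAMES",
    "apply_transform",
    "augment_image",
    "augment_training_set",
]

PHASES = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Per-image phase labels plus the seed that produced them."""

    phase: dict[str, str]
    seed: int

    def ids_in_phase(self, phase: str) -> list[str]:
        return [i for i, p in self.phase.items() if p == phase]

    def counts(self, labels: Mapping[str, str]) -> dict[str, dict[str, int]]:
        """Per-class, per-phase counts given an id -> label mapping."""
        out: dict[str, dict[str, int]] = {}
        for img_id, phase in self.phase.items():
            cls = labels[img_id]
            out.setdefault(cls, {p: 0 for p in PHASES})[phase] += 1
        return out


def split_counts(n: int) -> tuple[int, int, int]:
    """(train, val, test) counts for a class of size ``n`` under the
    floor-rounded 80/20 -> 80/20 rule."""
    trainval = math.floor(0.8 * n)
    test = n - trainval
    train = math.floor(0.8 * trainval)
    val = trainval - train
    return train, val, test


def stratified_split(labels: Sequence[str] | Mapping[str, str],
                     seed: int, ids: Sequence[str] | None = None) -> SplitAssignment:
    """Assign each id to train/val/test, stratified by class.

    ``labels`` may be a sequence (paired with ``ids``, or positional ids)
    or a mapping id -> label. Membership within a class is a seeded
    uniform permutation; counts follow :func:`split_counts`.
    """
    if isinstance(labels, Mapping):
        id_label = list(labels.items())
    else:
        if ids is None:
            ids = [f"img{i:05d}" for i in range(len(labels))]
        if len(ids) != len(labels):
            raise ValueError("ids and labels must have equal length")
        id_label = list(zip(ids, labels))

    by_class: dict[str, list[str]] = {}
    for img_id, label in id_label:
        by_class.setdefault(label, []).append(img_id)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 images")

    rng = np.random.default_rng(seed)
    phase: dict[str, str] = {}
    for cls in sorted(by_class):
        members = by_class[cls]
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n_train, n_val, _ = split_counts(len(members))
        for rank, img_id in enumerate(shuffled):
            if rank < n_train:
                phase[img_id] = "train"
            elif rank < n_train + n_val:
                phase[img_id] = "val"
            else:
                phase[img_id] = "test"
    return SplitAssignment(phase=phase, seed=seed)


# --- augmentation -----------------------------------------------------------

TRANSFORM_NAMES = (
    "rot90", "rot180", "rot270",
    "fliph", "flipv",
    "shift_x_pos", "shift_x_neg", "shift_y_pos", "shift_y_neg",
    "fliph_rot90", "fliph_rot180", "fliph_rot270",
)

SHIFT_FRACTION = 0.10


def _shift(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer-pixel translation with reflect fill (no interpolation)."""
    h, w = img.shape[:2]
    pad = [(abs(dy), abs(dy)), (abs(dx), abs(dx))] + [(0, 0)] * (img.ndim - 2)
    padded = np.pad(img, pad, mode="reflect")
    y0 = abs(dy) - dy
    x0 = abs(dx) - dx
    return padded[y0:y0 + h, x0:x0 + w]


def apply_transform(img: np.ndarray, name: str) -> np.ndarray:
    h, w = img.shape[:2]
    sy = max(1, int(round(SHIFT_FRACTION * h)))
    sx = max(1, int(round(SHIFT_FRACTION * w)))
    if name == "rot90":
        return np.rot90(img, 1).copy()
    if name == "rot180":
        return np.rot90(img, 2).copy()
    if name == "rot270":
        return np.rot90(img, 3).copy()
    if name == "fliph":
        return img[:, ::-1].copy()
    if name == "flipv":
        return img[::-1].copy()
    if name == "shift_x_pos":
        return _shift(img, 0, sx)
    if name == "shift_x_neg":
        return _shift(img, 0, -sx)
    if name == "shift_y_pos":
        return _shift(img, sy, 0)
    if name == "shift_y_neg":
        return _shift(img, -sy, 0)
    if name.startswith("fliph_rot"):
        k = {"fliph_rot90": 1, "fliph_rot180": 2, "fliph_rot270": 3}[name]
        return np.rot90(img[:, ::-1], k).copy()
    raise ValueError(f"unknown transform {name!r}")


def augment_image(img: np.ndarray) -> list[np.ndarray]:
    """The 12 deterministic variants of one image, in menu order."""
    return [apply_transform(img, name) for name in TRANSFORM_NAMES]


@dataclass
class AugmentedSet:
    """Derived images with provenance (source id, transform name)."""

    images: list[np.ndarray]
    labels: list[str]
    ids: list[str]
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


def augment_training_set(dataset: LabeledImageSet,
                         split: SplitAssignment | None = None) -> AugmentedSet:
    """Produce exactly 12 variants per input image.

    If ``split`` is given, every input id must be in the training phase;
    validation/test ids raise ValueError so augmented copies can never
    leak into evaluation.
    """
    if split is not None:
        for img_id in dataset.ids:
            if split.phase.get(img_id) != "train":
                raise ValueError(f"id {img_id!r} is not a training-phase image")
    images: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    provenance: list[tuple[str, str]] = []
    for img, label, img_id in zip(dataset.images, dataset.labels, dataset.ids):
        for name in TRANSFORM_NAMES:
            images.append(apply_transform(img, name))
            labels.append(label)
            ids.append(f"{img_id}__{name}")
            provenance.append((img_id, name))
    return AugmentedSet(images=images, labels=labels, ids=ids, provenance=provenance)
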