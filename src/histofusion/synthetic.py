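"""Seeded synthetic two-class histology-like images.

Real H&E slides of oral mucosa show a pink/purple palette: eosin-stained
cytoplasm and stroma (pink) dotted with hematoxylin-stained nuclei (dark
purple). Malignant tissue is typically more cellular (denser, more
pleomorphic nuclei) and stains darker overall. The generator emulates just
enough of this — a per-class base color, soft-edged dark "nuclei" disks, a
low-frequency sinusoidal texture, and Gaussian pixel noise — for color and
texture descriptors to separate the two classes. It makes the whole
pipeline exercisable offline, with full bitwise reproducibility from
(spec, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ClassParams",
    "SyntheticSpec",
    "LabeledImageSet",
    "separable_spec",
    "hard_spec",
    "generate_dataset",
    "read_image",
    "write_image",
    "write_manifest",
    "read_manifest",
]

NORMAL = "normal"
MALIGNANT = "malignant"


@dataclass(frozen=True)
class ClassParams:
    """Rendering parameters for one tissue class.

    base_color      : RGB triple in [0, 255], the background stain color.
    blob_density    : nuclei blobs per 10^4 pixels (>= 0).
    blob_radius_range : (min, max) blob radius in pixels.
    texture_freq    : cycles per image of the sinusoidal texture (0 = none).
    noise_sd        : SD of additive Gaussian pixel noise, intensity units.
    """

    base_color: tuple[float, float, float]
    blob_density: float = 4.0
    blob_radius_range: tuple[float, float] = (3.0, 7.0)
    texture_freq: float = 6.0
    noise_sd: float = 8.0

    def __post_init__(self):
        if self.blob_density < 0:
            raise ValueError("blob_density must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a two-class synthetic data set."""

    class_params: dict[str, ClassParams]
    image_size: tuple[int, int] = (227, 227)
    seed: int = 0

    def __post_init__(self):
        if set(self.class_params) != {NORMAL, MALIGNANT}:
            raise ValueError(
                f"class_params must define exactly {{{NORMAL!r}, {MALIGNANT!r}}}"
            )


@dataclass
class LabeledImageSet:
    """Images with aligned labels and unique string ids."""

    images: list[np.ndarray]
    labels: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.images) == len(self.labels)):
            raise ValueError("images and labels must have equal length")
        if not self.ids:
            self.ids = [f"img{i:05d}" for i in range(len(self.images))]
        if len(self.ids) != len(self.images):
            raise ValueError("ids length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    def __len__(self) -> int:
        return len(self.images)


def separable_spec(image_size: tuple[int, int] = (227, 227), seed: int = 0) -> SyntheticSpec:
    """Preset with clearly distinct classes.

    Normal: light pink, sparse nuclei, gentle texture. Malignant: darker
    purple (lower blue and red), denser nuclei, busier texture.
    """
    return SyntheticSpec(
        class_params={
            NORMAL: ClassParams(
                base_color=(225.0, 170.0, 205.0),
                blob_density=3.0,
                blob_radius_range=(3.0, 6.0),
                texture_freq=4.0,
                noise_sd=8.0,
            ),
            MALIGNANT: ClassParams(
                base_color=(140.0, 70.0, 150.0),
                blob_density=9.0,
                blob_radius_range=(2.0, 5.0),
                texture_freq=10.0,
                noise_sd=8.0,
            ),
        },
        image_size=image_size,
        seed=seed,
    )


def hard_spec(image_size: tuple[int, int] = (227, 227), seed: int = 0) -> SyntheticSpec:
    """Preset with overlapping classes: small color gap, similar texture,
    heavier noise. Useful for exercising the non-trivial regime."""
    return SyntheticSpec(
        class_params={
            NORMAL: ClassParams(
                base_color=(200.0, 150.0, 185.0),
                blob_density=5.0,
                blob_radius_range=(3.0, 6.0),
                texture_freq=6.0,
                noise_sd=20.0,
            ),
            MALIGNANT: ClassParams(
                base_color=(190.0, 138.0, 175.0),
                blob_density=6.5,
                blob_radius_range=(3.0, 6.0),
                texture_freq=7.0,
                noise_sd=20.0,
            ),
        },
        image_size=image_size,
        seed=seed,
    )


def _render_image(params: ClassParams, size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(params.base_color, dtype=np.float64)

    if params.texture_freq > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        angle = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        coord = (np.cos(angle) * xx / w + np.sin(angle) * yy / h)
        wave = np.sin(2 * np.pi * params.texture_freq * coord + phase)
        img += (10.0 * wave)[:, :, None]

    n_blobs = int(round(params.blob_density * h * w / 1e4))
    if n_blobs > 0:
        # nuclei: darker version of the base color with a purple cast
        blob_color = 0.35 * np.asarray(params.base_color) + np.array([10.0, 0.0, 25.0])
        rmin, rmax = params.blob_radius_range
        for _ in range(n_blobs):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            r = rng.uniform(rmin, rmax)
            # Gaussian-soft disk, evaluated on its 3r support window:
            # ~1 inside the radius, smooth falloff at the edge
            ext = int(np.ceil(3 * r))
            y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
            x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            mask = np.exp(-0.5 * d2 / (0.5 * r) ** 2)
            patch = img[y0:y1, x0:x1]
            patch += mask[:, :, None] * (blob_color - patch)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)

    return np.clip(img, 0.0, 255.0)


def generate_dataset(spec: SyntheticSpec, n_per_class: int) -> LabeledImageSet:
    """Render ``n_per_class`` images for each class.

    The output is a pure function of ``(spec, n_per_class)``: a single
    ``numpy`` generator seeded from ``spec.seed`` drives every random
    choice, consumed in a fixed class-then-index order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    for label in (NORMAL, MALIGNANT):
        params = spec.class_params[label]
        for i in range(n_per_class):
            images.append(_render_image(params, spec.image_size, rng))
            labels.append(label)
            ids.append(f"{label}_{i:05d}")
    return LabeledImageSet(images=images, labels=labels, ids=ids)


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Save an RGB image as PNG/JPEG (by extension). Values are rounded
    and clamped to uint8; PNG round-trips losslessly."""
    arr = np.clip(np.asarray(img), 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/JPEG image as an H×W×3 float64 array in [0, 255]."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.float64)
    except (FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot read image file: {path}") from exc


def write_manifest(dataset: LabeledImageSet, directory: str | os.PathLike) -> str:
    """Write images as PNGs plus a ``manifest.csv`` (id,path,label)."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for img, label, img_id in zip(dataset.images, dataset.labels, dataset.ids):
        path = os.path.join(directory, f"{img_id}.png")
        write_image(img, path)
        rows.append({"id": img_id, "path": path, "label": label})
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | os.PathLike) -> LabeledImageSet:
    """Load a dataset back from a ``manifest.csv`` written by
    :func:`write_manifest` (or any CSV with id,path,label columns)."""
    df = pd.read_csv(path)
    missing = {"id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    images = [read_image(p) for p in df["path"]]
    return LabeledImageSet(images=images, labels=list(df["label"]), ids=[str(i) for i in df["id"]])
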