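"""Deep-feature stage: CNN primitives and fixed-width backbones.

The classification heads consume a 4096-dimensional deep descriptor per
image. Three backbones satisfy that contract:

* ``stub``    — a seeded fixed linear map applied to the 32×32-downsampled
  RGB pixels. Instant, fully deterministic; the workhorse for tests and
  desk-scale runs.
* ``minicnn`` — a small untrained conv/ReLU/max-pool stack (channels
  8, 16, 32, 3×3 filters) with seeded fixed weights, average-pooled and
  linearly mapped to the output width. Exercises the convolution
  primitives end to end.
* ``adapter:<id>`` — registry hook for pretrained backbones (AlexNet's
  fc7 naturally emits 4096 features; ResNet-18's penultimate width is
  512, so an adapter must name its extraction layer). No adapter ships by
  default; unknown ids raise :class:`ConfigurationError`.

The conv / pooling / ReLU primitives are written out explicitly (strided
sliding windows) because they are part of the package's testable surface,
each checked against brute-force loop oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .errors import ConfigurationError

__all__ = [
    "conv2d",
    "max_pool",
    "avg_pool",
    "relu",
    "BackboneSpec",
    "register_adapter",
    "extract_deep_features",
    "DEFAULT_OUTPUT_DIM",
]

DEFAULT_OUTPUT_DIM = 4096


def _as_chw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected a 2-D map or a C×H×W stack")
    return x


def conv2d(x: np.ndarray, filters: np.ndarray, stride: int = 1,
           zero_padding: int = 0) -> np.ndarray:
    """2-D cross-correlation of a C×H×W input with F filters.

    ``filters`` may be (kh, kw), (C, kh, kw) or (F, C, kh, kw). Output is
    F×H'×W' with H' = floor((H + 2·pad − kh)/stride) + 1.
    """
    x = _as_chw(x)
    f = np.asarray(filters, dtype=np.float64)
    if f.ndim == 2:
        f = np.broadcast_to(f, (1, x.shape[0]) + f.shape)
    elif f.ndim == 3:
        f = f[None]
    if f.ndim != 4:
        raise ValueError("filters must have 2, 3 or 4 dimensions")
    if f.shape[1] != x.shape[0]:
        raise ValueError("filter channel count does not match input")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    kh, kw = f.shape[2:]
    p = int(zero_padding)
    if p < 0:
        raise ValueError("zero_padding must be >= 0")
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    if kh > xp.shape[1] or kw > xp.shape[2]:
        raise ValueError("filter larger than the padded input")
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    return np.einsum("chwij,fcij->fhw", win, f, optimize=True)


def _pool(x: np.ndarray, k: int, stride: int, reducer: str) -> np.ndarray:
    x = _as_chw(x)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if k > x.shape[1] or k > x.shape[2]:
        raise ValueError("pooling window larger than the input")
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    if reducer == "max":
        return win.max(axis=(-2, -1))
    return win.mean(axis=(-2, -1))


def max_pool(x: np.ndarray, k: int, stride: int | None = None) -> np.ndarray:
    """Windowed maximum; ``stride`` defaults to ``k`` (non-overlapping)."""
    return _pool(x, k, stride if stride is not None else k, "max")


def avg_pool(x: np.ndarray, k: int, stride: int | None = None) -> np.ndarray:
    """Windowed arithmetic mean; ``stride`` defaults to ``k``."""
    return _pool(x, k, stride if stride is not None else k, "mean")


def relu(x: np.ndarray) -> np.ndarray:
    """Element-wise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


@dataclass(frozen=True)
class BackboneSpec:
    """Which deep-feature extractor to run and how it is seeded."""

    name: str = "stub"
    weights_seed: int = 0
    output_dim: int = DEFAULT_OUTPUT_DIM
    input_size: tuple[int, int] = (227, 227)

    def __post_init__(self):
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


_ADAPTERS: dict[str, Callable[[Sequence[np.ndarray], "BackboneSpec"], np.ndarray]] = {}


def register_adapter(adapter_id: str,
                     fn: Callable[[Sequence[np.ndarray], BackboneSpec], np.ndarray]) -> None:
    """Register a pretrained-backbone adapter.

    ``fn(images, spec)`` must return an n × spec.output_dim float matrix.
    Adapters are addressed as backbone name ``"adapter:<id>"``.
    """
    _ADAPTERS[adapter_id] = fn


def _resize_to(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.shape[:2] == tuple(size):
        return img
    return resize(img, size, order=1, anti_aliasing=True, preserve_range=True)


def _linear_map(seed: int, d_in: int, d_out: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)


def _stub_features(images: Sequence[np.ndarray], spec: BackboneSpec) -> np.ndarray:
    flat = np.stack([
        _resize_to(img, (32, 32)).reshape(-1) / 255.0 for img in images
    ])
    W = _linear_map(spec.weights_seed, flat.shape[1], spec.output_dim)
    return flat @ W


def _minicnn_features(images: Sequence[np.ndarray], spec: BackboneSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.weights_seed)
    channels = (3, 8, 16, 32)
    filters = [
        rng.standard_normal((channels[i + 1], channels[i], 3, 3))
        / np.sqrt(9 * channels[i])
        for i in range(3)
    ]
    feats = []
    W = None
    for img in images:
        x = _resize_to(img, spec.input_size).transpose(2, 0, 1) / 255.0
        for f in filters:
            x = max_pool(relu(conv2d(x, f, stride=1, zero_padding=1)), 2, 2)
        # coarse spatial summary before the fixed linear head
        k = max(1, min(x.shape[1], x.shape[2]) // 7)
        x = avg_pool(x, k, k)
        v = x.reshape(-1)
        if W is None:
            W = _linear_map(spec.weights_seed + 1, v.size, spec.output_dim)
        feats.append(v @ W)
    return np.stack(feats)


def extract_deep_features(images: Sequence[np.ndarray], spec: BackboneSpec) -> np.ndarray:
    """n × output_dim deep-feature matrix; a pure function of
    (pixel content, spec)."""
    if len(images) == 0:
        return np.zeros((0, spec.output_dim))
    if spec.name == "stub":
        return _stub_features(images, spec)
    if spec.name == "minicnn":
        return _minicnn_features(images, spec)
    if spec.name.startswith("adapter:"):
        adapter_id = spec.name.split(":", 1)[1]
        if adapter_id not in _ADAPTERS:
            raise ConfigurationError(
                f"no adapter registered under id {adapter_id!r}; "
                f"known: {sorted(_ADAPTERS) or 'none'}"
            )
        out = np.asarray(_ADAPTERS[adapter_id](images, spec), dtype=np.float64)
        if out.shape != (len(images), spec.output_dim):
            raise ConfigurationError(
                f"adapter {adapter_id!r} returned shape {out.shape}, "
                f"expected {(len(images), spec.output_dim)}"
            )
        return out
    raise ConfigurationError(f"unknown backbone {spec.name!r}")
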