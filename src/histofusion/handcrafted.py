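"""Handcrafted descriptor blocks: DWT, LBP, FCH and GLCM.

Each image is summarized by a fixed 244-value vector laid out as four
named blocks, always in this order:

* ``dwt``  (12)  — one-level orthonormal Haar decomposition into LL, LH,
  HL, HH subbands; per subband the mean, population variance and standard
  deviation. Captures coarse spatial-frequency energy.
* ``lbp``  (203) — local binary patterns over 5×5 neighborhoods: each
  interior pixel is compared with its 24 surrounding pixels (row-major),
  giving a 24-bit code; the code space [0, 2^24) is histogrammed into 203
  equal-width bins (last bin absorbs the remainder) and L1-normalized.
  A monotone gray-shift-invariant texture signature.
* ``fch``  (16)  — fuzzy color histogram on the hue circle: 16 evenly
  spaced bin centers; every pixel splits unit mass between its two
  nearest centers with triangular (linear) membership, with circular
  wraparound. Softens the hard bin boundaries of an ordinary color
  histogram.
* ``glcm`` (13)  — gray-level co-occurrence statistics at 8 gray levels:
  for each direction θ ∈ {0°, 45°, 90°, 135°} (offset distance 1 for the
  axial, √2 for the diagonal directions) the symmetric normalized
  co-occurrence matrix is built and Haralick's 13 statistics computed,
  then averaged over the four directions.

Gray conversion uses the fixed luminance weights (0.299, 0.587, 0.114)
and is performed once per image and shared by the DWT/LBP/GLCM blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from skimage.color import rgb2hsv

__all__ = [
    "BLOCK_LAYOUT",
    "TOTAL_FEATURES",
    "FeatureVector",
    "rgb_to_gray",
    "dwt_features",
    "lbp_code",
    "lbp_features",
    "fch_features",
    "glcm_matrix",
    "haralick_stats",
    "glcm_features",
    "handcrafted_features",
    "extract_handcrafted",
    "feature_names",
]

#: Immutable block layout: name -> (offset, length).
BLOCK_LAYOUT = {"dwt": (0, 12), "lbp": (12, 203), "fch": (215, 16), "glcm": (231, 13)}
TOTAL_FEATURES = 244

LBP_BINS = 203
LBP_CODE_SPACE = 2 ** 24
FCH_BINS = 16
GLCM_LEVELS = 8
GLCM_ANGLES = (0, 45, 90, 135)

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class FeatureVector:
    """A 244-value descriptor with the fixed block layout."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (TOTAL_FEATURES,):
            raise ValueError(f"expected {TOTAL_FEATURES} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def block(self, name: str) -> np.ndarray:
        off, length = BLOCK_LAYOUT[name]
        return self.values[off:off + length]


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance gray image in [0, 255] (float)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    return arr @ GRAY_WEIGHTS


# --- DWT -------------------------------------------------------------------

def dwt_features(gray: np.ndarray) -> np.ndarray:
    """12 statistics of the one-level Haar subbands (LL, LH, HL, HH);
    per subband: mean, population variance, standard deviation.

    Odd-sized images are reflect-padded to even dimensions first so the
    transform is orthonormal (Parseval holds exactly).
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("DWT requires a gray image of at least 2x2 pixels")
    pad_h = g.shape[0] % 2
    pad_w = g.shape[1] % 2
    if pad_h or pad_w:
        g = np.pad(g, ((0, pad_h), (0, pad_w)), mode="reflect")
    ll, (lh, hl, hh) = pywt.dwt2(g, "haar", mode="periodization")
    out = np.empty(12)
    for i, band in enumerate((ll, lh, hl, hh)):
        out[3 * i] = band.mean()
        out[3 * i + 1] = band.var()          # population variance
        out[3 * i + 2] = band.std()
    return out


# --- LBP -------------------------------------------------------------------

def lbp_code(gray: np.ndarray, center: tuple[int, int]) -> int:
    """24-bit local binary pattern of the 5×5 window around ``center``.

    Neighbors are the 24 non-center pixels of the window in row-major
    order; bit p is set when neighbor_p >= center (ties count as 1).
    """
    g = np.asarray(gray, dtype=np.float64)
    r, c = center
    if r < 2 or c < 2 or r > g.shape[0] - 3 or c > g.shape[1] - 3:
        raise ValueError("center must be at least 2 pixels from every border")
    gc = g[r, c]
    code = 0
    p = 0
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            if dr == 0 and dc == 0:
                continue
            if g[r + dr, c + dc] - gc >= 0:
                code |= 1 << p
            p += 1
    return code


def _lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Vectorized 24-bit codes for every valid (interior) center."""
    g = np.asarray(gray, dtype=np.float64)
    win = sliding_window_view(g, (5, 5))            # (H-4, W-4, 5, 5)
    flat = win.reshape(win.shape[0], win.shape[1], 25)
    center = flat[:, :, 12]
    codes = np.zeros(center.shape, dtype=np.int64)
    bit = 0
    for idx in range(25):
        if idx == 12:
            continue
        codes |= (flat[:, :, idx] >= center).astype(np.int64) << bit
        bit += 1
    return codes


def lbp_features(gray: np.ndarray) -> np.ndarray:
    """203-bin L1-normalized histogram of the 24-bit LBP codes."""
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2 or g.shape[0] < 5 or g.shape[1] < 5:
        raise ValueError("LBP requires a gray image of at least 5x5 pixels")
    codes = _lbp_codes(g).ravel()
    width = LBP_CODE_SPACE // LBP_BINS          # last bin absorbs the remainder
    idx = np.minimum(codes // width, LBP_BINS - 1)
    hist = np.bincount(idx, minlength=LBP_BINS).astype(np.float64)
    return hist / hist.sum()


# --- FCH -------------------------------------------------------------------

def fch_features(img: np.ndarray) -> np.ndarray:
    """16-bin fuzzy hue histogram, L1-normalized.

    Bin centers sit at hue j/16 (j = 0..15) on the unit hue circle; each
    pixel splits its unit mass linearly between the two nearest centers.
    Achromatic pixels (saturation exactly 0) are assigned to bin 0 by
    convention.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.size == 0:
        raise ValueError("FCH requires a non-empty RGB image")
    hsv = rgb2hsv(arr / 255.0)
    hue = hsv[:, :, 0].ravel()
    sat = hsv[:, :, 1].ravel()

    hist = np.zeros(FCH_BINS)
    chrom = sat > 0
    pos = hue[chrom] * FCH_BINS
    j = np.floor(pos).astype(int) % FCH_BINS
    frac = pos - np.floor(pos)
    np.add.at(hist, j, 1.0 - frac)
    np.add.at(hist, (j + 1) % FCH_BINS, frac)
    hist[0] += np.count_nonzero(~chrom)
    return hist / hist.sum()


# --- GLCM ------------------------------------------------------------------

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    g = np.clip(np.asarray(gray, dtype=np.float64), 0.0, 255.0)
    return np.minimum((g * levels / 256.0).astype(int), levels - 1)


def glcm_matrix(gray: np.ndarray, theta: int, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric, normalized L×L gray-level co-occurrence matrix.

    Gray values are quantized to ``levels`` equal-width bins over
    [0, 256). θ selects the offset: (0,1) for 0°, (-1,1) for 45°, (-1,0)
    for 90°, (-1,-1) for 135° — unit distance axially, √2 diagonally.
    Ordered pair counts are symmetrized (added to their transpose) and
    normalized to sum to 1.
    """
    if theta not in _ANGLE_OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_ANGLE_OFFSETS)}")
    q = _quantize(gray, levels)
    dr, dc = _ANGLE_OFFSETS[theta]
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("image too small for the requested offset")
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a, b), 1.0)
    sym = counts + counts.T
    return sym / sym.sum()


def haralick_stats(P: np.ndarray) -> np.ndarray:
    """Haralick's 13 texture statistics of a normalized GLCM.

    Order: angular second moment, contrast, correlation, sum-of-squares
    variance, inverse difference moment, sum average, sum variance, sum
    entropy, entropy, difference variance, difference entropy, and the
    two information measures of correlation. Natural logarithms; the
    0·log 0 convention is 0. Correlation is defined as 0 when a marginal
    standard deviation vanishes (e.g. constant images).
    """
    P = np.asarray(P, dtype=np.float64)
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    asm = float((P ** 2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    mu_x = float((np.arange(L) * px).sum())
    mu_y = float((np.arange(L) * py).sum())
    var_x = float(((np.arange(L) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(L) - mu_y) ** 2 * py).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = float(((i - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    k_sum = np.arange(2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (i + j).ravel(), P.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = _ent(p_sum)

    k_diff = np.arange(L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(i - j).ravel(), P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _ent(p_diff)

    entropy = _ent(P.ravel())
    hx = _ent(px)
    hy = _ent(py)
    pxy = px[:, None] * py[None, :]
    mask = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[mask] * np.log(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log(pxy[mask2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, entropy, diff_var, diff_ent, imc1, imc2,
    ])


def glcm_features(gray: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """13 Haralick statistics averaged over the four directions."""
    stats = [haralick_stats(glcm_matrix(gray, theta, levels)) for theta in GLCM_ANGLES]
    return np.mean(stats, axis=0)


# --- concatenation ---------------------------------------------------------

def handcrafted_features(img: np.ndarray) -> FeatureVector:
    """Full 244-value descriptor: dwt(12) ∥ lbp(203) ∥ fch(16) ∥ glcm(13)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[0] < 5 or arr.shape[1] < 5:
        raise ValueError("handcrafted features require an RGB image of at least 5x5")
    gray = rgb_to_gray(arr)
    values = np.concatenate([
        dwt_features(gray),
        lbp_features(gray),
        fch_features(arr),
        glcm_features(gray),
    ])
    return FeatureVector(values)


def extract_handcrafted(images: Sequence[np.ndarray]) -> np.ndarray:
    """n × 244 matrix of handcrafted descriptors."""
    if len(images) == 0:
        return np.zeros((0, TOTAL_FEATURES))
    return np.stack([handcrafted_features(img).values for img in images])


def feature_names() -> list[str]:
    """Column names ``<block>_<index>`` in layout order."""
    names = []
    for block, (_, length) in sorted(BLOCK_LAYOUT.items(), key=lambda kv: kv[1][0]):
        names.extend(f"{block}_{i}" for i in range(length))
    return names
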