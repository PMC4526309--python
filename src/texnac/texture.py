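"""Grey-level co-occurrence and run-length texture analysis on masked ROIs.

Computation conventions (all configurable where noted):

* intensities are min–max quantized *within the analysed mask* into
  ``2**bits`` grey levels (default 5 bits → 32 levels), which makes every
  feature invariant under positive affine rescaling of the raw image;
* pixel pairs and runs are taken at distance 1 along the four main
  directions (0°, 45°, 90°, 135°) and pooled into a single matrix — for
  the normalized co-occurrence matrix, averaging the four directional
  matrices and summing them coincide;
* only pairs/runs fully inside the mask count, and runs break wherever a
  line of pixels leaves the mask, so irregular ROIs are handled exactly;
* co-occurrence feature formulas use 1-based grey-level indices
  (i, j = 1..G), the classical convention, and the run-length weights
  likewise index levels from 1 so that the low-grey-level emphases never
  divide by zero;
* entropy is in bits (log base 2).

The co-occurrence features are energy, entropy, contrast, homogeneity,
correlation, inverse difference moment, sum average, sum variance and
difference variance.  The run-length features are SRE, LRE, GLN, RLN,
RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE and LRHGE.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import SubtractedImage
from .masks import as_mask_array

__all__ = [
    "QuantizedImage",
    "CoocMatrix",
    "RunLengthMatrix",
    "GLCM_FEATURES",
    "RLM_FEATURES",
    "TEXTURE_FEATURES",
    "quantize",
    "glcm",
    "glcm_features",
    "rlm",
    "rlm_features",
    "texture_features",
    "texture_map",
]

# offsets of the four main directions: 0°, 45°, 90°, 135°
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

GLCM_FEATURES = (
    "energy",
    "entropy",
    "contrast",
    "homogeneity",
    "correlation",
    "inv_diff_moment",
    "sum_average",
    "sum_variance",
    "difference_variance",
)
RLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
)
TEXTURE_FEATURES = GLCM_FEATURES + RLM_FEATURES


@dataclass(frozen=True)
class QuantizedImage:
    levels: np.ndarray  # int array, values in 0..n_levels-1 inside mask
    n_levels: int
    mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 0 or inside.max() >= self.n_levels):
            raise ValueError("in-mask levels outside 0..G-1")


@dataclass(frozen=True)
class CoocMatrix:
    """Symmetric joint grey-level probability matrix, pooled over directions."""

    p: np.ndarray  # (G, G), sums to 1
    n_pairs: int  # ordered pair count before normalization


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts r[level, length-1] accumulated over the four directions."""

    r: np.ndarray  # (G, Lmax) counts
    n_runs: int
    pixel_basis: int  # in-mask pixel count summed over the directions used


def quantize(image, mask, bits: int = 5) -> QuantizedImage:
    """Min–max linear binning of in-mask intensities into 2**bits levels.

    The in-mask maximum maps to level G−1.  A constant in-mask image maps
    everything to level 0 (valid, if degenerate, input for the matrices).
    """
    pixels = image.pixels if isinstance(image, SubtractedImage) else np.asarray(image, dtype=float)
    m = as_mask_array(mask)
    if pixels.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    g = 2 ** int(bits)
    inside = pixels[m]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(pixels.shape, dtype=np.int64)
    if hi > lo:
        scaled = (pixels - lo) / (hi - lo) * g
        levels = np.minimum(np.floor(scaled), g - 1).astype(np.int64)
        levels = np.clip(levels, 0, g - 1)
    return QuantizedImage(np.where(m, levels, 0), g, m)


def glcm(q: QuantizedImage) -> CoocMatrix:
    """Symmetrized co-occurrence matrix pooled over the four directions."""
    g = q.n_levels
    counts = np.zeros((g, g), dtype=np.int64)
    lv, m = q.levels, q.mask
    h, w = lv.shape
    for dr, dc in DIRECTIONS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        valid = m[src] & m[dst]
        np.add.at(counts, (lv[src][valid], lv[dst][valid]), 1)
    counts = counts + counts.T  # symmetrize
    total = int(counts.sum())
    if total == 0:
        raise ValueError("mask contains no valid pixel pair in any direction")
    return CoocMatrix(counts / total, total)


def glcm_features(m: CoocMatrix) -> dict[str, float]:
    """The nine co-occurrence features of a normalized matrix.

    Grey levels are indexed 1..G.  For a constant image the matrix has a
    single cell and the correlation denominator vanishes; correlation is
    then defined as 0 (with a warning) instead of propagating NaN.
    """
    p = m.p
    g = p.shape[0]
    idx = np.arange(1, g + 1, dtype=float)
    i = idx[:, None]
    j = idx[None, :]

    energy = float((p ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    inv_diff_moment = float((p / (1.0 + (i - j) ** 2)).sum())

    px = p.sum(axis=1)
    mu_x = float((idx * px).sum())
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    # symmetric matrix: y-margin equals x-margin
    py = p.sum(axis=0)
    mu_y = float((idx * py).sum())
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))
    if sigma_x * sigma_y == 0:
        warnings.warn("degenerate co-occurrence matrix: correlation set to 0", stacklevel=2)
        correlation = 0.0
    else:
        correlation = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sigma_x * sigma_y))

    # p_{x+y}(k), k = 2..2G and p_{x-y}(k), k = 0..G-1
    ksum = np.arange(2, 2 * g + 1, dtype=float)
    p_sum = np.array([p[(i + j) == k].sum() for k in ksum])
    sum_average = float((ksum * p_sum).sum())
    sum_variance = float((((ksum - sum_average) ** 2) * p_sum).sum())

    kdiff = np.arange(0, g, dtype=float)
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in kdiff])
    mu_d = float((kdiff * p_diff).sum())
    difference_variance = float((((kdiff - mu_d) ** 2) * p_diff).sum())

    return {
        "energy": energy,
        "entropy": entropy,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "inv_diff_moment": inv_diff_moment,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "difference_variance": difference_variance,
    }


def _lines(shape: tuple[int, int], direction: tuple[int, int]):
    """Index lists of the maximal collinear pixel sequences of a direction."""
    h, w = shape
    dr, dc = direction
    if (dr, dc) == (0, 1):  # horizontal
        for r in range(h):
            yield [(r, c) for c in range(w)]
    elif (dr, dc) == (-1, 0):  # vertical (scanned downward; run content is unaffected)
        for c in range(w):
            yield [(r, c) for r in range(h)]
    elif (dr, dc) == (-1, 1):  # 45°: anti-diagonals
        for s in range(h + w - 1):
            line = [(r, s - r) for r in range(h - 1, -1, -1) if 0 <= s - r < w]
            yield line
    elif (dr, dc) == (-1, -1):  # 135°: main diagonals
        for d in range(-(h - 1), w):
            line = [(r, r + d) for r in range(h) if 0 <= r + d < w]
            yield line
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def rlm(q: QuantizedImage, directions=DIRECTIONS) -> RunLengthMatrix:
    """Run-length matrix over the given directions (default: all four).

    Each maximal in-mask collinear sequence is decomposed into maximal
    runs of equal level; runs break at mask boundaries.
    """
    g = q.n_levels
    lv, m = q.levels, q.mask
    if not m.any():
        raise ValueError("empty mask")
    lmax = max(lv.shape)
    r = np.zeros((g, lmax), dtype=np.int64)
    n_runs = 0
    for direction in directions:
        for line in _lines(lv.shape, direction):
            run_level, run_len = None, 0
            for (row, col) in line + [(-1, -1)]:  # sentinel flushes the last run
                inside = row >= 0 and m[row, col]
                level = lv[row, col] if inside else None
                if inside and level == run_level:
                    run_len += 1
                else:
                    if run_level is not None and run_len > 0:
                        r[run_level, run_len - 1] += 1
                        n_runs += 1
                    run_level, run_len = (level, 1) if inside else (None, 0)
    if n_runs == 0:
        raise ValueError("no runs found (empty mask)")
    pixel_basis = int(m.sum()) * len(directions)
    return RunLengthMatrix(r, n_runs, pixel_basis)


def rlm_features(rl: RunLengthMatrix) -> dict[str, float]:
    """The eleven run-length features; levels indexed i = 1..G."""
    if rl.n_runs == 0:
        raise ValueError("run-length matrix has no runs")
    r = rl.r.astype(float)
    g, lmax = r.shape
    i = np.arange(1, g + 1, dtype=float)[:, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, :]
    n = float(rl.n_runs)

    return {
        "sre": float((r / j ** 2).sum() / n),
        "lre": float((r * j ** 2).sum() / n),
        "gln": float((r.sum(axis=1) ** 2).sum() / n),
        "rln": float((r.sum(axis=0) ** 2).sum() / n),
        "rp": float(n / rl.pixel_basis),
        "lgre": float((r / i ** 2).sum() / n),
        "hgre": float((r * i ** 2).sum() / n),
        "srlge": float((r / (i ** 2 * j ** 2)).sum() / n),
        "srhge": float((r * i ** 2 / j ** 2).sum() / n),
        "lrlge": float((r * j ** 2 / i ** 2).sum() / n),
        "lrhge": float((r * i ** 2 * j ** 2).sum() / n),
    }


def texture_features(image, mask, bits: int = 5) -> dict[str, float]:
    """All 20 texture features of a masked image: quantize → GLCM + RLM."""
    q = quantize(image, mask, bits=bits)
    out = glcm_features(glcm(q))
    out.update(rlm_features(rlm(q)))
    return out


def texture_map(image, feature: str, window: int = 3, bits: int = 5,
                scaled: bool = True) -> np.ndarray:
    """Sliding-window co-occurrence feature map.

    The feature is computed on each pixel's ``window``×``window``
    neighbourhood (clipped at the image border, quantized within the
    window) and, when ``scaled``, min–max normalized to the 0–255 range
    over the whole image.  A flat map cannot be normalized and comes back
    as all zeros with a warning.
    """
    if feature not in GLCM_FEATURES:
        raise ValueError(f"unknown co-occurrence feature {feature!r}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    pixels = image.pixels if isinstance(image, SubtractedImage) else np.asarray(image, dtype=float)
    h, w = pixels.shape
    if window > min(h, w):
        raise ValueError("window larger than image")
    half = window // 2
    out = np.empty((h, w))
    full = np.ones((window, window), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate windows are expected at flat spots
        for r in range(h):
            for c in range(w):
                crop = pixels[max(0, r - half): r + half + 1, max(0, c - half): c + half + 1]
                q = quantize(crop, full[: crop.shape[0], : crop.shape[1]], bits=bits)
                out[r, c] = glcm_features(glcm(q))[feature]
    if not scaled:
        return out
    lo, hi = out.min(), out.max()
    if hi == lo:
        warnings.warn("flat feature map: 0-255 scaling is degenerate, returning zeros",
                      stacklevel=2)
        return np.zeros_like(out)
    return (out - lo) / (hi - lo) * 255.0
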