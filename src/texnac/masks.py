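"""Binary region-of-interest masks on the image lattice.

ROIs come in several flavours mirroring a typical breast-MRI reading
session: a manually drawn lesion outline, a healthy-tissue reference
region, a small kinetic ROI over the most enhancing pixels, the
rectangular search box handed to the automatic segmentation, and the
segmentation's own output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MASK_KINDS = ("manual_lesion", "healthy_tissue", "small_kinetic", "rectangle", "auto_lesion")


@dataclass(frozen=True)
class RoiMask:
    """A binary pixel set on the frame lattice."""

    pixels: np.ndarray
    kind: str = "manual_lesion"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={px.ndim}")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}; expected one of {MASK_KINDS}")
        object.__setattr__(self, "pixels", px)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_mask_array(mask) -> np.ndarray:
    """Accept a RoiMask or a plain boolean array; return a 2D bool array."""
    if isinstance(mask, RoiMask):
        return mask.pixels
    arr = np.asarray(mask, dtype=bool)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2D, got ndim={arr.ndim}")
    return arr


def rectangle_mask(shape: tuple[int, int], top: int, left: int, height: int, width: int) -> RoiMask:
    """Axis-aligned rectangular ROI, e.g. the box covering the breast."""
    if height <= 0 or width <= 0:
        raise ValueError("rectangle must have positive height and width")
    if top < 0 or left < 0 or top + height > shape[0] or left + width > shape[1]:
        raise ValueError("rectangle extends outside the image")
    px = np.zeros(shape, dtype=bool)
    px[top : top + height, left : left + width] = True
    return RoiMask(px, kind="rectangle")


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on
    "nothing there").
    """
    pa, pb = as_mask_array(a), as_mask_array(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    denom = int(pa.sum()) + int(pb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / denom
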