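"""Automatic lesion segmentation from kinetic maps.

The pipeline mimics what a reader would do with a semi-automatic tool:
place a rectangular box over the breast, compute per-pixel amplitude and
wash-in, partition the pixels into lesion / non-lesion by 2-means
clustering on the two (z-scored) kinetic features, clean up with a
morphological opening, and keep the largest contiguous region.

Conventions the clustering step leaves open are fixed as follows: the
cluster with the higher mean (raw) amplitude is the lesion; features are
z-scored within the box before clustering because amplitude (AU) and
wash-in (AU/s) live on different scales; contiguity is 4-connectivity;
the opening uses a disc structuring element.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import disk, opening
from sklearn.cluster import KMeans

from .kinetics import DynamicSeries, kinetic_maps
from .masks import RoiMask, as_mask_array

__all__ = ["SegmentationParams", "segment_lesion"]


@dataclass(frozen=True)
class SegmentationParams:
    opening_radius: int = 1  # pixels; 0 skips the opening
    n_replicates: int = 10  # k-means restarts, best by within-cluster inertia
    connectivity: int = 1  # 1 → 4-connected, 2 → 8-connected
    seed: int = 0

    #: number of clusters is part of the method, not a tunable
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.n_clusters != 2:
            raise ValueError("the segmentation is defined for exactly 2 clusters")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")


def segment_lesion(series: DynamicSeries, rect, params: SegmentationParams | None = None) -> RoiMask:
    """Segment the lesion inside a rectangular search ROI.

    Returns the largest connected component, after opening, of the
    k-means cluster with the higher mean amplitude.  Deterministic given
    ``params.seed``.
    """
    params = params or SegmentationParams()
    box = as_mask_array(rect)
    if not box.any():
        raise ValueError("empty search ROI")
    amp_map, win_map = kinetic_maps(series, box)
    amp = amp_map[box]
    win = win_map[box]
    feats = np.column_stack([amp, win])
    sd = feats.std(axis=0)
    if np.all(sd == 0):
        raise ValueError(
            "degenerate clustering input: amplitude and wash-in are constant over the ROI "
            "(no enhancing structure to separate)"
        )
    z = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    km = KMeans(
        n_clusters=2,
        init="random",  # pick 2 observations at random as initial centroids
        n_init=params.n_replicates,
        random_state=params.seed,
    ).fit(z)
    assign = km.labels_
    sizes = np.bincount(assign, minlength=2)
    if sizes.min() == 0:
        raise ValueError(
            f"degenerate clustering: one cluster is empty (sizes {sizes.tolist()})"
        )
    lesion_cluster = int(np.argmax([amp[assign == c].mean() for c in (0, 1)]))

    mask = np.zeros(box.shape, dtype=bool)
    mask[box] = assign == lesion_cluster
    if params.opening_radius > 0:
        mask = opening(mask, disk(params.opening_radius))
    if not mask.any():
        raise ValueError("segmentation empty after morphological opening")
    labels = label(mask, connectivity=params.connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    largest = int(np.argmax(counts))
    return RoiMask(labels == largest, kind="auto_lesion")
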