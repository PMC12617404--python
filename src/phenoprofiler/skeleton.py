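"""Skeleton morphometry of elongated structures (Golgi fragments, cilia).

Skeletonization represents objects as lines by removing thickness: a
fragmented Golgi yields many short line objects, a compact one few longer
"tubular" objects, and a primary cilium appears as a single short unbranched
line in the acetylated-tubulin channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.morphology import skeletonize

from .segmentation import STRUCT8, binarize

__all__ = [
    "SkeletonObject",
    "skeletonize_mask",
    "skeleton_objects",
    "skeleton_stats",
    "call_cilia",
    "count_cilia",
]

SQRT2 = math.sqrt(2.0)

#: default primary-cilium length window in micrometres
CILIUM_MIN_UM = 1.0
CILIUM_MAX_UM = 15.0


@dataclass
class SkeletonObject:
    """One 8-connected skeleton component."""

    pixels: list[tuple[int, int]]
    length: float
    endpoints: list[tuple[int, int]]

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving two-subiteration thinning of a boolean mask.

    Idempotent, and a subset of the input mask.
    """
    return skeletonize(np.asarray(mask, bool))


def _component_length(ys: np.ndarray, xs: np.ndarray) -> float:
    """Length of a skeleton component: total weight of a minimum spanning
    traversal over 8-adjacent pixels (axial step 1, diagonal sqrt(2))."""
    n = ys.size
    if n <= 1:
        return 0.0
    order = {(int(y), int(x)): i for i, (y, x) in enumerate(zip(ys, xs))}
    rows, cols, weights = [], [], []
    for (y, x), i in order.items():
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                j = order.get((y + dy, x + dx))
                if j is not None and j > i:
                    rows.append(i)
                    cols.append(j)
                    weights.append(1.0 if dy == 0 or dx == 0 else SQRT2)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))
    return float(minimum_spanning_tree(graph).sum())


def _endpoints(ys: np.ndarray, xs: np.ndarray) -> list[tuple[int, int]]:
    pts = set(zip(ys.tolist(), xs.tolist()))
    out = []
    for y, x in sorted(pts):
        nn = sum(
            ((y + dy, x + dx) in pts)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dy, dx) != (0, 0)
        )
        if nn == 1:
            out.append((y, x))
    return out


def skeleton_objects(
    skeleton_mask: np.ndarray, min_length: float = 0.0
) -> list[SkeletonObject]:
    """8-connected skeleton components with traversal lengths.

    Endpoints are skeleton pixels with exactly one skeleton neighbor;
    components shorter than ``min_length`` are dropped.
    """
    lab, n = ndi.label(np.asarray(skeleton_mask, bool), structure=STRUCT8)
    objects: list[SkeletonObject] = []
    for k in range(1, n + 1):
        ys, xs = np.nonzero(lab == k)
        length = _component_length(ys, xs)
        if length < min_length:
            continue
        objects.append(
            SkeletonObject(
                pixels=list(zip(ys.tolist(), xs.tolist())),
                length=length,
                endpoints=_endpoints(ys, xs),
            )
        )
    return objects


def skeleton_stats(objects: list[SkeletonObject]) -> dict[str, float]:
    """Count, mean length and total length; empty input gives zeros."""
    if not objects:
        return {"objects_num": 0, "len_mean": 0.0, "len_total": 0.0}
    lengths = [o.length for o in objects]
    return {
        "objects_num": len(objects),
        "len_mean": float(np.mean(lengths)),
        "len_total": float(np.sum(lengths)),
    }


def _cilia_from_mask(
    mask: np.ndarray, min_len_px: float, max_len_px: float
) -> list[SkeletonObject]:
    skel = skeletonize_mask(mask)
    objects = skeleton_objects(skel)
    # a cilium is a simple unbranched line: exactly two endpoints
    return [
        o
        for o in objects
        if min_len_px <= o.length <= max_len_px and len(o.endpoints) == 2
    ]


def _length_window_px(
    min_len: float, max_len: float, pixel_size_um: float | None
) -> tuple[float, float]:
    if pixel_size_um:
        return min_len / pixel_size_um, max_len / pixel_size_um
    return min_len, max_len


def call_cilia(
    cilia_mask: np.ndarray,
    min_len: float = CILIUM_MIN_UM,
    max_len: float = CILIUM_MAX_UM,
    pixel_size_um: float | None = None,
) -> dict:
    """Count cilium-shaped skeleton objects within a binarized cilia mask.

    The length window is in micrometres when a pixel size is given, else in
    pixels.  ``ciliated`` is true when at least one object qualifies.
    """
    lo, hi = _length_window_px(min_len, max_len, pixel_size_um)
    cilia = _cilia_from_mask(np.asarray(cilia_mask, bool), lo, hi)
    return {"objects_num_cilia": len(cilia), "ciliated": len(cilia) >= 1}


def count_cilia(
    cilia_plane: np.ndarray,
    min_len: float = CILIUM_MIN_UM,
    max_len: float = CILIUM_MAX_UM,
    pixel_size_um: float | None = None,
    threshold_method: str = "otsu",
) -> int:
    """Whole-image cilium count from a raw cilia-marker plane.

    Feeds the per-image ciliated fraction (cilia / nuclei), which is computed
    on the whole image rather than only on segmented cells.
    """
    mask, _ = binarize(cilia_plane, threshold_method)
    lo, hi = _length_window_px(min_len, max_len, pixel_size_um)
    return len(_cilia_from_mask(mask, lo, hi))
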