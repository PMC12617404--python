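"""Per-cell records from label masks, and subcellular binarization.

Cell boundaries come from an external segmenter (e.g. cellpose) via an
integer label mask, or from the built-in non-deep-learning fallback
(Otsu-thresholded nuclei seeding a watershed on a cytoplasmic marker).
Subcellular structures (nucleus, Golgi, cilia, ...) are binarized with
whole-image Otsu/Yen thresholds and intersected with each cell's mask:
per-cell thresholds destabilize on cells whose structure is absent, so the
global threshold is the reproducible default (a per-cell switch is exposed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_yen
from skimage.morphology import disk as disk_footprint
from skimage.segmentation import watershed

from .image_io import ChannelMap, LabelMask, MultiChannelImage

__all__ = [
    "CellRecord",
    "SegmentationParams",
    "binarize",
    "segment_cells_fallback",
    "extract_cells",
    "filter_cells",
]

logger = logging.getLogger(__name__)

# 8-connectivity everywhere: thin fluorescent structures continue diagonally
STRUCT8 = np.ones((3, 3), bool)

#: roles binarized into per-cell structure masks
STRUCTURE_ROLES = ("golgi", "tubulin", "cilia", "actin", "centriole")


@dataclass
class SegmentationParams:
    """Knobs for cell extraction and the fallback segmenter.

    min_cell_area / min_nucleus_area reject segmentation shards (px);
    threshold_method applies to all subcellular binarization;
    per_cell_thresholds switches structure thresholds from whole-image
    (default) to per-cell.
    """

    min_cell_area: int = 200
    min_nucleus_area: int = 50
    min_structure_area: int = 5
    threshold_method: str = "otsu"
    per_cell_thresholds: bool = False
    smoothing_sigma: float = 2.0
    dilate_radius: int = 10


@dataclass
class CellRecord:
    """One segmented cell: masks stored cropped to the bounding box.

    ``bbox`` is half-open ``(y0, x0, y1, x1)`` tightly bounding ``cell_mask``;
    all masks share the bbox crop shape.
    """

    cell_id: int
    bbox: tuple[int, int, int, int]
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    structure_masks: dict[str, np.ndarray] = field(default_factory=dict)
    touches_border: bool = False

    @property
    def area(self) -> int:
        return int(self.cell_mask.sum())

    def crop(self, plane: np.ndarray) -> np.ndarray:
        """Crop a full-frame plane to this cell's bounding box."""
        y0, x0, y1, x1 = self.bbox
        return plane[y0:y1, x0:x1]

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Paste the cropped cell mask back into a full frame."""
        out = np.zeros(shape, bool)
        y0, x0, y1, x1 = self.bbox
        out[y0:y1, x0:x1] = self.cell_mask
        return out


def binarize(plane: np.ndarray, method: str = "otsu") -> tuple[np.ndarray, float | None]:
    """Threshold a non-negative intensity plane; returns (mask, threshold).

    Otsu maximizes between-class variance, Yen maximizes entropic
    correlation, both over the histogram of the observed range (one bin per
    integer level for integer planes, 256 bins otherwise); the mask is
    ``plane > t``.  A constant plane has no defined threshold and yields an
    empty mask with a warning.
    """
    plane = np.asarray(plane)
    if plane.min() == plane.max():
        warnings.warn("constant plane: threshold undefined, returning empty mask")
        return np.zeros(plane.shape, bool), None
    if method == "otsu":
        t = float(threshold_otsu(plane, nbins=256))
    elif method == "yen":
        t = float(threshold_yen(plane, nbins=256))
    else:
        raise ValueError(f"unknown threshold method {method!r}; use 'otsu' or 'yen'")
    return plane > t, t


def segment_cells_fallback(
    image: MultiChannelImage,
    channel_map: ChannelMap,
    params: SegmentationParams | None = None,
) -> LabelMask:
    """Non-deep-learning cell segmentation.

    Nuclei (Otsu on the nucleus channel, 8-connected components above the
    minimum area) seed a watershed on the smoothed, inverted cytoplasmic
    marker (tubulin or actin), restricted to the marker's Otsu foreground.
    Without a cytoplasmic role, cells are nuclei dilated by a fixed radius.
    """
    params = params or SegmentationParams()
    channel_map.validate(image)
    nuc_plane = channel_map.plane(image, "nucleus")
    nuc_mask, _ = binarize(nuc_plane, params.threshold_method)
    # a threshold inside unimodal noise splits the frame roughly in half
    # with barely separated class means: treat that as "no signal"
    if nuc_mask.any() and not nuc_mask.all():
        fg = nuc_plane[nuc_mask].astype(float)
        bg = nuc_plane[~nuc_mask].astype(float)
        if nuc_mask.mean() > 0.5 or fg.mean() - bg.mean() < 3 * bg.std():
            nuc_mask = np.zeros_like(nuc_mask)
    seeds, n_seeds = ndi.label(nuc_mask, structure=STRUCT8)
    if n_seeds:
        areas = ndi.sum_labels(np.ones_like(seeds), seeds, index=np.arange(1, n_seeds + 1))
        keep = np.flatnonzero(areas >= params.min_nucleus_area) + 1
        seeds = np.where(np.isin(seeds, keep), seeds, 0)
        # relabel seeds contiguously
        seeds = np.searchsorted(np.unique(seeds), seeds)
    if seeds.max() == 0:
        warnings.warn("no nuclei found; returning empty segmentation")
        return LabelMask(labels=np.zeros(image.shape, np.int32))

    cyto_plane = None
    for role in ("tubulin", "actin"):
        if role in channel_map:
            cyto_plane = channel_map.plane(image, role)
            break
    if cyto_plane is None:
        dil = ndi.binary_dilation(
            seeds > 0, structure=disk_footprint(params.dilate_radius)
        )
        labels = watershed(np.zeros(image.shape), markers=seeds, mask=dil)
    else:
        cyto_fg, _ = binarize(cyto_plane, params.threshold_method)
        fg = cyto_fg | (seeds > 0)
        smooth = ndi.gaussian_filter(cyto_plane.astype(float), params.smoothing_sigma)
        labels = watershed(-smooth, markers=seeds, mask=fg)
    logger.info("fallback segmentation: %d cells", int(labels.max()))
    return LabelMask(labels=labels.astype(np.int32))


def _largest_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Connected components of ``mask`` with area >= min_area; if none
    qualifies but the mask is nonempty, keep the single largest component."""
    lab, n = ndi.label(mask, structure=STRUCT8)
    if n == 0:
        return np.zeros_like(mask)
    areas = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        return np.zeros_like(mask)
    return np.isin(lab, keep)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    if min_area <= 1 or not mask.any():
        return mask
    lab, n = ndi.label(mask, structure=STRUCT8)
    areas = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(lab, keep)


def extract_cells(
    image: MultiChannelImage,
    label_mask: LabelMask,
    channel_map: ChannelMap,
    params: SegmentationParams | None = None,
) -> list[CellRecord]:
    """Build one CellRecord per label, with nucleus and structure masks.

    The nucleus mask is the whole-image nucleus binarization intersected with
    the cell, keeping connected components above the minimum nucleus area;
    each mapped structure role is binarized (whole-image threshold by
    default) and intersected likewise.  Labels smaller than the minimum cell
    area are dropped with a log entry; ``touches_border`` marks cells whose
    mask meets the image frame.
    """
    params = params or SegmentationParams()
    channel_map.validate(image)
    if label_mask.shape != image.shape:
        raise ValueError(
            f"label mask shape {label_mask.shape} != image shape {image.shape}"
        )
    labels = label_mask.labels
    H, W = labels.shape

    global_masks: dict[str, np.ndarray] = {}
    if not params.per_cell_thresholds:
        nuc_mask, _ = binarize(channel_map.plane(image, "nucleus"), params.threshold_method)
        global_masks["nucleus"] = nuc_mask
        for role in STRUCTURE_ROLES:
            if role in channel_map:
                m, _ = binarize(channel_map.plane(image, role), params.threshold_method)
                global_masks[role] = m

    records: list[CellRecord] = []
    slices = ndi.find_objects(labels)
    for idx, slc in enumerate(slices):
        cell_id = idx + 1
        if slc is None:
            continue
        cell_mask = labels[slc] == cell_id
        area = int(cell_mask.sum())
        if area < params.min_cell_area:
            logger.info("cell %d dropped: area %d < %d", cell_id, area, params.min_cell_area)
            continue
        y0, x0 = slc[0].start, slc[1].start
        y1, x1 = slc[0].stop, slc[1].stop
        touches = y0 == 0 or x0 == 0 or y1 == H or x1 == W

        def role_mask(role: str) -> np.ndarray:
            if params.per_cell_thresholds:
                plane = channel_map.plane(image, role)[slc]
                vals = plane[cell_mask]
                if vals.size == 0 or vals.min() == vals.max():
                    return np.zeros_like(cell_mask)
                m, _ = binarize(np.where(cell_mask, plane, vals.min()), params.threshold_method)
                return m & cell_mask
            return global_masks[role][slc] & cell_mask

        nucleus = _largest_components(role_mask("nucleus"), params.min_nucleus_area)
        # despeckle: isolated above-threshold noise pixels are not structures
        structures = {
            role: _remove_small(role_mask(role), params.min_structure_area)
            for role in STRUCTURE_ROLES
            if role in channel_map
        }
        records.append(
            CellRecord(
                cell_id=cell_id,
                bbox=(y0, x0, y1, x1),
                cell_mask=cell_mask,
                nucleus_mask=nucleus,
                structure_masks=structures,
                touches_border=touches,
            )
        )
    return records


def count_nuclei(
    nucleus_plane: np.ndarray,
    min_area: int = 50,
    threshold_method: str = "otsu",
) -> int:
    """Whole-image nucleus count: Otsu/Yen foreground, 8-connected
    components above ``min_area``.  Denominator of the per-image ciliated
    fraction (cilia / nuclei)."""
    mask, _ = binarize(nucleus_plane, threshold_method)
    lab, n = ndi.label(mask, structure=STRUCT8)
    if n == 0:
        return 0
    areas = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return int((areas >= min_area).sum())


def filter_cells(records: list[CellRecord], exclude_border: bool = True) -> list[CellRecord]:
    """Optionally remove border-touching cells; stable order by cell id."""
    out = [r for r in records if not (exclude_border and r.touches_border)]
    return sorted(out, key=lambda r: r.cell_id)
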