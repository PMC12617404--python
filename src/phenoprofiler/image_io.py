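"""Raster and tabular I/O for the profiling pipeline.

Reads multichannel fluorescence TIFFs into the internal image model, reads and
writes integer cell-label masks (the interchange format with external
segmenters such as cellpose), and writes colored cluster overlays.

Conventions: coordinates are 0-based ``(row, col) = (y, x)``; all geometry is
in pixel units and converted to micrometres only at reporting time when a
pixel size is known; z-stacks are collapsed by maximum-intensity projection at
read time, so only 2D planes enter analysis.
"""

from __future__ import annotations

import colorsys
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MultiChannelImage",
    "ChannelMap",
    "LabelMask",
    "FormatError",
    "read_multichannel_tiff",
    "write_multichannel_tiff",
    "read_label_mask",
    "write_label_mask",
    "write_overlay",
    "write_feature_table",
    "read_feature_table",
    "max_project",
]

#: biological roles a channel can be assigned to
KNOWN_ROLES = (
    "nucleus",
    "golgi",
    "tubulin",
    "cilia",
    "actin",
    "centriole",
    "edu",
    "ki67",
    "aurka",
)


class FormatError(ValueError):
    """Raised when an input file does not match the declared layout."""


@dataclass
class MultiChannelImage:
    """Named 2D intensity planes sharing one shape.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2D non-negative integer plane
        (16-bit range).
    pixel_size_um
        Physical pixel size in micrometres per pixel, if known.
    image_id
        Identifier carried into feature tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image must contain at least one channel")
        shapes = {name: p.shape for name, p in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel planes differ in shape: {shapes}")
        for name, plane in self.channels.items():
            if plane.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2D plane")
            if not np.issubdtype(plane.dtype, np.integer):
                raise FormatError(f"channel {name!r} has non-integer dtype {plane.dtype}")
            if plane.min() < 0 or plane.max() > 65535:
                raise ValueError(f"channel {name!r} outside the 16-bit range")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def plane(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class ChannelMap:
    """Assignment of biological roles (nucleus, golgi, ...) to channel names.

    Only the ``nucleus`` role is mandatory.  Channel order never comes from
    file metadata: ND2-to-TIFF conversions scramble it, so the assignment is
    always explicit.
    """

    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "nucleus" not in self.roles:
            raise ValueError("channel map must assign the 'nucleus' role")

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def __getitem__(self, role: str) -> str:
        return self.roles[role]

    def get(self, role: str) -> str | None:
        return self.roles.get(role)

    def validate(self, image: MultiChannelImage) -> None:
        missing = {r: c for r, c in self.roles.items() if c not in image.channels}
        if missing:
            raise ValueError(
                f"channel map refers to channels absent from image "
                f"{image.image_id!r}: {missing}"
            )

    def plane(self, image: MultiChannelImage, role: str) -> np.ndarray | None:
        name = self.roles.get(role)
        return None if name is None else image.plane(name)

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelMap":
        with open(path) as fh:
            return cls(roles=dict(json.load(fh)))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.roles, fh, indent=2)


@dataclass
class LabelMask:
    """Integer cell-label plane: 0 = background, k > 0 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label mask has non-integer dtype {self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValueError("label mask must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    @property
    def n_cells(self) -> int:
        return int(self.ids.size)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over the leading (z) axis; idempotent on 2D input."""
    if stack.ndim == 2:
        return stack
    return stack.max(axis=0)


def read_multichannel_tiff(
    path: str | Path,
    channel_names: Sequence[str],
    pixel_size_um: float | None = None,
    image_id: str | None = None,
) -> MultiChannelImage:
    """Read a multichannel (optionally z-stacked) TIFF into named 2D planes.

    The file's plane count must equal ``len(channel_names)`` (single z) or an
    integer multiple of it (``channels x z``); in the stacked case each
    channel's z-planes are max-projected.  Planes are assumed interleaved with
    channel varying fastest (ImageJ hyperstack XYCZT order).
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path.name}: expected 2D planes, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path.name}: non-integer dtype {arr.dtype}")
    n_planes, n_chan = arr.shape[0], len(channel_names)
    if n_chan == 0:
        raise ValueError("channel_names must be non-empty")
    if n_planes % n_chan != 0:
        raise FormatError(
            f"{path.name}: {n_planes} planes cannot be divided among "
            f"{n_chan} declared channels"
        )
    n_z = n_planes // n_chan
    # (z, c, H, W) with channel fastest within each z-block
    stack = arr.reshape(n_z, n_chan, *arr.shape[1:])
    channels = {
        name: max_project(stack[:, ci]) for ci, name in enumerate(channel_names)
    }
    return MultiChannelImage(
        channels=channels,
        pixel_size_um=pixel_size_um,
        image_id=image_id if image_id is not None else path.stem,
    )


def write_multichannel_tiff(image: MultiChannelImage, path: str | Path) -> None:
    """Write channels as a plane-per-channel 16-bit TIFF, in channel order."""
    planes = np.stack([image.channels[n].astype(np.uint16) for n in image.channels])
    tifffile.imwrite(Path(path), planes)


def read_label_mask(path: str | Path) -> LabelMask:
    """Read a single-plane integer TIFF/PNG label mask."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        raise FormatError(f"{path.name}: RGB/multiplane input is not a label mask")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path.name}: float-typed input is not a label mask")
    return LabelMask(labels=np.asarray(arr))


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask; round-trips bit-exactly through read_label_mask."""
    path = Path(path)
    labels = mask.labels
    if labels.max() <= 65535:
        labels = labels.astype(np.uint16)
    else:
        labels = labels.astype(np.int32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels)
    else:
        if labels.dtype != np.uint16:
            raise FormatError("PNG label masks support at most 16-bit labels")
        iio.imwrite(path, labels)


def cluster_color(label: int) -> tuple[float, float, float]:
    """Deterministic RGB tint per cluster label; noise (-1) maps to gray."""
    if label < 0:
        return (0.6, 0.6, 0.6)
    # golden-ratio hue walk: well-separated, stable under new labels
    hue = (label * 0.61803398875) % 1.0
    return colorsys.hsv_to_rgb(hue, 0.85, 1.0)


def write_overlay(
    image: MultiChannelImage,
    mask: LabelMask,
    clusters: Mapping[int, int],
    path: str | Path,
    base_channel: str | None = None,
) -> np.ndarray:
    """Write an 8-bit RGB PNG with each cell tinted by its cluster color.

    ``clusters`` maps cell id to cluster label (-1 = noise, gray tint).  Cells
    absent from ``clusters`` stay untinted; ids in ``clusters`` missing from
    the mask are skipped with a warning.  Returns the RGB array written.
    """
    if base_channel is None:
        base_channel = next(iter(image.channels))
    base = image.plane(base_channel).astype(float)
    hi = np.percentile(base, 99.5)
    gray = np.clip(base / hi if hi > 0 else base, 0, 1)
    rgb = np.stack([gray] * 3, axis=-1)
    present = set(int(v) for v in mask.ids)
    for cell_id, label in sorted(clusters.items()):
        if int(cell_id) not in present:
            warnings.warn(f"cell id {cell_id} not present in label mask; skipped")
            continue
        tint = np.array(cluster_color(int(label)))
        sel = mask.labels == int(cell_id)
        rgb[sel] = 0.45 * rgb[sel] + 0.55 * tint
    out = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)
    iio.imwrite(Path(path), out)
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell feature table as CSV (floats at 6 significant digits)."""
    table.to_csv(Path(path), index=False, float_format="%.6g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
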