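"""Reading and writing the standard formats the pipeline touches.

Imaging-mass-cytometry acquisitions arrive as stacks of 16-bit single-channel
TIFF files, one per metal-tagged marker, all registered to the same region of
interest (ROI). This module loads them into a :class:`ChannelStack`, persists
label masks as lossless TIFF, emits per-cell statistics as plain CSV, and reads
the panel configuration that declares which channel is the nuclei stain, which
channels carry membrane signal, and which marker pairs are mutually exclusive.

Coordinate convention used everywhere in this package: ``(x, y) = (column,
row)``, 0-based, with pixel centers at integer coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ChannelStack",
    "PanelConfig",
    "CellTable",
    "read_channel_stack",
    "write_channel_stack",
    "read_label_mask",
    "write_label_mask",
    "write_cell_csv",
    "read_cell_csv",
    "read_panel_config",
]

# 6 significant digits: reproducible diffs without drowning in float noise
_CSV_FLOAT_FORMAT = "%.6g"


@dataclass
class ChannelStack:
    """A registered stack of single-marker intensity images for one ROI.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, height, width)`` holding raw,
        non-negative ion counts (unsigned 8/16-bit integers or floats).
    channel_names
        Unique marker names, one per channel, in channel order.
    roi_id
        Identifier of the acquired region of interest.
    """

    data: np.ndarray
    channel_names: list[str]
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D (C, H, W), got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every channel."""
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D image of one marker by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}; panel has {self.channel_names}") from None
        return self.data[idx]


@dataclass
class PanelConfig:
    """Marker-role assignment for segmentation and evaluation.

    ``nuclei_channel`` names the DNA/iridium-intercalator stain; the
    ``membrane_channels`` are summed into the green composite plane;
    ``exclusive_pairs`` list lineage markers a single cell cannot co-express
    (used to score false-positive segmentations); ``gains`` optionally
    overrides per-channel display gain.
    """

    nuclei_channel: str
    membrane_channels: list[str]
    exclusive_pairs: list[tuple[str, str]] = field(default_factory=list)
    gains: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membrane_channels = list(self.membrane_channels)
        self.exclusive_pairs = [tuple(p) for p in self.exclusive_pairs]
        if self.nuclei_channel in self.membrane_channels:
            raise ValueError(
                f"nuclei channel {self.nuclei_channel!r} cannot also be a membrane channel"
            )
        if len(set(self.membrane_channels)) != len(self.membrane_channels):
            raise ValueError("membrane channel listed twice")
        for pair in self.exclusive_pairs:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(f"exclusive pair must name two distinct markers, got {pair}")
        for name, g in self.gains.items():
            if g <= 0:
                raise ValueError(f"gain for {name!r} must be > 0, got {g}")

    def validate_for(self, stack: ChannelStack) -> None:
        """Check that every marker the panel names exists in *stack*."""
        known = set(stack.channel_names)
        named = {self.nuclei_channel, *self.membrane_channels, *self.gains}
        for a, b in self.exclusive_pairs:
            named.update((a, b))
        missing = sorted(named - known)
        if missing:
            raise ValueError(f"panel names markers absent from stack: {missing}")


@dataclass
class CellTable:
    """Per-cell records: id, centroid, size, and per-marker mean/median.

    Backed by a :class:`pandas.DataFrame` with columns ``cell_id``,
    ``centroid_x``, ``centroid_y``, ``n_pixels`` and, for every marker ``m``,
    ``mean_<m>`` and ``median_<m>``.
    """

    df: pd.DataFrame
    markers: list[str]

    def __post_init__(self) -> None:
        self.markers = list(self.markers)
        base = ["cell_id", "centroid_x", "centroid_y", "n_pixels"]
        stat_cols = [f"{s}_{m}" for m in self.markers for s in ("mean", "median")]
        missing = [c for c in base + stat_cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        if len(self.df):
            ids = self.df["cell_id"].to_numpy()
            if ids.min() < 1:
                raise ValueError("cell ids must be positive integers")
            if len(np.unique(ids)) != len(ids):
                raise ValueError("cell ids must be unique")
            if (self.df["n_pixels"].to_numpy() < 1).any():
                raise ValueError("every cell must cover at least one pixel")

    def __len__(self) -> int:
        return len(self.df)

    def stat_frame(self, stat: str) -> pd.DataFrame:
        """Flat frame ``cell_id, centroid_x, centroid_y, n_pixels, <markers>``
        holding the chosen statistic (``"mean"`` or ``"median"``)."""
        if stat not in ("mean", "median"):
            raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
        out = self.df[["cell_id", "centroid_x", "centroid_y", "n_pixels"]].copy()
        for m in self.markers:
            out[m] = self.df[f"{stat}_{m}"].to_numpy()
        return out


# ---------------------------------------------------------------------------
# TIFF


def _check_grayscale(arr: np.ndarray, source: object) -> np.ndarray:
    if arr.ndim != 2:
        raise ValueError(f"{source}: expected a single-channel 2-D image, got shape {arr.shape}")
    if arr.dtype.kind == "u" and arr.dtype.itemsize <= 2:
        return arr
    if arr.dtype.kind == "f":
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError(f"{source}: negative intensities in float image")
        return arr
    raise ValueError(f"{source}: unsupported dtype {arr.dtype} (need uint8/uint16 or float)")


def read_channel_stack(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    names: Sequence[str],
    roi_id: str = "",
) -> ChannelStack:
    """Load a marker stack from single-channel TIFFs or one multi-page TIFF.

    Values are preserved exactly — no rescaling, no dtype promotion beyond the
    common dtype of the pages. Channels are ordered as given.
    """
    if isinstance(paths, (str, os.PathLike)):
        pages = tifffile.imread(paths)
        if pages.ndim == 2:
            pages = pages[None]
        planes = [_check_grayscale(pages[i], f"{paths}[page {i}]") for i in range(pages.shape[0])]
    else:
        planes = [_check_grayscale(tifffile.imread(p), p) for p in paths]
    if len(planes) != len(names):
        raise ValueError(f"{len(planes)} channels read but {len(names)} names given")
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValueError(f"channel images disagree on shape: {sorted(shapes)}")
    return ChannelStack(np.stack(planes), list(names), roi_id=roi_id)


def write_channel_stack(stack: ChannelStack, path: str | os.PathLike) -> None:
    """Write a stack as one multi-page TIFF (one page per marker, lossless)."""
    tifffile.imwrite(path, stack.data, photometric="minisblack")


def write_label_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Persist an integer label mask as a lossless single-page TIFF.

    Labels ≤ 65535 are stored as uint16; wider label ranges fall back to
    uint32 so the round trip stays exact.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {mask.shape}")
    if mask.dtype.kind not in "iu":
        raise ValueError(f"label mask must be integer, got dtype {mask.dtype}")
    if mask.size and mask.min() < 0:
        raise ValueError("label mask contains negative labels")
    dtype = np.uint16 if (mask.size == 0 or mask.max() <= np.iinfo(np.uint16).max) else np.uint32
    tifffile.imwrite(path, mask.astype(dtype), photometric="minisblack")


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a label mask written by :func:`write_label_mask`."""
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise ValueError(f"{path}: label mask must be single-page 2-D, got shape {mask.shape}")
    return mask.astype(np.int64)


# ---------------------------------------------------------------------------
# CSV


def write_cell_csv(table: CellTable, stat: str, path: str | os.PathLike) -> None:
    """Write one of the two single-cell CSV files.

    Layout: header ``cell_id,centroid_x,centroid_y,n_pixels,<marker...>`` and
    one data row per cell, where each marker column holds the chosen statistic
    (``mean`` or ``median``) of that marker's raw intensity over the cell's
    pixels. The median file exists to shrug off the aberrant hot pixels that
    ion-count images frequently contain.
    """
    flat = table.stat_frame(stat)  # validates stat
    flat.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_cell_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a cell CSV as a flat DataFrame (markers as plain columns)."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Panel configuration

_PANEL_KEYS = {"nuclei_channel", "membrane_channels", "exclusive_pairs", "gains"}


def read_panel_config(path: str | os.PathLike) -> PanelConfig:
    """Load a panel configuration from a YAML file.

    Schema (YAML mapping)::

        nuclei_channel: DNA
        membrane_channels: [CD3, CD20, CD68]
        exclusive_pairs:            # optional
          - [CD3, CD20]
        gains:                      # optional, multiplicative display gains
          DNA: 2.5

    Unknown keys are rejected so typos fail loudly rather than silently
    changing the segmentation input.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: panel config must be a mapping")
    unknown = set(raw) - _PANEL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown panel config keys: {sorted(unknown)}")
    if "nuclei_channel" not in raw:
        raise ValueError(f"{path}: panel config must name a nuclei_channel")
    return PanelConfig(
        nuclei_channel=str(raw["nuclei_channel"]),
        membrane_channels=[str(m) for m in raw.get("membrane_channels", [])],
        exclusive_pairs=[tuple(map(str, p)) for p in raw.get("exclusive_pairs", [])],
        gains={str(k): float(v) for k, v in (raw.get("gains") or {}).items()},
    )
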