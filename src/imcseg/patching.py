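"""Split composites into fixed-size patches and losslessly reassemble outputs.

The network consumes 128x128 patches. Images are tiled without overlap in
row-major order; edge tiles are zero-padded to full size and the padding
amounts recorded so reassembly can discard them, making split -> merge the
exact identity for any image size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from imcseg.compositing import CompositeImage

__all__ = ["Patch", "split_patches", "merge_patches", "DEFAULT_PATCH_SIZE"]

DEFAULT_PATCH_SIZE = 128


@dataclass
class Patch:
    """One tile of a composite: (2, size, size) planes plus its geometry.

    ``pixels[0]`` is the membrane plane, ``pixels[1]`` the nuclei plane.
    ``origin_row``/``origin_col`` locate the tile's top-left corner in the
    source image; ``pad_bottom``/``pad_right`` record how much of the tile is
    zero padding beyond the image edge.
    """

    pixels: np.ndarray
    origin_row: int
    origin_col: int
    pad_bottom: int = 0
    pad_right: int = 0

    @property
    def size(self) -> int:
        return self.pixels.shape[-1]

    @property
    def valid_height(self) -> int:
        return self.pixels.shape[-2] - self.pad_bottom

    @property
    def valid_width(self) -> int:
        return self.pixels.shape[-1] - self.pad_right


def split_patches(image: CompositeImage, patch_size: int = DEFAULT_PATCH_SIZE) -> list[Patch]:
    """Tile an image into ``ceil(H/s) * ceil(W/s)`` patches, row-major.

    Edge patches are zero-padded at the bottom/right to the full patch size.
    """
    if patch_size < 1:
        raise ValueError(f"patch_size must be >= 1, got {patch_size}")
    planes = image.planes()
    _, h, w = planes.shape
    if h == 0 or w == 0:
        raise ValueError("cannot split an empty image")
    patches: list[Patch] = []
    for r0 in range(0, h, patch_size):
        for c0 in range(0, w, patch_size):
            tile = planes[:, r0:r0 + patch_size, c0:c0 + patch_size]
            pad_b = patch_size - tile.shape[1]
            pad_r = patch_size - tile.shape[2]
            if pad_b or pad_r:
                tile = np.pad(tile, ((0, 0), (0, pad_b), (0, pad_r)))
            patches.append(Patch(tile.copy(), origin_row=r0, origin_col=c0,
                                 pad_bottom=pad_b, pad_right=pad_r))
    return patches


def merge_patches(
    values: Sequence[np.ndarray],
    geometry: Sequence[Patch],
    out_height: int,
    out_width: int,
) -> np.ndarray:
    """Reassemble per-patch 2-D outputs into the full image.

    ``values[i]`` must be a 2-D array with the same tile size as
    ``geometry[i]``; padded regions are discarded. The tiles must cover
    ``out_height x out_width`` exactly once — gaps and overlaps are errors.
    """
    if len(values) != len(geometry):
        raise ValueError(f"{len(values)} value tiles for {len(geometry)} geometries")
    out = np.zeros((out_height, out_width), dtype=np.result_type(*[v.dtype for v in values])
                   if values else np.float64)
    coverage = np.zeros((out_height, out_width), dtype=np.uint8)
    for tile, geom in zip(values, geometry):
        tile = np.asarray(tile)
        if tile.ndim != 2 or tile.shape != (geom.pixels.shape[-2], geom.pixels.shape[-1]):
            raise ValueError(
                f"tile shape {tile.shape} does not match patch size "
                f"{geom.pixels.shape[-2:]} at ({geom.origin_row}, {geom.origin_col})"
            )
        vh, vw = geom.valid_height, geom.valid_width
        r0, c0 = geom.origin_row, geom.origin_col
        if r0 < 0 or c0 < 0 or r0 + vh > out_height or c0 + vw > out_width:
            raise ValueError(
                f"patch at ({r0}, {c0}) with valid area {vh}x{vw} "
                f"exceeds output {out_height}x{out_width}"
            )
        out[r0:r0 + vh, c0:c0 + vw] = tile[:vh, :vw]
        coverage[r0:r0 + vh, c0:c0 + vw] += 1
    if (coverage > 1).any():
        raise ValueError("patches overlap")
    if (coverage == 0).any():
        raise ValueError("patches leave gaps in the output")
    return out


def expected_patch_count(height: int, width: int, patch_size: int = DEFAULT_PATCH_SIZE) -> int:
    """Number of tiles produced for an image of the given size."""
    return math.ceil(height / patch_size) * math.ceil(width / patch_size)
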