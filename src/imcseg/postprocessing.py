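"""Rule-based cleanup of the network's binary mask and instance labeling.

A semantic U-Net makes three characteristic mistakes on ion-count images:
it occasionally hallucinates objects where no nucleus exists, it leaves
one-or-two-pixel specks, and it can puncture nuclei with small holes. The
post-processing pipeline fixes each in turn, in this order:

1. every labeled object with no nuclei signal above threshold anywhere in its
   footprint (checked on the raw nuclei acquisition) is eliminated;
2. objects of at most 2 pixels are removed;
3. holes fully enclosed by a single cell are filled with that cell's label.

Instances are recovered from the binary mask by connected-component labeling
(8-connectivity by default — touching cells merge, a documented limitation of
semantic segmentation).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label

from imcseg.net import binarize

__all__ = [
    "label_cells",
    "remove_anucleate_cells",
    "remove_tiny_objects",
    "fill_holes",
    "postprocess",
    "otsu_nuclei_threshold",
]

DEFAULT_MAX_REMOVED_SIZE = 2  # objects of 1 or 2 pixels are specks


def _compact_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel to the contiguous range 1..K in raster-scan order of each
    label's first pixel."""
    flat = labels.ravel()
    fg = flat > 0
    if not fg.any():
        return np.zeros_like(labels, dtype=np.int64)
    order_ids, first_pos = np.unique(flat[fg], return_index=True)
    # sort surviving ids by first occurrence in raster order
    rank = np.argsort(np.argsort(first_pos))
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int64)
    lut[order_ids] = rank + 1
    return lut[labels]


def label_cells(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected components of the foreground, labeled 1..K.

    ``connectivity`` is 4 (edge neighbors) or 8 (edge + diagonal, the default:
    biological blobs touch diagonally). Labels are assigned in raster-scan
    order of each component's first pixel; 0 is background.
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("label_cells expects a binary mask of 0s and 1s")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    lab = _sk_label(mask.astype(np.uint8), connectivity=1 if connectivity == 4 else 2)
    return _compact_relabel(lab)


def remove_anucleate_cells(labels: np.ndarray, nuclei: np.ndarray,
                           nuclei_threshold: float) -> np.ndarray:
    """Drop every cell whose footprint shows no nuclei signal.

    A cell survives iff at least one of its pixels exceeds ``nuclei_threshold``
    on the (raw) nuclei image. Removed cells become background; remaining
    labels are compacted to 1..K preserving raster order.
    """
    labels = np.asarray(labels)
    nuclei = np.asarray(nuclei)
    if labels.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs nuclei {nuclei.shape}")
    if nuclei_threshold < 0:
        raise ValueError(f"nuclei_threshold must be >= 0, got {nuclei_threshold}")
    n = int(labels.max())
    if n == 0:
        return np.zeros_like(labels, dtype=np.int64)
    peak = ndimage.maximum(nuclei, labels=labels, index=np.arange(1, n + 1))
    keep = np.asarray(peak) > nuclei_threshold
    lut = np.zeros(n + 1, dtype=np.int64)
    lut[1:][keep] = 1
    return _compact_relabel(lut[labels] * labels)


def remove_tiny_objects(labels: np.ndarray,
                        max_removed_size: int = DEFAULT_MAX_REMOVED_SIZE) -> np.ndarray:
    """Delete cells covering at most ``max_removed_size`` pixels (default 2)."""
    if max_removed_size < 0:
        raise ValueError(f"max_removed_size must be >= 0, got {max_removed_size}")
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return np.zeros_like(labels, dtype=np.int64)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    lut = (sizes > max_removed_size).astype(np.int64)
    lut[0] = 0
    return _compact_relabel(lut[labels] * labels)


def fill_holes(labels: np.ndarray) -> np.ndarray:
    """Fill background regions fully enclosed by a single cell.

    Filling is per label: a pocket jointly enclosed by two different cells is
    left open, and background touching the image border is never filled. Only
    background pixels are ever claimed, so existing cells are untouched and
    the cell count never changes.
    """
    labels = np.asarray(labels).astype(np.int64)
    out = labels.copy()
    objects = ndimage.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        cell = labels[sl] == k
        filled = ndimage.binary_fill_holes(cell)
        hole = filled & ~cell & (out[sl] == 0)
        out[sl][hole] = k
    return out


def otsu_nuclei_threshold(nuclei: np.ndarray) -> float:
    """Otsu threshold of the nuclei image (fallback 0 for a constant image)."""
    nuclei = np.asarray(nuclei, dtype=np.float64)
    if np.ptp(nuclei) == 0:
        return 0.0
    return float(threshold_otsu(nuclei))


def postprocess(
    prob: np.ndarray,
    nuclei: np.ndarray,
    threshold: float = 0.5,
    nuclei_threshold: float | str = "otsu",
    max_removed_size: int = DEFAULT_MAX_REMOVED_SIZE,
    connectivity: int = 8,
) -> np.ndarray:
    """Binarize a probability map and apply the three cleanup steps in order.

    ``nuclei`` is the raw nuclei channel of the same ROI. ``nuclei_threshold``
    may be a float or ``"otsu"`` (computed on the nuclei image). Returns the
    final instance label mask.
    """
    prob = np.asarray(prob)
    nuclei = np.asarray(nuclei)
    if prob.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs nuclei {nuclei.shape}")
    if nuclei_threshold == "otsu":
        nuclei_threshold = otsu_nuclei_threshold(nuclei)
    labels = label_cells(binarize(prob, threshold), connectivity=connectivity)
    labels = remove_anucleate_cells(labels, nuclei, float(nuclei_threshold))
    labels = remove_tiny_objects(labels, max_removed_size)
    return fill_holes(labels)
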