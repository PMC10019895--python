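"""Segmentation evaluation: per-cell IoU and biology-driven quality metrics.

Two complementary views of segmentation quality:

* **Geometric** — the Jaccard index (IoU) between predicted and ground-truth
  pixel sets. The patch-level score is the mean over ground-truth cells of the
  IoU against each cell's best-overlapping predicted object (an unmatched
  truth cell scores 0).

* **Biological** — no ground truth needed. A segmented object only deserves to
  be called a *real cell* if it sits on nuclei signal: the default rule
  requires its mean nuclei intensity to reach a tenth of the grayscale range
  of the nuclei image (robust maximum, so hot pixels don't inflate the scale).
  And because lineage markers such as CD3 (T cells) and CD20 (B cells) are
  never co-expressed by one cell, any object gated positive for both members
  of such an exclusive pair exposes a segmentation or gating error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.filters import threshold_otsu

from imcseg.io import CellTable, ChannelStack, PanelConfig

__all__ = [
    "MetricsReport",
    "jaccard",
    "mean_patch_iou",
    "real_cell_fraction",
    "double_positive_rate",
    "evaluate",
]

# "real cell" rule: mean nuclei intensity must reach this fraction of the
# nuclei image's robust grayscale maximum
REAL_CELL_GRAYSCALE_FRACTION = 0.10
ROBUST_MAX_PERCENTILE = 99.9


@dataclass
class MetricsReport:
    """Aggregate evaluation of one segmented ROI."""

    n_cells: int
    pct_real_cells: float
    pct_double_positive: dict[tuple[str, str], float] = field(default_factory=dict)
    mean_iou: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_real_cells <= 100.0:
            raise ValueError("pct_real_cells must be within [0, 100]")
        for pair, pct in self.pct_double_positive.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"double-positive rate for {pair} outside [0, 100]")
        if self.mean_iou is not None and not 0.0 <= self.mean_iou <= 1.0:
            raise ValueError("mean_iou must be within [0, 1]")

    def to_text(self) -> str:
        lines = [f"n_cells\t{self.n_cells}", f"pct_real_cells\t{self.pct_real_cells:.4f}"]
        if self.mean_iou is not None:
            lines.append(f"mean_iou\t{self.mean_iou:.6f}")
        for (a, b), pct in sorted(self.pct_double_positive.items()):
            lines.append(f"pct_double_positive_{a}_{b}\t{pct:.4f}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def _as_pixel_set(obj) -> set[tuple[int, int]]:
    arr = np.asarray(obj)
    if arr.dtype == bool or (arr.ndim == 2 and arr.shape[1] != 2):
        rows, cols = np.nonzero(arr)
        return set(zip(rows.tolist(), cols.tolist()))
    return {tuple(p) for p in obj}


def jaccard(a, b) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| between two pixel sets.

    Accepts sets of (row, col) pairs or boolean masks. Undefined (raises) when
    both sets are empty.
    """
    sa, sb = _as_pixel_set(a), _as_pixel_set(b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(sa & sb) / len(union)


def mean_patch_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over ground-truth cells of the best-overlap IoU.

    Each ground-truth cell is paired with the predicted object sharing the
    most pixels with it (ties broken toward the smaller predicted label);
    a truth cell overlapped by no prediction scores 0. Predicted objects
    matching no truth cell do not enter the mean. Raises if the ground truth
    contains no cells.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    if truth_ids.size == 0:
        raise ValueError("ground truth contains no cells; mean IoU undefined")
    pred_sizes = np.bincount(pred.ravel())
    truth_sizes = np.bincount(truth.ravel())
    # contingency counts over the truth foreground
    t = truth.ravel()
    p = pred.ravel()
    fg = t > 0
    pairs = t[fg].astype(np.int64) * (int(pred.max()) + 1) + p[fg].astype(np.int64)
    uniq, counts = np.unique(pairs, return_counts=True)
    t_of = uniq // (int(pred.max()) + 1)
    p_of = uniq % (int(pred.max()) + 1)
    ious = []
    for tid in truth_ids:
        sel = (t_of == tid) & (p_of > 0)
        if not sel.any():
            ious.append(0.0)
            continue
        cand_pred = p_of[sel]
        cand_inter = counts[sel]
        best = np.lexsort((cand_pred, -cand_inter))[0]  # max overlap, then smallest label
        inter = int(cand_inter[best])
        pid = int(cand_pred[best])
        union = int(truth_sizes[tid]) + int(pred_sizes[pid]) - inter
        ious.append(inter / union)
    return float(np.mean(ious))


def nuclei_positivity_threshold(nuclei_plane: np.ndarray,
                                fraction: float = REAL_CELL_GRAYSCALE_FRACTION) -> float:
    """The real-cell threshold: ``fraction`` of the nuclei image's robust max.

    The robust maximum is the 99.9th-percentile intensity, so rare aberrant
    hot pixels do not stretch the grayscale range.
    """
    robust_max = float(np.percentile(np.asarray(nuclei_plane, dtype=np.float64),
                                     ROBUST_MAX_PERCENTILE))
    return fraction * robust_max


def real_cell_fraction(
    table: CellTable,
    nuclei_plane: np.ndarray,
    nuclei_marker: str,
    threshold: float | None = None,
) -> tuple[int, float]:
    """Count cells and the percentage qualifying as real.

    A cell is *real* iff its mean nuclei intensity is at least the threshold
    (default: 10% of the nuclei image's robust grayscale maximum, see
    :func:`nuclei_positivity_threshold`). Returns ``(n_cells, pct_real)``.
    """
    if len(table) == 0:
        raise ValueError("cell table is empty; real-cell fraction undefined")
    if nuclei_marker not in table.markers:
        raise KeyError(f"nuclei marker {nuclei_marker!r} not in table markers {table.markers}")
    if threshold is None:
        threshold = nuclei_positivity_threshold(nuclei_plane)
    means = table.df[f"mean_{nuclei_marker}"].to_numpy(dtype=np.float64)
    n = len(means)
    real = int((means >= threshold).sum())
    return n, 100.0 * real / n


def _marker_threshold(values: np.ndarray, rule) -> float:
    if isinstance(rule, (int, float)):
        return float(rule)
    if rule == "otsu":
        vals = np.asarray(values, dtype=np.float64)
        if np.ptp(vals) == 0:
            return float(vals[0])  # constant distribution: nothing exceeds it
        return float(threshold_otsu(vals))
    raise ValueError(f"unknown positivity rule {rule!r}")


def double_positive_rate(
    table: CellTable,
    pair: tuple[str, str],
    positivity: Mapping[str, float] | str = "otsu",
) -> float:
    """Percentage of cells gated positive for *both* exclusive markers.

    A cell is positive for a marker iff its mean intensity strictly exceeds
    that marker's threshold. ``positivity`` is either ``"otsu"`` (threshold
    each marker by Otsu on its per-cell mean distribution) or a mapping
    ``marker -> threshold``.
    """
    a, b = pair
    for m in (a, b):
        if m not in table.markers:
            raise KeyError(f"marker {m!r} not in table markers {table.markers}")
    if len(table) == 0:
        raise ValueError("cell table is empty; double-positive rate undefined")
    va = table.df[f"mean_{a}"].to_numpy(dtype=np.float64)
    vb = table.df[f"mean_{b}"].to_numpy(dtype=np.float64)
    if isinstance(positivity, str):
        ta = _marker_threshold(va, positivity)
        tb = _marker_threshold(vb, positivity)
    else:
        ta = float(positivity[a])
        tb = float(positivity[b])
    both = int(((va > ta) & (vb > tb)).sum())
    return 100.0 * both / len(table)


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray | None,
    stack: ChannelStack,
    panel: PanelConfig,
    table: CellTable | None = None,
    positivity: Mapping[str, float] | str = "otsu",
) -> MetricsReport:
    """Full evaluation of a predicted label mask on one ROI.

    Biological metrics (cell count, real-cell percentage, double-positive rate
    per exclusive pair) are always computed from the raw stack; the geometric
    mean IoU is filled in only when a ground-truth label mask is supplied.
    ``table`` may pass a precomputed :func:`~imcseg.quantify.cell_intensities`
    result to avoid re-measuring.
    """
    from imcseg.quantify import cell_intensities  # local import to avoid a cycle

    panel.validate_for(stack)
    if table is None:
        table = cell_intensities(pred, stack)
    n_cells = len(table)
    if n_cells:
        n_cells, pct_real = real_cell_fraction(
            table, stack.channel(panel.nuclei_channel), panel.nuclei_channel
        )
        dp = {
            pair: double_positive_rate(table, pair, positivity)
            for pair in panel.exclusive_pairs
        }
    else:
        pct_real = 0.0
        dp = {pair: 0.0 for pair in panel.exclusive_pairs}
    miou = mean_patch_iou(pred, truth) if truth is not None else None
    return MetricsReport(n_cells=n_cells, pct_real_cells=pct_real,
                         pct_double_positive=dp, mean_iou=miou)
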