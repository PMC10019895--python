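"""Desk-scale evaluation benchmarks on synthetic scenes.

Three standard experiments, all fully reproducible from one master seed:

* ``iou_benchmark`` — train the CPU-profile U-Net (base_filters=16) on
  patches from synthetic scenes and score the mean per-cell IoU on 90
  held-out 128x128 patches from unseen scenes.
* ``real_cell_benchmark`` — segment scenes contaminated with 10% anucleate
  objects through the full post-processing chain and report the mean
  percentage of surviving objects that qualify as real cells.
* ``double_positive_benchmark`` — segment scenes holding only CD3+ T cells
  and CD20+ B cells (true co-expression rate zero) and report the mean
  percentage of cells gated positive for both markers, i.e. the
  false-positive rate from merged or mis-gated objects.

Every scene seed is derived from the master seed so independent runs with the
same seed agree bit for bit.
"""

from __future__ import annotations

import numpy as np

from imcseg.metrics import double_positive_rate, mean_patch_iou, real_cell_fraction
from imcseg.net import NetConfig, UNet, binarize, predict, train
from imcseg.patching import split_patches
from imcseg.postprocessing import _compact_relabel, label_cells, postprocess
from imcseg.quantify import cell_intensities
from imcseg.synthetic import (
    CellType,
    SceneParams,
    generate_scene,
    make_training_set,
    scene_composite,
)

__all__ = [
    "benchmark_net_config",
    "train_benchmark_model",
    "iou_benchmark",
    "real_cell_benchmark",
    "double_positive_benchmark",
]

# seed offsets for the independent scene families
_TRAIN_OFFSET = 1
_IOU_EVAL_OFFSET = 1001
_REAL_CELL_OFFSET = 101
_DOUBLE_POS_OFFSET = 201
_SEED_SPAN = 100_000  # master seeds map to disjoint seed blocks
_MOD = 2 ** 31


def _derive(master_seed: int, offset: int) -> int:
    return (master_seed * _SEED_SPAN + offset) % _MOD


def benchmark_net_config(seed: int = 0) -> NetConfig:
    """CPU-profile training configuration: base 16 filters, 25 epochs max,
    early stop at patience 10 on a 10% validation split."""
    return NetConfig(depth=4, base_filters=16, batch_size=16, max_epochs=25,
                     early_stop_patience=10, validation_fraction=0.1, seed=seed)


def train_benchmark_model(seed: int = 0, n_train_scenes: int = 50):
    """Train on ~200 patches cut from ``n_train_scenes`` default 256x256
    scenes; returns the fitted model and its training log."""
    params = [SceneParams(seed=_derive(seed, _TRAIN_OFFSET + i))
              for i in range(n_train_scenes)]
    examples = make_training_set(params)
    model = UNet(benchmark_net_config(seed))
    log = train(model, examples)
    return model, log


def iou_benchmark(model: UNet, seed: int = 0, n_patches: int = 90) -> float:
    """Mean per-cell IoU over held-out patches from scenes the model never saw.

    Each scene is composited and segmented whole; the binary prediction and
    the ground truth are then scored patchwise: instances are the connected
    components of the prediction within the patch, matched against the truth
    cells clipped to the patch. Returns the unweighted mean of the per-patch
    mean IoUs.
    """
    size = model.config.patch_size
    ious: list[float] = []
    scene_idx = 0
    while len(ious) < n_patches:
        scene = generate_scene(SceneParams(seed=_derive(seed, _IOU_EVAL_OFFSET + scene_idx)))
        scene_idx += 1
        comp = scene_composite(scene)
        pred_bin = binarize(predict(model, comp))
        for patch in split_patches(comp, size):
            r0, c0 = patch.origin_row, patch.origin_col
            truth_tile = scene.truth[r0:r0 + size, c0:c0 + size]
            if truth_tile.max() == 0:
                continue
            pred_lab = label_cells(pred_bin[r0:r0 + size, c0:c0 + size])
            ious.append(mean_patch_iou(pred_lab, _compact_relabel(truth_tile)))
            if len(ious) >= n_patches:
                break
    return float(np.mean(ious))


def _segment_scene(model: UNet, scene) -> np.ndarray:
    comp = scene_composite(scene)
    prob = predict(model, comp)
    nuclei = scene.stack.channel(scene.params.nuclei_channel).astype(np.float64)
    return postprocess(prob, nuclei)


def real_cell_benchmark(model: UNet, seed: int = 0, n_scenes: int = 18) -> float:
    """Mean real-cell percentage across scenes with 10% anucleate objects."""
    pcts: list[float] = []
    for i in range(n_scenes):
        scene = generate_scene(SceneParams(anucleate_fraction=0.1,
                                           seed=_derive(seed, _REAL_CELL_OFFSET + i)))
        labels = _segment_scene(model, scene)
        table = cell_intensities(labels, scene.stack)
        nuclei = scene.stack.channel("DNA").astype(np.float64)
        _, pct = real_cell_fraction(table, nuclei, "DNA")
        pcts.append(pct)
    return float(np.mean(pcts))


def _exclusive_pair_types() -> list[CellType]:
    return [
        CellType("T_cell", membrane={"CD3": 25.0}),
        CellType("B_cell", membrane={"CD20": 25.0}),
    ]


def double_positive_benchmark(model: UNet, seed: int = 0, n_scenes: int = 18) -> float:
    """Mean CD3/CD20 double-positive rate across two-lineage scenes where the
    true co-expression rate is zero by construction."""
    rates: list[float] = []
    for i in range(n_scenes):
        scene = generate_scene(SceneParams(cell_types=_exclusive_pair_types(),
                                           min_gap=3.0,
                                           seed=_derive(seed, _DOUBLE_POS_OFFSET + i)))
        labels = _segment_scene(model, scene)
        table = cell_intensities(labels, scene.stack)
        rates.append(double_positive_rate(table, ("CD3", "CD20"), "otsu"))
    return float(np.mean(rates))
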