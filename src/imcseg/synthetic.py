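"""Synthetic IMC-like scenes with exact ground truth.

Real acquisitions are stacks of ion-count images: bright compact nuclei on the
DNA-intercalator channel, ring-like membrane signal where lineage markers sit
on the cell surface, cytoplasmic markers filling whole cells, sparse Poisson
background, and rare isolated hot pixels. The generator emulates exactly these
features with randomly oriented ellipse cells placed by rejection sampling at
a guaranteed border gap, so every pixel's true owner is known. That makes the
whole pipeline — training, post-processing, quantification, and both metric
families — testable without any external data.

Cell types carry marker profiles: *membrane* markers render as a ring at the
cell boundary, *lineage* (cytoplasmic) markers fill the footprint. The default
panel mirrors a lymphoid tissue: DNA nuclei plus CD3/CD8 T cells, CD20 B
cells, CD68 macrophages and PanKeratin epithelium, giving the two classic
mutually exclusive pairs (CD3, CD20) and (PanKeratin, CD8) whose true
co-expression rate is zero by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from imcseg.compositing import make_composite
from imcseg.io import ChannelStack, PanelConfig, write_channel_stack, write_label_mask
from imcseg.net import TrainingExample
from imcseg.patching import DEFAULT_PATCH_SIZE

__all__ = [
    "CellType",
    "SceneParams",
    "SyntheticScene",
    "ScenePlacementError",
    "generate_scene",
    "make_training_set",
    "default_cell_types",
    "default_panel",
    "scene_composite",
    "save_scene",
]

MAX_INTENSITY = 65535  # 16-bit storage ceiling


class ScenePlacementError(RuntimeError):
    """Raised when not all cells fit at the requested gap; carries the count."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved} of {requested} cells at the requested minimum gap"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class CellType:
    """A named marker profile: membrane markers ring the boundary, lineage
    markers fill the footprint; values are mean ion counts."""

    name: str
    membrane: dict[str, float] = field(default_factory=dict)
    lineage: dict[str, float] = field(default_factory=dict)


def default_cell_types() -> list[CellType]:
    """Lymphoid-tissue-like panel with two mutually exclusive marker pairs."""
    return [
        CellType("T_cell", membrane={"CD3": 25.0, "CD8": 18.0}),
        CellType("B_cell", membrane={"CD20": 25.0}),
        CellType("macrophage", membrane={"CD68": 20.0}),
        CellType("epithelial", lineage={"PanKeratin": 25.0}),
    ]


@dataclass
class SceneParams:
    """Everything that defines one synthetic acquisition.

    Intensities are mean ion counts (Poisson sampling adds shot noise on top
    of ``background_rate`` everywhere). ``min_gap`` separates cell *borders*,
    guaranteed via bounding circles. ``anucleate_fraction`` of the cells are
    rendered without a nucleus disk — the contamination the first
    post-processing rule must remove.
    """

    height: int = 256
    width: int = 256
    n_cells: int = 60
    radius_range: tuple[float, float] = (5.0, 9.0)
    min_gap: float = 3.0
    cell_types: list[CellType] = field(default_factory=default_cell_types)
    nuclei_channel: str = "DNA"
    nuclei_intensity: float = 40.0
    nuclei_radius_fraction: float = 0.6
    membrane_ring_fraction: float = 0.75  # ring spans this fraction of the radius outward
    background_rate: float = 0.5
    hot_pixel_rate: float = 1e-4
    hot_pixel_value: float = 500.0
    anucleate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"radius_range must satisfy 0 < min <= max, got {self.radius_range}")
        if 2 * hi + 2 > min(self.height, self.width):
            raise ValueError("cells do not fit in the frame at the requested radii")
        if not 0 < self.nuclei_radius_fraction < 1:
            raise ValueError("nuclei_radius_fraction must be in (0, 1)")
        if not 0 < self.membrane_ring_fraction < 1:
            raise ValueError("membrane_ring_fraction must be in (0, 1)")
        if not 0.0 <= self.anucleate_fraction <= 1.0:
            raise ValueError("anucleate_fraction must be in [0, 1]")
        if not 0.0 <= self.hot_pixel_rate <= 1.0:
            raise ValueError("hot_pixel_rate must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not self.cell_types:
            raise ValueError("need at least one cell type")

    def marker_names(self) -> list[str]:
        """Channel order: nuclei stain first, then markers by first appearance."""
        names = [self.nuclei_channel]
        for ct in self.cell_types:
            for m in list(ct.membrane) + list(ct.lineage):
                if m not in names:
                    names.append(m)
        return names


@dataclass
class SyntheticScene:
    """A generated stack plus its exact ground truth."""

    stack: ChannelStack
    truth: np.ndarray
    cell_types: list[str]
    nucleated: np.ndarray
    params: SceneParams

    @property
    def n_cells(self) -> int:
        return int(self.truth.max())


def default_panel(params: SceneParams | None = None) -> PanelConfig:
    """Panel matching the generator's channels: all non-nuclei markers feed the
    membrane composite plane; exclusive pairs are declared when present."""
    params = params if params is not None else SceneParams()
    markers = params.marker_names()
    membrane = [m for m in markers if m != params.nuclei_channel]
    pairs = [p for p in [("CD3", "CD20"), ("PanKeratin", "CD8")]
             if p[0] in markers and p[1] in markers]
    return PanelConfig(nuclei_channel=params.nuclei_channel,
                       membrane_channels=membrane, exclusive_pairs=pairs)


def _ellipse_mask(shape, cy, cx, a, b, theta) -> np.ndarray:
    """Boolean mask of an ellipse (semi-axes a, b, rotation theta)."""
    h, w = shape
    r0 = max(0, int(np.floor(cy - max(a, b) - 1)))
    r1 = min(h, int(np.ceil(cy + max(a, b) + 2)))
    c0 = max(0, int(np.floor(cx - max(a, b) - 1)))
    c1 = min(w, int(np.ceil(cx + max(a, b) + 2)))
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy = rows - cy
    dx = cols - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = u * u + v * v <= 1.0
    return out


def generate_scene(params: SceneParams, max_attempts_per_cell: int = 500) -> SyntheticScene:
    """Generate one scene, fully reproducible from ``params.seed``.

    Cells are random ellipses placed by rejection sampling so that bounding
    circles keep at least ``min_gap`` pixels between any two cell borders.
    Raises :class:`ScenePlacementError` if the requested count cannot be
    placed within the attempt budget.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    lo, hi = params.radius_range

    centers: list[tuple[float, float]] = []
    axes: list[tuple[float, float]] = []
    thetas: list[float] = []
    budget = max_attempts_per_cell * max(params.n_cells, 1)
    while len(centers) < params.n_cells and budget > 0:
        budget -= 1
        a, b = rng.uniform(lo, hi, size=2)
        r = max(a, b)
        cy = rng.uniform(r + 1, h - r - 2)
        cx = rng.uniform(r + 1, w - r - 2)
        ok = all(
            np.hypot(cy - py, cx - px) >= r + max(pa, pb) + params.min_gap
            for (py, px), (pa, pb) in zip(centers, axes)
        )
        if ok:
            centers.append((cy, cx))
            axes.append((a, b))
            thetas.append(rng.uniform(0, np.pi))
    if len(centers) < params.n_cells:
        raise ScenePlacementError(params.n_cells, len(centers))

    n = params.n_cells
    type_idx = rng.integers(len(params.cell_types), size=n)
    nucleated = np.ones(n, dtype=bool)
    n_anuc = int(round(params.anucleate_fraction * n))
    if n_anuc:
        nucleated[rng.choice(n, size=n_anuc, replace=False)] = False

    markers = params.marker_names()
    lam = {m: np.zeros((h, w), dtype=np.float64) for m in markers}
    truth = np.zeros((h, w), dtype=np.int64)
    for k in range(n):
        (cy, cx), (a, b), th = centers[k], axes[k], thetas[k]
        ct = params.cell_types[type_idx[k]]
        foot = _ellipse_mask((h, w), cy, cx, a, b, th)
        truth[foot] = k + 1
        ring = foot & ~_ellipse_mask(
            (h, w), cy, cx, a * params.membrane_ring_fraction,
            b * params.membrane_ring_fraction, th
        )
        for m, mean in ct.membrane.items():
            lam[m][ring] += mean
        for m, mean in ct.lineage.items():
            lam[m][foot] += mean
        if nucleated[k]:
            nuc = _ellipse_mask((h, w), cy, cx, a * params.nuclei_radius_fraction,
                                b * params.nuclei_radius_fraction, th)
            lam[params.nuclei_channel][nuc] += params.nuclei_intensity

    data = np.empty((len(markers), h, w), dtype=np.uint16)
    for i, m in enumerate(markers):
        counts = rng.poisson(lam[m] + params.background_rate)
        data[i] = np.minimum(counts, MAX_INTENSITY).astype(np.uint16)

    if params.hot_pixel_rate > 0:
        n_sites = rng.binomial(data.size, params.hot_pixel_rate)
        if n_sites:
            flat_idx = rng.choice(data.size, size=n_sites, replace=False)
            data.ravel()[flat_idx] = min(int(params.hot_pixel_value), MAX_INTENSITY)

    stack = ChannelStack(data, markers, roi_id=f"synthetic-seed{params.seed}")
    return SyntheticScene(
        stack=stack,
        truth=truth,
        cell_types=[params.cell_types[i].name for i in type_idx],
        nucleated=nucleated,
        params=params,
    )


def scene_composite(scene: SyntheticScene, **composite_kwargs):
    """Composite of a scene's stack under its default panel."""
    return make_composite(scene.stack, default_panel(scene.params), **composite_kwargs)


def make_training_set(
    params_list: Sequence[SceneParams],
    patch_size: int = DEFAULT_PATCH_SIZE,
) -> list[TrainingExample]:
    """Generate scenes, composite them with default settings, and cut
    supervised patches (target = ground-truth foreground)."""
    from imcseg.patching import split_patches

    examples: list[TrainingExample] = []
    for params in params_list:
        if params.height < patch_size or params.width < patch_size:
            raise ValueError(
                f"scene {params.height}x{params.width} smaller than patch size {patch_size}"
            )
        scene = generate_scene(params)
        composite = scene_composite(scene)
        fg = (scene.truth > 0).astype(np.float32)
        for patch in split_patches(composite, patch_size):
            r0, c0 = patch.origin_row, patch.origin_col
            tgt = np.zeros((patch_size, patch_size), dtype=np.float32)
            tile = fg[r0:r0 + patch_size, c0:c0 + patch_size]
            tgt[:tile.shape[0], :tile.shape[1]] = tile
            examples.append(TrainingExample(patch=patch.pixels, target=tgt))
    return examples


def save_scene(scene: SyntheticScene, out_dir: str | os.PathLike) -> None:
    """Write a scene to disk: one multi-page TIFF stack plus per-channel
    single-marker TIFFs (as an acquisition export would provide), the truth
    label mask, and a ground-truth CSV (cell id, type, nucleated flag)."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_channel_stack(scene.stack, out / "stack.tiff")
    channels = out / "channels"
    channels.mkdir(exist_ok=True)
    for i, name in enumerate(scene.stack.channel_names):
        tifffile.imwrite(channels / f"{name}.tiff", scene.stack.data[i],
                         photometric="minisblack")
    write_label_mask(scene.truth, out / "truth.tiff")
    pd.DataFrame({
        "cell_id": np.arange(1, scene.n_cells + 1),
        "cell_type": scene.cell_types,
        "nucleated": scene.nucleated.astype(int),
    }).to_csv(out / "truth_cells.csv", index=False)
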