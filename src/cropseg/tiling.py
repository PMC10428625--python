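"""Patch extraction, augmentation, plot-aware splitting and tile blending.

Training samples are square patches cut from full scenes on a sliding
window.  Splits are made at the level of whole plots (fields) so that no
plot contributes pixels to both the training and validation sets — the
spatial analogue of subject-wise cross-validation.  Scene-level inference
averages overlapping per-tile softmax maps back into one probability
raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import IGNORE_LABEL, SceneBundle


@dataclass
class PatchSet:
    """Aligned model inputs and labels for N patches.

    ``inputs`` is N×S×S×C float in [0, 1], ``labels`` N×S×S int with −1 for
    ignore, ``plot_ids`` one frozenset of plot ids per patch (provenance
    for leakage-free splitting).  ``plots``, when present, is the N×S×S
    per-pixel plot-id raster that allows pixel-exact split masking.
    """

    inputs: np.ndarray
    labels: np.ndarray
    plot_ids: list[frozenset[int]]
    plots: np.ndarray | None = None

    def __post_init__(self):
        if len(self.inputs) != len(self.labels) or len(self.inputs) != len(self.plot_ids):
            raise ValueError("inputs, labels and plot_ids must have equal length")
        if self.inputs.shape[1:3] != self.labels.shape[1:3]:
            raise ValueError("inputs and labels must share patch size")
        if self.plots is not None and self.plots.shape != self.labels.shape:
            raise ValueError("plots raster must align with labels")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def patch_size(self) -> int:
        return self.inputs.shape[1]

    def subset(self, idx) -> "PatchSet":
        idx = np.asarray(idx, dtype=np.int64)
        return PatchSet(
            inputs=self.inputs[idx],
            labels=self.labels[idx],
            plot_ids=[self.plot_ids[i] for i in idx],
            plots=None if self.plots is None else self.plots[idx],
        )


def tile_offsets(height: int, width: int, size: int, stride: int) -> list[tuple[int, int]]:
    """Top-left offsets of a sliding window covering an H×W raster.

    The last row/column of tiles is shifted inward so every pixel is
    covered without stepping outside the raster.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if size > height or size > width:
        raise ValueError(f"tile size {size} exceeds raster {height}×{width}")

    def starts(n: int) -> list[int]:
        s = list(range(0, n - size + 1, stride))
        if s[-1] != n - size:
            s.append(n - size)
        return s

    return [(r, c) for r in starts(height) for c in starts(width)]


def _reflect_pad_to(arr: np.ndarray, h: int, w: int, ignore: bool = False) -> np.ndarray:
    """Reflect-pad the first two axes up to (h, w)."""
    ph, pw = h - arr.shape[0], w - arr.shape[1]
    if ph == 0 and pw == 0:
        return arr
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad, mode="reflect")


def extract_patches(
    scene: SceneBundle,
    input3: np.ndarray,
    size: int,
    stride: int = 128,
) -> PatchSet:
    """Sliding-window patches of the model input paired with label patches.

    Scenes smaller than one tile are reflection-padded up to the tile
    size.  Each patch records the set of plot ids it overlaps.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    h, w = input3.shape[:2]
    if scene.labels.shape != (h, w):
        raise ValueError("input raster and scene labels must share H×W")
    hp, wp = max(h, size), max(w, size)
    x = _reflect_pad_to(input3, hp, wp)
    y = _reflect_pad_to(scene.labels, hp, wp)
    plots = _reflect_pad_to(scene.plots, hp, wp)

    offs = tile_offsets(hp, wp, size, stride)
    inputs = np.stack([x[r : r + size, c : c + size] for r, c in offs])
    labels = np.stack([y[r : r + size, c : c + size] for r, c in offs])
    plot_patches = np.stack([plots[r : r + size, c : c + size] for r, c in offs])
    plot_ids = [
        frozenset(int(p) for p in np.unique(pp) if p != 0) for pp in plot_patches
    ]
    return PatchSet(inputs=inputs.astype(np.float32), labels=labels.astype(np.int64),
                    plot_ids=plot_ids, plots=plot_patches.astype(np.int64))


def apply_dihedral(arr: np.ndarray, flip_h: bool, flip_v: bool, k_rot: int) -> np.ndarray:
    """Apply flips and a 90°·k rotation to the first two axes of a patch."""
    if flip_h:
        arr = arr[:, ::-1]
    if flip_v:
        arr = arr[::-1, :]
    if k_rot % 4:
        arr = np.rot90(arr, k_rot % 4, axes=(0, 1))
    return arr


def augment(batch: PatchSet, seed: int = 0) -> PatchSet:
    """Random flips and 90° rotations, identical for input and label."""
    rng = np.random.default_rng(seed)
    inputs = np.empty_like(batch.inputs)
    labels = np.empty_like(batch.labels)
    for i in range(len(batch)):
        fh, fv = rng.random(2) < 0.5
        k = int(rng.integers(0, 4))
        inputs[i] = apply_dihedral(batch.inputs[i], fh, fv, k)
        labels[i] = apply_dihedral(batch.labels[i], fh, fv, k)
    return PatchSet(inputs=inputs, labels=labels, plot_ids=list(batch.plot_ids))


def split_by_plot(
    patches: PatchSet,
    fractions: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
) -> tuple[PatchSet, PatchSet]:
    """Partition patches into train/val by plot id, with no plot shared.

    Plots (not patches) are shuffled and allotted to the two splits by the
    given fractions.  When the patch set carries a per-pixel plot raster,
    each side receives the patches overlapping its plots with all other
    pixels masked to ignore, so no plot contributes labeled pixels to both
    sides (a patch with no labeled pixels for a side is dropped from that
    side).  Without a plot raster, a patch joins a split only if every
    plot it touches belongs to that split (straddling patches dropped).
    """
    f_train, f_val = fractions
    if f_train + f_val > 1 + 1e-9:
        raise ValueError("fractions must sum to at most 1")
    all_plots = sorted({p for s in patches.plot_ids for p in s})
    if len(all_plots) < 2:
        raise ValueError("need at least 2 plots for a plot-level split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_plots))
    n_train = int(round(f_train * len(all_plots)))
    n_val = int(round(f_val * len(all_plots)))
    train_plots = {all_plots[i] for i in order[:n_train]}
    val_plots = {all_plots[i] for i in order[n_train : n_train + n_val]}

    if patches.plots is None:
        tr_idx = [i for i, s in enumerate(patches.plot_ids) if s and s <= train_plots]
        va_idx = [i for i, s in enumerate(patches.plot_ids) if s and s <= val_plots]
        return patches.subset(tr_idx), patches.subset(va_idx)

    def _masked(side_plots: set[int]) -> PatchSet:
        keep = np.isin(patches.plots, sorted(side_plots)) & (patches.labels != -1)
        idx = [i for i in range(len(patches)) if keep[i].any()]
        sub = patches.subset(idx)
        if len(idx):
            k = keep[idx]
            sub.labels = np.where(k, sub.labels, -1)
            sub.plot_ids = [
                frozenset(int(p) for p in np.unique(pp[m]) if p != 0)
                for pp, m in zip(sub.plots, k)
            ]
        return sub

    return _masked(train_plots), _masked(val_plots)


def blend_tiles(
    prob_tiles: list[tuple[np.ndarray, tuple[int, int]]],
    height: int,
    width: int,
) -> np.ndarray:
    """Average overlapping S×S×K probability tiles into an H×W×K map.

    Every pixel must be covered by at least one tile; the averaged map
    remains a probability simplex per pixel.
    """
    k = prob_tiles[0][0].shape[2]
    acc = np.zeros((height, width, k), dtype=np.float64)
    cover = np.zeros((height, width), dtype=np.int64)
    for tile, (r, c) in prob_tiles:
        s0, s1 = tile.shape[:2]
        if r < 0 or c < 0 or r + s0 > height or c + s1 > width:
            raise ValueError(f"tile at ({r}, {c}) falls outside {height}×{width}")
        acc[r : r + s0, c : c + s1] += tile
        cover[r : r + s0, c : c + s1] += 1
    if np.any(cover == 0):
        n = int((cover == 0).sum())
        raise ValueError(f"{n} pixels not covered by any tile")
    return (acc / cover[..., None]).astype(np.float32)
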