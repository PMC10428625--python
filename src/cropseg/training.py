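"""Training loop (Adam, masked cross-entropy) and tiled scene inference.

Published training configuration: Adam at learning rate 0.001, 120 epochs,
batch size 16, with each algorithm trained five times and metrics reported
as mean ± sample SD across repeats.  The loss is categorical cross-entropy
over non-ignore pixels only; ignore-labeled pixels (−1) contribute neither
loss nor gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn, tiling
from .evaluation import MetricsReport
from .model import MSSNet
from .raster_io import IGNORE_LABEL
from .tiling import PatchSet


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 120
    batch_size: int = 16
    n_repeats: int = 5
    seeds: list[int] | None = None
    augment: bool = True
    seed: int = 0
    val_every: int = 1  # validate every k-th epoch (validation is not free:
    # it includes a batch-norm recalibration pass)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.seeds is None:
            self.seeds = [self.seed + i for i in range(self.n_repeats)]
        if len(self.seeds) != self.n_repeats:
            raise ValueError("len(seeds) must equal n_repeats")


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over non-ignore pixels and its logit gradient.

    ``logits`` is N×K×H×W, ``labels`` N×H×W with −1 ignored.  The gradient
    is (softmax − onehot)/n_valid, zero at ignored pixels.
    """
    probs = nn.softmax_channels(logits)
    valid = labels != IGNORE_LABEL
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all labels are ignore; nothing to train on")
    safe = np.where(valid, labels, 0)
    n, k, h, w = logits.shape
    p_true = np.take_along_axis(probs, safe[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.clip(p_true[valid], 1e-12, None)).mean())
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, safe[:, None], 1.0, axis=1)
    grad = (probs - onehot) * (valid[:, None] / n_valid)
    return loss, grad.astype(np.float32)


def _batch_oa(logits: np.ndarray, labels: np.ndarray) -> float:
    valid = labels != IGNORE_LABEL
    pred = logits.argmax(axis=1)
    return float((pred[valid] == labels[valid]).mean())


def _nchw(inputs: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(inputs.transpose(0, 3, 1, 2))


def recalibrate_batchnorm(
    model: MSSNet, inputs: np.ndarray, max_patches: int = 32
) -> None:
    """Set batch-norm running statistics to the exact statistics of one
    training-set forward pass ("precise BN").

    Running averages tracked with momentum lag badly over the short
    training schedules used here; recomputing them over (up to
    ``max_patches``) training patches makes inference-mode normalization
    consistent with the trained weights.
    """
    bns = [l for l in nn.iter_layers(model) if isinstance(l, nn.BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.0
    try:
        model.forward_logits(_nchw(inputs[:max_patches]), train=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m
            bn._cache = None


def train(
    model: MSSNet,
    train_set: PatchSet,
    val_set: PatchSet | None,
    cfg: TrainConfig,
) -> tuple[MSSNet, dict]:
    """Train in place; returns the model and a per-epoch history dict.

    Fully reproducible from ``cfg.seed``: batch order and augmentation
    draws come from one seeded generator and all ops are deterministic.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if np.all(train_set.labels == IGNORE_LABEL):
        raise ValueError("training set has no labeled pixels")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: dict = {"train_loss": [], "train_oa": [], "val_loss": [], "val_oa": []}

    n = len(train_set)
    for epoch in range(cfg.epochs):
        batch_src = (
            tiling.augment(train_set, seed=int(rng.integers(2**31)))
            if cfg.augment
            else train_set
        )
        order = rng.permutation(n)
        losses, oas = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = _nchw(batch_src.inputs[idx])
            y = batch_src.labels[idx]
            if np.all(y == IGNORE_LABEL):
                continue
            logits = model.forward_logits(x, train=True)
            loss, dlogits = masked_cross_entropy(logits, y)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            oas.append(_batch_oa(logits, y))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_oa"].append(float(np.mean(oas)))
        if val_set is not None and len(val_set) > 0 and (epoch + 1) % cfg.val_every == 0:
            recalibrate_batchnorm(model, train_set.inputs)
            vl, voa = evaluate_patches(model, val_set)
            history["val_loss"].append(vl)
            history["val_oa"].append(voa)
    recalibrate_batchnorm(model, train_set.inputs)
    return model, history


def evaluate_patches(model: MSSNet, patches: PatchSet, batch_size: int = 8):
    """Masked loss and OA of a patch set under the current weights."""
    losses, correct, total = [], 0, 0
    for start in range(0, len(patches), batch_size):
        x = _nchw(patches.inputs[start : start + batch_size])
        y = patches.labels[start : start + batch_size]
        valid = y != IGNORE_LABEL
        if not np.any(valid):
            continue
        logits = model.forward_logits(x, train=False)
        loss, _ = masked_cross_entropy(logits, y)
        losses.append((loss, int(valid.sum())))
        pred = logits.argmax(axis=1)
        correct += int((pred[valid] == y[valid]).sum())
        total += int(valid.sum())
    if total == 0:
        raise ValueError("no labeled pixels to evaluate")
    wsum = sum(w for _, w in losses)
    return sum(l * w for l, w in losses) / wsum, correct / total


def predict_patches(model: MSSNet, inputs: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Per-pixel class predictions (N×S×S) for N×S×S×C inputs."""
    preds = []
    for start in range(0, len(inputs), batch_size):
        probs = model.forward(_nchw(inputs[start : start + batch_size]), train=False)
        preds.append(probs.argmax(axis=1))
    return np.concatenate(preds)


def predict_scene(
    model: MSSNet,
    input3: np.ndarray,
    tile: int = 256,
    stride: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Tiled inference over a full scene.

    Overlapping softmax tiles are averaged, then argmaxed.  Returns
    (label raster H×W, probability map H×W×K).  Scenes smaller than one
    tile are reflection-padded and cropped back.
    """
    h, w = input3.shape[:2]
    hp, wp = max(h, tile), max(w, tile)
    x = tiling._reflect_pad_to(input3, hp, wp)
    tiles = []
    for r, c in tiling.tile_offsets(hp, wp, tile, stride):
        patch = x[r : r + tile, c : c + tile]
        probs = model.forward(_nchw(patch[None]), train=False)[0]
        tiles.append((probs.transpose(1, 2, 0), (r, c)))
    blended = tiling.blend_tiles(tiles, hp, wp)[:h, :w]
    return blended.argmax(axis=2).astype(np.int64), blended


def repeat_runs(cfg: TrainConfig, run_fn) -> dict:
    """Run ``run_fn(seed) -> MetricsReport | dict`` once per seed and
    summarize each metric as mean ± sample SD.

    Returns {"runs": [...], "mean": {...}, "sd": {...}}.
    """
    flat_runs = []
    for seed in cfg.seeds:
        rep = run_fn(seed)
        d = rep.to_dict() if isinstance(rep, MetricsReport) else dict(rep)
        flat: dict[str, float] = {}
        for key, val in d.items():
            if isinstance(val, dict):
                for sub, v in val.items():
                    if v is not None:
                        flat[f"{key}.{sub}"] = v
            elif val is not None:
                flat[key] = val
        flat_runs.append(flat)
    keys = sorted(set().union(*flat_runs))
    mean = {k: float(np.mean([r[k] for r in flat_runs if k in r])) for k in keys}
    sd = {
        k: float(np.std([r[k] for r in flat_runs if k in r], ddof=1))
        if sum(k in r for r in flat_runs) >= 2
        else float("nan")
        for k in keys
    }
    return {"runs": flat_runs, "mean": mean, "sd": sd}
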