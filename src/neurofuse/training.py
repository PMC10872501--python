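"""Augmentation, the optimization loop, and best-k checkpointing.

Pre-training follows the self-supervised recipe: min–max intensity rescaling
to [0, 1], random crops after reflective padding, RAdam, and retention of the
k checkpoints with the best validation value of the training objective (no
labels are consulted for model selection).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .losses import ObjectiveSpec, compose_objective
from .nn.autograd import Tensor
from .nn.optim import RAdam, SGD

__all__ = ["AugmentationConfig", "TrainConfig", "Checkpoint", "minmax_rescale",
           "random_crop_padded", "augment_batch", "train", "evaluate_loss"]


@dataclass
class AugmentationConfig:
    pad: int = 8          # reflective padding, voxels per face
    crop: int = 64        # crop edge length
    rescale: bool = True  # min-max rescale each volume to [0, 1]
    share_offsets: bool = False  # same crop offset for both modalities

    def __post_init__(self):
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


@dataclass
class TrainConfig:
    epochs: int = 500
    lr: float = 4e-4
    optimizer: str = "radam"
    keep_checkpoints: int = 10
    seed: int = 0
    batch_size: int = 16

    def __post_init__(self):
        if self.keep_checkpoints < 1:
            raise ValueError("keep_checkpoints must be >= 1")
        if self.batch_size < 2:
            raise ValueError("contrastive training needs batch_size >= 2")


@dataclass
class Checkpoint:
    epoch: int
    val_loss: float
    states: dict = field(repr=False, default_factory=dict)  # modality -> state


def minmax_rescale(volume: np.ndarray) -> np.ndarray:
    """(v − min)/(max − min); a constant volume maps to all zeros."""
    v = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("volume contains non-finite voxels")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def random_crop_padded(volume: np.ndarray, cfg: AugmentationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Reflect-pad by cfg.pad on all faces, crop a cfg.crop³ block uniformly."""
    v = np.asarray(volume)
    if len(set(v.shape)) != 1 or v.ndim != 3:
        raise ValueError("volume must be cubic")
    padded = np.pad(v, cfg.pad, mode="reflect") if cfg.pad else v
    room = padded.shape[0] - cfg.crop
    if room < 0:
        raise ValueError(f"crop {cfg.crop} larger than padded extent {padded.shape[0]}")
    off = rng.integers(0, room + 1, size=3)
    return padded[off[0]:off[0] + cfg.crop,
                  off[1]:off[1] + cfg.crop,
                  off[2]:off[2] + cfg.crop]


def augment_batch(batch: dict, cfg: AugmentationConfig,
                  rng: np.random.Generator) -> dict:
    """Apply crops (and optional rescale) to a dict modality -> (n, s, s, s)."""
    out = {}
    mods = sorted(batch)
    n = len(batch[mods[0]])
    edge = batch[mods[0]].shape[1]
    room = edge + 2 * cfg.pad - cfg.crop
    if room < 0:
        raise ValueError(f"crop {cfg.crop} larger than padded extent {edge + 2 * cfg.pad}")
    offsets = rng.integers(0, room + 1, size=(n, len(mods), 3))
    for j, m in enumerate(mods):
        v = np.asarray(batch[m], dtype=np.float64)
        if cfg.rescale:
            lo = v.min(axis=(1, 2, 3), keepdims=True)
            hi = v.max(axis=(1, 2, 3), keepdims=True)
            span = np.where(hi > lo, hi - lo, 1.0)
            v = (v - lo) / span
        p = cfg.pad
        vp = np.pad(v, ((0, 0), (p, p), (p, p), (p, p)), mode="reflect") if p else v
        crops = np.empty((n, cfg.crop, cfg.crop, cfg.crop), dtype=v.dtype)
        for i in range(n):
            o = offsets[i, 0] if cfg.share_offsets else offsets[i, j]
            crops[i] = vp[i, o[0]:o[0] + cfg.crop, o[1]:o[1] + cfg.crop,
                          o[2]:o[2] + cfg.crop]
        out[m] = crops
    return out


def _forward_bundles(models: dict, batch: dict, spec: ObjectiveSpec):
    bundles, recons = {}, {}
    for m, model in models.items():
        x = Tensor(np.ascontiguousarray(batch[m][:, None], dtype=model.dtype))
        bundles[m] = model(x)
        if "AE" in spec.terms:
            if model.decoder is None:
                raise ValueError("objective includes AE but model has no decoder")
            z = bundles[m].global_raw.vectors
            recons[m] = (x, model.decoder(z))
    return bundles, recons or None


def evaluate_loss(models: dict, volumes: dict, idx: np.ndarray,
                  spec: ObjectiveSpec, cfg: TrainConfig,
                  aug: AugmentationConfig | None, rng) -> float:
    """Mean objective over batches of a split (penalty included)."""
    losses = []
    for start in range(0, len(idx) - 1, cfg.batch_size):
        bidx = idx[start:start + cfg.batch_size]
        if len(bidx) < 2:
            continue
        batch = {m: volumes[m][bidx] for m in volumes}
        if aug is not None:
            batch = augment_batch(batch, aug, rng)
        bundles, recons = _forward_bundles(models, batch, spec)
        bd = compose_objective(spec, bundles, rng, recons)
        losses.append(bd.total)
    return float(np.mean(losses))


def train(models: dict, volumes: dict, train_idx, val_idx,
          objective: ObjectiveSpec, cfg: TrainConfig,
          aug: AugmentationConfig | None = None,
          log_path: str | None = None,
          checkpoint_dir: str | None = None) -> list:
    """Optimize the composed objective; return the best-k checkpoints.

    ``models`` maps modality id -> ModalityModel; ``volumes`` maps modality id
    -> (n, s, s, s) arrays; rows are subject-paired across modalities.
    Multimodal objectives yield one checkpoint covering both encoders.
    Checkpoints are sorted by ascending validation loss.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if len(val_idx) < 2:
        raise ValueError("validation split is empty or too small")
    rng = np.random.default_rng(cfg.seed)
    params = []
    for model in models.values():
        model.train()
        params.extend(model.parameters())
    if cfg.optimizer.lower() == "radam":
        opt = RAdam(params, lr=cfg.lr)
    elif cfg.optimizer.lower() == "sgd":
        opt = SGD(params, lr=cfg.lr)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    log = []
    checkpoints: list[Checkpoint] = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order) - 1, cfg.batch_size):
            bidx = order[start:start + cfg.batch_size]
            if len(bidx) < 2:
                continue
            batch = {m: volumes[m][bidx] for m in volumes}
            if aug is not None:
                batch = augment_batch(batch, aug, rng)
            bundles, recons = _forward_bundles(models, batch, objective)
            bd = compose_objective(objective, bundles, rng, recons)
            opt.zero_grad()
            bd.total_tensor.backward()
            opt.step()
            step += 1
            log.append({"step": step, "epoch": epoch, "total": bd.total,
                        "per_term": {f"{t}{p}": v for (t, p), v in bd.per_term.items()},
                        "regularizer": bd.regularizer})
        for model in models.values():
            model.eval()
        val_loss = evaluate_loss(models, volumes, val_idx, objective, cfg,
                                 aug, np.random.default_rng(cfg.seed + 1))
        for model in models.values():
            model.train()
        ck = Checkpoint(epoch=epoch, val_loss=val_loss,
                        states={m: model.named_state() for m, model in models.items()})
        checkpoints.append(ck)
        checkpoints.sort(key=lambda c: (c.val_loss, -c.epoch))
        checkpoints = checkpoints[:cfg.keep_checkpoints]

    if log_path:
        with open(log_path, "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    if checkpoint_dir:
        save_checkpoints(checkpoints, checkpoint_dir, cfg)
    return checkpoints


def save_checkpoints(checkpoints: list, out_dir: str, cfg: TrainConfig):
    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for rank, ck in enumerate(checkpoints):
        blob = os.path.join(out_dir, f"ckpt_{rank:02d}.npz")
        flat = {f"{m}::{k}": v for m, st in ck.states.items() for k, v in st.items()}
        np.savez(blob, **flat)
        manifest.append({"rank": rank, "epoch": ck.epoch,
                         "val_loss": ck.val_loss, "file": os.path.basename(blob),
                         "config": asdict(cfg)})
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(path: str) -> dict:
    """Read a saved checkpoint blob back into {modality: state dict}."""
    with np.load(path) as z:
        states: dict = {}
        for key in z.files:
            m, k = key.split("::", 1)
            states.setdefault(int(m), {})[k] = z[key]
    return states
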