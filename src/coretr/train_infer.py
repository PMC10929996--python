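"""Training loop and whole-volume sliding-window inference.

Training follows the patch-based protocol: per epoch, each training volume
contributes a few randomly cropped (foreground-biased) cubic patches, each
augmented and fed through the network one at a time (batch size 1), optimized
by SGD with Nesterov momentum from an initial learning rate of 1e-3 under
polynomial decay.  The loss is the sum of a soft-Dice term and voxel-wise
binary cross-entropy — the dominant convention for heavily class-imbalanced
3D segmentation, making the evaluation metric its own optimization surrogate.

Whole volumes are segmented by tiling with overlapping patches, averaging the
sigmoid probabilities in overlap regions, and thresholding at 0.5.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .augment import AugmentConfig, apply_augmentations
from .config import ModelConfig, TrainConfig
from .decoder import CoReTr, LogitVolume
from .metrics import dice_score
from .volume_io import CTVolume, SegMask, crop_random_patches


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    model_config: ModelConfig
    epoch: int = 0
    best_val_dice: float = float("nan")
    history: list[dict] = field(default_factory=list)
    rng_state: dict | None = None  # trainer generator state at save time

    def build_model(self) -> CoReTr:
        model = CoReTr(self.model_config, rng=0)
        model.load_state_dict(self.state)
        return model

    def save(self, path: str | os.PathLike):
        meta = {
            "model_config": self.model_config.to_dict(),
            "epoch": self.epoch,
            "best_val_dice": self.best_val_dice,
            "history": self.history,
        }
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state)
        with open(path, "wb") as f:
            f.write(buf.getvalue())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(state=state, model_config=ModelConfig.from_dict(meta["model_config"]),
                   epoch=meta["epoch"], best_val_dice=meta["best_val_dice"],
                   history=meta["history"])


def compute_loss(logits: LogitVolume | Tensor, target, kind: str = "dice_bce") -> Tensor:
    """Soft-Dice + BCE (default), or either term alone.

    BCE uses the logit-stable form softplus(z) - z*t, averaged over voxels;
    the soft-Dice term is 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s) with smoothing
    s=1, which tends to 0 for a perfect prediction.
    """
    z = logits.grid if isinstance(logits, LogitVolume) else logits
    t = target.voxels if isinstance(target, SegMask) else np.asarray(target)
    if z.data.shape != t.shape:
        raise ValueError(f"logit/target shape mismatch: {z.data.shape} vs {t.shape}")
    t = Tensor(t.astype(np.float32))
    terms = []
    if kind in ("dice_bce", "bce"):
        terms.append(ad.tmean(ad.softplus(z) - ad.mul(z, t)))
    if kind in ("dice_bce", "dice"):
        p = ad.sigmoid(z)
        smooth = 1.0
        num = 2.0 * ad.tsum(ad.mul(p, t)) + smooth
        den = ad.tsum(p) + ad.tsum(t) + smooth
        terms.append(1.0 - num / den)
    if not terms:
        raise ValueError(f"unknown loss kind {kind!r}")
    out = terms[0]
    for extra in terms[1:]:
        out = out + extra
    return out


def _check_preprocessed(vol: CTVolume):
    if not vol.normalized:
        raise ValueError("volume must be preprocessed (truncate + min-max normalize) first")


def train(dataset, cfg: TrainConfig, model_cfg: ModelConfig,
          log_fn=None) -> Checkpoint:
    """Train on a list of (CTVolume, SegMask[, ...]) pairs; returns the best
    checkpoint (by validation Dice when a validation split exists, else the
    final weights).  Deterministic for a fixed ``cfg.seed``."""
    cases = [(c[0], c[1]) for c in dataset]
    if not cases:
        raise ValueError("empty dataset")
    for vol, _ in cases:
        _check_preprocessed(vol)
    rng = np.random.default_rng(cfg.seed)
    model = CoReTr(model_cfg, rng=np.random.default_rng(rng.integers(2 ** 31 - 1)))
    from .nn import SGD  # local import to keep module load light
    opt = SGD(model.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum,
              nesterov=cfg.nesterov, weight_decay=cfg.weight_decay,
              clip_norm=cfg.clip_norm)

    order = rng.permutation(len(cases))
    n_val = int(round(cfg.val_fraction * len(cases))) if cfg.val_fraction > 0 else 0
    n_val = min(n_val, len(cases) - 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    aug_cfg = AugmentConfig() if cfg.augment else None

    total_steps = max(cfg.epochs * len(train_idx) * cfg.patches_per_volume, 1)
    step = 0
    history: list[dict] = []
    best = (float("-inf"), model.state_dict(), 0)
    for epoch in range(cfg.epochs):
        losses = []
        for vi in rng.permutation(train_idx):
            vol, mask = cases[vi]
            patches = crop_random_patches(vol, mask, size=model_cfg.patch_size,
                                          n=cfg.patches_per_volume,
                                          fg_fraction=cfg.fg_fraction, rng=rng,
                                          volume_id=str(vi))
            for patch in patches:
                if aug_cfg is not None:
                    patch = apply_augmentations(patch, aug_cfg, rng)
                if cfg.lr_schedule == "poly":
                    opt.set_poly_lr(step, total_steps, cfg.lr_power)
                logits = model(patch.image)
                loss = compute_loss(logits, patch.mask, cfg.loss)
                lval = loss.item()
                if not np.isfinite(lval):
                    raise TrainingDivergedError(
                        f"non-finite loss {lval} at epoch {epoch}, step {step}")
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(lval)
                step += 1
        entry = {"epoch": epoch, "mean_loss": float(np.mean(losses)) if losses else None,
                 "lr": opt.lr}
        stop = False
        if cfg.train_dice_stop is not None and cfg.val_interval and \
                (epoch + 1) % cfg.val_interval == 0:
            dices = [dice_score(sliding_window_predict(cases[vi][0], model,
                                                       patch_size=model_cfg.patch_size,
                                                       overlap=0.5), cases[vi][1])
                     for vi in train_idx]
            entry["train_dice"] = float(np.mean(dices))
            stop = entry["train_dice"] >= cfg.train_dice_stop
        if n_val and cfg.val_interval and (epoch + 1) % cfg.val_interval == 0:
            dices = []
            for vi in val_idx:
                vol, mask = cases[vi]
                pred = sliding_window_predict(vol, model, patch_size=model_cfg.patch_size)
                dices.append(dice_score(pred, mask))
            entry["val_dice"] = float(np.mean(dices))
            if entry["val_dice"] > best[0]:
                best = (entry["val_dice"], model.state_dict(), epoch)
        history.append(entry)
        if log_fn is not None:
            log_fn(json.dumps(entry))
        if stop:
            break

    if n_val and best[0] > float("-inf"):
        state, best_epoch, best_dice = best[1], best[2], best[0]
    else:
        state, best_epoch, best_dice = model.state_dict(), max(cfg.epochs - 1, 0), float("nan")
    return Checkpoint(state=state, model_config=model_cfg, epoch=best_epoch,
                      best_val_dice=best_dice, history=history)


def _window_starts(dim: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, max(dim - patch, 0) + 1, max(stride, 1)))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return sorted(set(starts))


def sliding_window_predict(vol: CTVolume, model: CoReTr | Checkpoint,
                           patch_size: int | None = None,
                           overlap: float = 0.5, threshold: float = 0.5) -> SegMask:
    """Tile a preprocessed volume with overlapping patches, average sigmoid
    probabilities where windows overlap, and threshold at 0.5."""
    _check_preprocessed(vol)
    if isinstance(model, Checkpoint):
        model = model.build_model()
    if patch_size is None:
        patch_size = model.cfg.patch_size
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    img = vol.voxels
    pads = [(0, max(patch_size - n, 0)) for n in img.shape]
    padded = np.pad(img, pads) if any(p[1] for p in pads) else img
    dims = padded.shape
    stride = max(int(round(patch_size * (1.0 - overlap))), 1)
    prob = np.zeros(dims, dtype=np.float64)
    count = np.zeros(dims, dtype=np.float64)
    with ad.no_grad():
        for h in _window_starts(dims[0], patch_size, stride):
            for w in _window_starts(dims[1], patch_size, stride):
                for d in _window_starts(dims[2], patch_size, stride):
                    sl = (slice(h, h + patch_size), slice(w, w + patch_size),
                          slice(d, d + patch_size))
                    logits = model(padded[sl])
                    prob[sl] += ad.sigmoid(logits.grid).data
                    count[sl] += 1.0
    prob /= count
    mask = (prob[tuple(slice(0, n) for n in img.shape)] >= threshold).astype(np.uint8)
    return SegMask(voxels=mask, spacing=vol.spacing, origin=vol.origin)
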