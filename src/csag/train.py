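"""Training and prediction orchestration (CPU, desk scale).

Optimiser recipe: momentum SGD (momentum 0.9, weight decay 5e-4), initial
learning rate 0.1 multiplied by 0.9 every 50 epochs, mini-batch 16.  The
step schedule reads "decay of 10% every 50 epochs" as multiply-by-0.9 --
decaying *to* 10% would leave no usable rate by epoch 200.

Checkpoints are single ``.npz`` archives holding the network config (JSON),
model state, optimiser velocity and the last finished epoch; training is
resumable and deterministic for a fixed seed because each epoch's shuffle
is derived from ``(seed, epoch)``.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import compute_metrics, confusion
from .network import NetworkConfig, SegModel, build_model, multi_label_loss
from .nn import SGD, Tensor

__all__ = [
    "TrainConfig",
    "lr_at_epoch",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "to_batch",
]

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    epochs: int = 30
    batch_size: int = 16
    lr: float = 0.1
    lr_decay: float = 0.9
    lr_step_epochs: int = 50
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0
    device: str = "cpu"
    checkpoint_path: str | None = None
    log_path: str | None = None
    stop_dice: float | None = None   # early stop once mean training Dice reaches this

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr_step_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("lr", "lr_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("momentum and weight_decay must be >= 0")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)


def to_batch(images, masks=None):
    """uint8 (H,W,3) images -> float32 (N,3,H,W) in [0,1]; masks -> (N,H,W) int."""
    x = np.stack([np.asarray(im, dtype=np.float32) / 255.0 for im in images])
    x = x.transpose(0, 3, 1, 2)
    if masks is None:
        return x
    t = np.stack([np.asarray(m) for m in masks]).astype(np.int64)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("masks must be binary {0,1}")
    return x, t


def _dice(pred: np.ndarray, gt: np.ndarray) -> float:
    return compute_metrics(confusion(pred, gt)).dic


def save_checkpoint(path, model: SegModel, optimizer: SGD | None, cfg: TrainConfig, epoch: int):
    payload = {
        "meta": json.dumps({
            "version": CHECKPOINT_VERSION,
            "epoch": epoch,
            "network": model.cfg.to_dict(),
            "train": {k: v for k, v in cfg.__dict__.items() if k != "network"},
        }),
    }
    for key, value in model.state_dict().items():
        payload["model/" + key] = value
    if optimizer is not None:
        for i, v in enumerate(optimizer.velocity):
            payload[f"optim/v{i}"] = v
    np.savez(path, **payload)


def load_checkpoint(path, dtype=np.float32):
    """Returns (model, meta dict, velocity list or None)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        net_cfg = NetworkConfig.from_dict(meta["network"])
        model = build_model(net_cfg, dtype=dtype)
        state = {k[len("model/"):]: data[k] for k in data.files if k.startswith("model/")}
        model.load_state_dict(state)
        vel_keys = sorted((k for k in data.files if k.startswith("optim/v")),
                          key=lambda k: int(k.split("v")[-1]))
        velocity = [data[k] for k in vel_keys] or None
    return model, meta, velocity


def train(cfg: TrainConfig, dataset, resume_from=None, model: SegModel | None = None,
          log_stream=None):
    """Mini-batch SGD on the multi-head cross-entropy loss.

    ``dataset`` is a sequence of (uint8 image (H,W,3), binary mask (H,W))
    pairs.  Returns (model, log) where log holds one record per epoch.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    log_stream = log_stream if log_stream is not None else sys.stderr

    start_epoch = 0
    velocity = None
    if resume_from is not None:
        model, meta, velocity = load_checkpoint(resume_from)
        start_epoch = meta["epoch"] + 1
    elif model is None:
        model = build_model(cfg.network, seed=cfg.seed)

    optimizer = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                    weight_decay=cfg.weight_decay)
    if velocity is not None:
        if len(velocity) != len(optimizer.velocity):
            raise ValueError("checkpoint does not match the model's parameter list")
        optimizer.velocity = [np.array(v) for v in velocity]

    n = len(dataset)
    log = []
    model.train()
    for epoch in range(start_epoch, cfg.epochs):
        optimizer.lr = lr_at_epoch(cfg, epoch)
        order = np.random.default_rng((cfg.seed, epoch)).permutation(n)
        losses = []
        dices = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            x, t = to_batch([dataset[i][0] for i in idx], [dataset[i][1] for i in idx])
            bundle = model(Tensor(x))
            loss = multi_label_loss(bundle, t)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            preds = bundle.masks()
            dices.extend(_dice(preds[j], t[j]) for j in range(len(idx)))
        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "loss": float(np.mean(losses)),
            "train_dice": float(np.mean(dices)),
        }
        log.append(record)
        print(f"epoch {epoch:3d}  lr {record['lr']:.4g}  loss {record['loss']:.4f}"
              f"  dice {record['train_dice']:.4f}", file=log_stream)
        if cfg.checkpoint_path:
            save_checkpoint(cfg.checkpoint_path, model, optimizer, cfg, epoch)
        if cfg.log_path:
            with open(cfg.log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        if cfg.stop_dice is not None and record["train_dice"] >= cfg.stop_dice:
            break
    return model, log


def predict(model_or_checkpoint, images, return_probabilities: bool = False):
    """Binary masks (uint8 {0,1}) for standardized uint8 RGB images.

    ``model_or_checkpoint`` is a built model or a checkpoint path.
    """
    if isinstance(model_or_checkpoint, (str, Path)):
        model, _, _ = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    model.eval()
    x = to_batch(images)
    bundle = model(Tensor(x))
    model.train()
    masks = bundle.masks()
    if return_probabilities:
        return masks, bundle.final.data
    return masks
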