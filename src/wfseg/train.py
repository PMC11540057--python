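"""Training loop, optimizer, checkpointing and inference.

The protocol mirrors common BraTS practice: per-modality z-score
normalization over brain voxels, random crops, mirror-flip and intensity
augmentation, Adam with polynomial learning-rate decay, batch size 1,
and a combined BCE + soft-Dice objective on the three nested region
channels.  Checkpoints store the flat parameter dict plus the full model
configuration and modality order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io_pipeline import (
    MODALITIES,
    MultimodalVolume,
    augment,
    encode_regions,
    load_case,
    random_crop,
    split_dataset,
    zscore_normalize,
)
from .losses import LossConfig, soft_dice
from .metrics import postprocess_et
from .network import ModelConfig, MultiEncoderUNet


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    learning_rate: float = 1e-5
    epochs: int = 100
    weight_decay: float = 1e-4
    batch_size: int = 1
    poly_decay_power: float = 0.9
    crop_size: tuple[int, int, int] = (128, 128, 128)
    split_ratio: tuple[int, int] = (4, 1)
    seed: int = 0
    flip_p: float = 0.5
    shift_factor: float = 0.1
    normalize: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.weight_decay < 0 or self.poly_decay_power <= 0:
            raise ValueError("weight_decay must be >= 0 and poly_decay_power > 0")
        factor = self.model.downsample_factor
        if any(c % factor for c in self.crop_size):
            raise ValueError(f"crop_size must be divisible by {factor}")


def poly_lr(lr0: float, step: int, total: int, power: float = 0.9) -> float:
    """Polynomial decay lr0 * (1 - t/T)^power, floored at 0."""
    frac = min(max(step / max(total, 1), 0.0), 1.0)
    return lr0 * (1.0 - frac) ** power


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = (p.data - lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


# ---------------------------------------------------------------------------
# differentiable loss on the graph


def loss_tensor(target: np.ndarray, prob: Tensor, config: LossConfig | None = None) -> Tensor:
    """BCE + soft-Dice on the (3, D, H, W) region stack, as a graph node."""
    config = config or LossConfig()
    u = np.asarray(target, dtype=np.float32)
    if u.shape != prob.data.shape:
        raise ValueError(f"target shape {u.shape} != prediction shape {prob.data.shape}")
    n_regions = u.shape[0]
    w = np.asarray(config.region_weights, dtype=np.float64)
    if w.size != n_regions:
        w = np.ones(n_regions)
    w = w / w.sum()

    vox = u[0].size
    v = ad.clip(prob, config.clip, 1.0 - config.clip)
    ut = Tensor(u)
    one = Tensor(np.ones_like(u))
    # per-voxel BCE, weighted per region and mean-reduced in one pass
    bce_vox = ad.mul(Tensor(-1.0), ad.add(ad.mul(ut, ad.log(v)),
                                          ad.mul(ad.sub(one, ut), ad.log(ad.sub(one, v)))))
    region_w = (w / vox).astype(np.float32).reshape(n_regions, *(1,) * (u.ndim - 1))
    bce = ad.tsum(ad.mul(bce_vox, Tensor(np.broadcast_to(region_w, u.shape).copy())))
    # soft Dice per region on flattened views
    v2 = ad.reshape(v, (n_regions, vox))
    u2 = ad.reshape(ut, (n_regions, vox))
    inter = ad.tsum(ad.mul(u2, v2), axis=1)  # (R,)
    sizes = ad.add(ad.tsum(u2, axis=1), ad.tsum(v2, axis=1))
    eps = config.epsilon
    ratio = _div(ad.add(ad.mul(Tensor(2.0), inter), Tensor(eps * np.ones(n_regions))),
                 ad.add(sizes, Tensor(eps * np.ones(n_regions))))
    dice = ad.tsum(ad.mul(ad.sub(Tensor(np.ones(n_regions)), ratio), Tensor(w.astype(np.float32))))
    return ad.add(bce, dice)


def loss_from_logits(target: np.ndarray, logits: Tensor, config: LossConfig | None = None) -> Tensor:
    """Same objective as :func:`loss_tensor` but BCE acts on raw logits.

    BCE-with-logits, softplus(x) − u·x, keeps a healthy gradient (v − u)
    even when the sigmoid saturates; the Dice term uses sigmoid(x).
    Numerically equal to the probability form wherever clipping is
    inactive.
    """
    config = config or LossConfig()
    u = np.asarray(target, dtype=np.float32)
    if u.shape != logits.data.shape:
        raise ValueError(f"target shape {u.shape} != logits shape {logits.data.shape}")
    n_regions = u.shape[0]
    w = np.asarray(config.region_weights, dtype=np.float64)
    if w.size != n_regions:
        w = np.ones(n_regions)
    w = w / w.sum()
    vox = u[0].size

    ut = Tensor(u)
    region_w = (w / vox).astype(np.float32).reshape(n_regions, *(1,) * (u.ndim - 1))
    wfull = Tensor(np.broadcast_to(region_w, u.shape).copy())
    bce_vox = ad.sub(ad.softplus(logits), ad.mul(ut, logits))
    bce = ad.tsum(ad.mul(bce_vox, wfull))

    v = ad.sigmoid(logits)
    v2 = ad.reshape(v, (n_regions, vox))
    u2 = ad.reshape(ut, (n_regions, vox))
    inter = ad.tsum(ad.mul(u2, v2), axis=1)
    sizes = ad.add(ad.tsum(u2, axis=1), ad.tsum(v2, axis=1))
    eps = config.epsilon
    ratio = _div(ad.add(ad.mul(Tensor(2.0), inter), Tensor(eps * np.ones(n_regions))),
                 ad.add(sizes, Tensor(eps * np.ones(n_regions))))
    dice = ad.tsum(ad.mul(ad.sub(Tensor(np.ones(n_regions)), ratio), Tensor(w.astype(np.float32))))
    return ad.add(bce, dice)


def _div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bwd(g):
        a._accumulate(g / b.data)
        b._accumulate(-g * a.data / (b.data**2))

    return Tensor(out_data, parents=(a, b), backward=bwd)


# ---------------------------------------------------------------------------
# fitting


def region_targets(labels: np.ndarray) -> np.ndarray:
    """(3, D, H, W) float WT/TC/ET stack from a label volume."""
    return encode_regions(labels).stacked()


def fit_steps(
    model: MultiEncoderUNet,
    volumes: Sequence[MultimodalVolume],
    steps: int,
    lr: float,
    weight_decay: float = 0.0,
    poly_power: float | None = None,
    loss_config: LossConfig | None = None,
    seed: int = 0,
) -> dict:
    """Plain step-wise optimization over pre-cropped volumes.

    Cycles through ``volumes`` deterministically (shuffled per epoch from
    ``seed``); returns per-step losses and final per-volume WT soft Dice.
    """
    loss_config = loss_config or LossConfig()
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    order: list[int] = []
    losses = []
    for step in range(steps):
        if not order:
            order = list(rng.permutation(len(volumes)))
        vol = volumes[order.pop()]
        target = region_targets(vol.labels)
        opt.zero_grad()
        out = model.forward(vol.channels, return_tensor=True)
        loss = loss_from_logits(target, out.logit_tensor, loss_config)
        loss.backward()
        step_lr = lr if poly_power is None else poly_lr(lr, step, steps, poly_power)
        opt.step(step_lr)
        losses.append(float(loss.data))
        if not np.isfinite(losses[-1]):
            raise FloatingPointError(f"non-finite loss at step {step}")
    dices = []
    for vol in volumes:
        out = model.forward(vol.channels)
        dices.append(soft_dice(region_targets(vol.labels)[0], out.probabilities[0]))
    return {"losses": losses, "wt_soft_dice": dices, "mean_wt_soft_dice": float(np.mean(dices))}


def overfit_benchmark(
    seed: int = 0,
    steps: int = 200,
    lr: float = 1e-3,
    n_phantoms: int = 4,
    shape: tuple[int, int, int] = (32, 32, 32),
    region_radii: tuple[float, float, float] = (9.0, 6.0, 3.0),
    base_channels: int = 8,
) -> dict:
    """Overfit a small model on noise-free phantoms.

    A capacity/optimization sanity check: with noise-free, high-contrast
    nested-ellipsoid phantoms the network must be able to memorize the
    training set quickly.  Returns the fit history including the final
    per-volume whole-tumor soft Dice.
    """
    from .phantom import PhantomSpec, generate_phantom

    vols = [
        zscore_normalize(
            generate_phantom(
                PhantomSpec(volume_shape=shape, region_radii=region_radii,
                            noise_sd=0.0, seed=seed + i)
            )
        )
        for i in range(n_phantoms)
    ]
    model = MultiEncoderUNet(ModelConfig(base_channels=base_channels), seed=seed)
    history = fit_steps(model, vols, steps=steps, lr=lr, seed=seed)
    history["model"] = model
    history["volumes"] = vols
    return history


def validation_dice(model: MultiEncoderUNet, volumes: Sequence[MultimodalVolume],
                    threshold: float = 0.5) -> float:
    """Mean hard Dice over regions and cases at the given threshold."""
    from .metrics import dice_score

    scores = []
    for vol in volumes:
        out = model.forward(vol.channels)
        target = encode_regions(vol.labels)
        for r, name in enumerate(("wt", "tc", "et")):
            scores.append(dice_score(out.probabilities[r] >= threshold, getattr(target, name)))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# full runs over datasets on disk


def _load_cases(manifest: dict) -> list[Path]:
    return [Path(c["dir"]) for c in manifest["cases"]]


def _prepare(vol: MultimodalVolume, cfg: TrainConfig, seed: int, training: bool) -> MultimodalVolume:
    if cfg.normalize:
        vol = zscore_normalize(vol)
    size = tuple(min(c, d) for c, d in zip(cfg.crop_size, vol.shape))
    factor = cfg.model.downsample_factor
    size = tuple((s // factor) * factor for s in size)
    vol = random_crop(vol, size, seed=seed)
    if training:
        vol = augment(vol, cfg.flip_p, cfg.shift_factor, seed=seed + 1)
    return vol


def train(manifest: dict, config: TrainConfig, out_dir: str | Path) -> dict:
    """Seeded training run with per-epoch validation and best checkpointing."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_dirs = _load_cases(manifest)
    train_dirs, val_dirs = split_dataset(case_dirs, config.split_ratio, config.seed)
    model = MultiEncoderUNet(config.model, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay)
    loss_cfg = config.loss
    total_steps = config.epochs * len(train_dirs)
    rng = np.random.default_rng(config.seed)

    log_path = out_dir / "training_log.csv"
    best = {"val_dice": -1.0, "epoch": -1}
    step = 0
    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "mean_loss", "val_dice", "lr"])
        for epoch in range(config.epochs):
            epoch_losses = []
            for idx in rng.permutation(len(train_dirs)):
                vol = load_case(train_dirs[idx])
                vol = _prepare(vol, config, seed=int(rng.integers(2**31)), training=True)
                opt.zero_grad()
                out = model.forward(vol.channels, return_tensor=True)
                loss = loss_from_logits(region_targets(vol.labels), out.logit_tensor, loss_cfg)
                loss.backward()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                lr = poly_lr(config.learning_rate, step, total_steps, config.poly_decay_power)
                opt.step(lr)
                epoch_losses.append(float(loss.data))
                step += 1
            val_vols = [
                _prepare(load_case(d), config, seed=config.seed, training=False)
                for d in val_dirs
            ]
            vd = validation_dice(model, val_vols)
            writer.writerow([epoch, float(np.mean(epoch_losses)), vd, lr])
            if vd > best["val_dice"]:
                best = {"val_dice": vd, "epoch": epoch}
                save_checkpoint(model, out_dir / "best.npz")
    save_checkpoint(model, out_dir / "last.npz")
    best["log"] = str(log_path)
    with open(out_dir / "best.json", "w") as fh:
        json.dump(best, fh, indent=2)
    return best


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: MultiEncoderUNet, path: str | Path) -> None:
    meta = {"model_config": asdict(model.config), "modalities": list(MODALITIES)}
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> MultiEncoderUNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["model_config"]
    for key in ("channel_schedule", "gcam_levels"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    model = MultiEncoderUNet(ModelConfig(**cfg_dict), seed=0)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# inference


def predict_volume(
    model: MultiEncoderUNet,
    channels: np.ndarray,
    tile: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Region probabilities for one (4, D, H, W) volume.

    Shapes divisible by the model's downsampling factor run in one pass;
    otherwise (or when ``tile`` is given) a sliding window with 50%
    overlap is used and overlapping probabilities are averaged.
    """
    channels = np.asarray(channels, dtype=np.float32)
    factor = model.config.downsample_factor
    shape = channels.shape[1:]
    if tile is None and all(d % factor == 0 for d in shape):
        return model.forward(channels).probabilities
    if tile is None:
        tile = tuple(min((d // factor) * factor or factor, 64) for d in shape)
    tile = tuple(min(t, (d // factor) * factor or factor) for t, d in zip(tile, shape))
    if any(t % factor or t > d for t, d in zip(tile, shape)):
        raise ValueError(f"tile {tile} incompatible with shape {shape}")
    acc = np.zeros((model.config.out_regions, *shape), dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    starts = [_tile_starts(d, t) for d, t in zip(shape, tile)]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + tile[0]), slice(sy, sy + tile[1]), slice(sz, sz + tile[2]))
                out = model.forward(channels[(slice(None), *sl)])
                acc[(slice(None), *sl)] += out.probabilities
                cnt[sl] += 1
    return (acc / cnt[None]).astype(np.float32)


def _tile_starts(dim: int, tile: int) -> list[int]:
    if tile >= dim:
        return [0]
    stride = max(tile // 2, 1)
    starts = list(range(0, dim - tile + 1, stride))
    if starts[-1] != dim - tile:
        starts.append(dim - tile)
    return starts


def predict_labels(
    model: MultiEncoderUNet,
    channels: np.ndarray,
    threshold: float = 0.5,
    postprocess: bool = False,
    et_threshold: int = 200,
) -> np.ndarray:
    """Threshold region probabilities and decode to BraTS labels.

    Nesting conflicts between the three sigmoid channels are resolved by
    precedence ET > TC > WT during decoding.
    """
    probs = predict_volume(model, channels)
    wt, tc, et = (probs[i] >= threshold for i in range(3))
    # enforce nesting before decoding: TC inside WT, ET inside TC
    labels = np.zeros(wt.shape, dtype=np.int16)
    labels[wt] = 2
    labels[tc] = 1
    labels[et] = 4
    if postprocess:
        labels = postprocess_et(labels, threshold=et_threshold)
    return labels
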