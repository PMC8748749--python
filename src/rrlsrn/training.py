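"""Training recipe: SGD with classical momentum and L2 weight decay, a
halving learning-rate schedule, random patch sampling, the 7:1:1:1 dataset
split, and the ablation runner.

One *epoch* draws one batch of ``batch_size`` aligned HR/LR patches
(sampled uniformly with replacement across the training images, at even
HR offsets) and takes a single optimizer step on the combined
Charbonnier + GDL loss.  The published recipe uses momentum 0.9, weight
decay 1e-4, 64 patches of 128x128, and a learning rate of 1e-5 halved
every 50 epochs — a fine-tuning rate for a warm-started network.
:func:`desk_train_config` provides the package's from-scratch desk-scale
recipe used by the smoke experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .degradation import crop_to_even, make_pair
from .losses import LossConfig, combined_loss_grad
from .metrics import psnr
from .network import NetworkConfig, RRLSRN, build_network, predict_slice

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "AblationReport",
    "lr_schedule",
    "split_dataset",
    "sgd_momentum_step",
    "adam_step",
    "clip_gradients",
    "train",
    "run_ablation",
    "desk_train_config",
]


#: Epoch counts of the desk-scale phantom experiments: the training smoke
#: run uses 30 epochs (one pass over the training images per epoch); the
#: three-arm ablation grid uses a shorter budget per run so the full
#: variant x seed grid stays affordable on one CPU.
DESK_SMOKE_EPOCHS = 30
DESK_ABLATION_EPOCHS = 12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe.

    The published defaults: momentum 0.9, weight decay 1e-4, 64 patches of
    128x128 per batch, learning rate 1e-5 halved every 50 epochs — a
    fine-tuning recipe for a warm-started network, driven by classical
    momentum gradient descent.  ``optimizer`` may be switched to ``"adam"``
    (diagonally preconditioned steps), which is what from-scratch desk-scale
    training needs to make progress in few epochs; ``grad_clip`` bounds the
    global gradient norm, 0 disables clipping.
    """

    initial_lr: float = 1e-5
    lr_halving_period: int = 50
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 64
    patch_hr: int = 128
    epochs: int = 30
    seed: int = 0
    optimizer: str = "momentum"
    adam_beta2: float = 0.99
    grad_clip: float = 0.0
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.initial_lr <= 0 or self.lr_halving_period <= 0:
            raise ValueError("learning-rate settings must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not 0 < self.adam_beta2 < 1:
            raise ValueError("adam_beta2 must be in (0, 1)")
        if self.weight_decay < 0 or self.grad_clip < 0:
            raise ValueError("weight_decay and grad_clip must be >= 0")
        if self.optimizer not in ("momentum", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patch_hr % 2 or self.patch_hr < 4:
            raise ValueError("patch_hr must be even and >= 4")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def desk_train_config(seed: int, epochs: int = 30, batch_size: int = 8,
                      patch_hr: int = 64, gdl_weight: float | None = None,
                      use_image_branch: bool = True) -> TrainConfig:
    """Desk-scale from-scratch recipe for phantom experiments.

    Keeps the published momentum/weight-decay/schedule structure but trains
    with Adam at 1e-3 under gradient clipping — from scratch, plain momentum
    descent cannot optimize the 13-layer stack in a handful of epochs.  The
    GDL weight rescales the summed GDL term against the averaged Charbonnier
    term; the default 16 over the patch pixel count was selected on held-out
    validation PSNR at desk scale, where a strong GDL term both sharpens the
    result and substantially accelerates optimization.
    """
    if gdl_weight is None:
        gdl_weight = 16.0 / (patch_hr * patch_hr)
    return TrainConfig(
        initial_lr=1e-3,
        lr_halving_period=50,
        batch_size=batch_size,
        patch_hr=patch_hr,
        epochs=epochs,
        seed=seed,
        optimizer="adam",
        grad_clip=1.0,
        loss=LossConfig(gdl_weight=gdl_weight),
        network=NetworkConfig(init_seed=seed, use_image_branch=use_image_branch),
    )


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Initial rate halved every ``lr_halving_period`` epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.initial_lr * 2.0 ** (-(epoch // cfg.lr_halving_period))


def split_dataset(items, ratios=(7, 1, 1, 1), seed: int = 0):
    """Disjoint seeded split of ``items`` into ``len(ratios)`` parts.

    The first share gets ``round(n * r0 / sum(ratios))`` items; the
    remainder is divided among the tail shares by largest remainder with
    ties resolved toward the earlier share.  For 1921 items at 7:1:1:1
    this yields (1345, 192, 192, 192).
    """
    items = list(items)
    n = len(items)
    if len(ratios) < 2 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be >= 2 positive counts")
    total = sum(ratios)
    if n < total:
        raise ValueError(f"need at least {total} items for ratios {ratios}, got {n}")
    n0 = int(np.floor(n * ratios[0] / total + 0.5))
    rem = n - n0
    tail = ratios[1:]
    quotas = [rem * r / sum(tail) for r in tail]
    sizes = [int(np.floor(q)) for q in quotas]
    left = rem - sum(sizes)
    order = sorted(range(len(tail)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:left]:
        sizes[i] += 1
    sizes = [n0] + sizes

    perm = np.random.default_rng(int(seed) % (2**63)).permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append([items[int(i)] for i in perm[start : start + s]])
        start += s
    return out


@dataclass
class TrainingHistory:
    """Per-epoch training record."""

    epoch: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    loss: list = field(default_factory=list)
    val_psnr: list = field(default_factory=list)

    def __len__(self):
        return len(self.epoch)


def sgd_momentum_step(params, grads, velocities, lr, momentum, weight_decay):
    """In-place classical-momentum update with L2 weight decay.

    ``v <- momentum * v + (g + weight_decay * w); w <- w - lr * v``.
    """
    for w, g, v in zip(params, grads, velocities):
        v *= momentum
        v += g + weight_decay * w
        w -= lr * v


def adam_step(params, grads, moments, variances, t, lr, beta1, beta2,
              weight_decay, eps=1e-8):
    """In-place bias-corrected Adam update with L2 weight decay; ``t`` is
    the 1-based step counter."""
    for w, g, m, v in zip(params, grads, moments, variances):
        g = g + weight_decay * w
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        w -= w.dtype.type(lr) * mhat / (np.sqrt(vhat) + eps)


def clip_gradients(grads, max_norm):
    """Scale the gradient list so its global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        grads = [g * scale for g in grads]
    return grads


def _sample_batch(pairs, patch_hr, batch_size, rng, dtype):
    p = patch_hr
    hr_batch = np.empty((batch_size, 1, p, p), dtype=dtype)
    lr_batch = np.empty((batch_size, 1, p // 2, p // 2), dtype=dtype)
    idx = rng.integers(0, len(pairs), size=batch_size)
    for b, k in enumerate(idx):
        pair = pairs[k]
        h, w = pair.hr.shape
        i = 2 * rng.integers(0, (h - p) // 2 + 1)
        j = 2 * rng.integers(0, (w - p) // 2 + 1)
        hr_batch[b, 0] = pair.hr[i : i + p, j : j + p]
        lr_batch[b, 0] = pair.lr[i // 2 : (i + p) // 2, j // 2 : (j + p) // 2]
    return hr_batch, lr_batch


def train(dataset, cfg: TrainConfig, val_images=None, callback=None):
    """Train an RRLSRN on HR slices; LR observations are derived internally.

    One epoch is a pass over the training set: each training image
    contributes one batch of ``batch_size`` uniformly sampled patch pairs
    and one optimizer step.  Returns ``(model, history)`` with per-epoch
    mean loss and validation PSNR.  Fully deterministic for a given
    ``(dataset, cfg)``: the seed drives initialization and patch sampling.
    """
    images = [crop_to_even(im, cfg.network.scale) for im in dataset]
    if not images:
        raise ValueError("dataset is empty")
    for im in images:
        if min(im.shape) < cfg.patch_hr:
            raise ValueError(
                f"image {im.shape} smaller than the {cfg.patch_hr} training patch"
            )
    scale = cfg.network.scale
    pairs = [make_pair(im, scale) for im in images]
    val_pairs = (
        [make_pair(crop_to_even(im, scale), scale) for im in val_images]
        if val_images
        else None
    )

    net_cfg = replace(cfg.network, init_seed=cfg.seed)
    model = build_network(net_cfg)
    rng = np.random.default_rng((int(cfg.seed) + 0x5EED) % (2**63))
    params = [layer[key] for layer in model.layers for key in ("W", "b")]
    velocities = [np.zeros_like(p) for p in params]
    variances = [np.zeros_like(p) for p in params]

    history = TrainingHistory()
    step = 0
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        epoch_losses = []
        for _ in range(len(pairs)):
            hr_b, lr_b = _sample_batch(
                pairs, cfg.patch_hr, cfg.batch_size, rng, model.dtype
            )
            out, cache, _, _ = model.forward(lr_b, want_cache=True)
            loss, dout = combined_loss_grad(out, hr_b, cfg.loss)
            grad_layers = model.backward(cache, dout)
            grads = [g[key] for g in grad_layers for key in ("W", "b")]
            if cfg.grad_clip:
                grads = clip_gradients(grads, cfg.grad_clip)
            step += 1
            if cfg.optimizer == "adam":
                adam_step(params, grads, velocities, variances, step, lr,
                          cfg.momentum, cfg.adam_beta2, cfg.weight_decay)
            else:
                sgd_momentum_step(params, grads, velocities, lr,
                                  cfg.momentum, cfg.weight_decay)
            epoch_losses.append(loss)

        val = np.nan
        if val_pairs is not None:
            val = float(
                np.mean([psnr(predict_slice(model, vp.lr), vp.hr) for vp in val_pairs])
            )
        history.epoch.append(epoch)
        history.lr.append(lr)
        history.loss.append(float(np.mean(epoch_losses)))
        history.val_psnr.append(val)
        if callback is not None:
            callback(epoch, lr, history.loss[-1], val)
    return model, history


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------


def _apply_overrides(cfg: TrainConfig, overrides: dict) -> TrainConfig:
    """Apply dotted-path overrides, e.g. {"loss.gdl_weight": 0.0}."""
    loss_kw, net_kw, top_kw = {}, {}, {}
    for key, value in overrides.items():
        if key.startswith("loss."):
            loss_kw[key[5:]] = value
        elif key.startswith("network."):
            net_kw[key[8:]] = value
        else:
            top_kw[key] = value
    if loss_kw:
        top_kw["loss"] = replace(cfg.loss, **loss_kw)
    if net_kw:
        top_kw["network"] = replace(cfg.network, **net_kw)
    return replace(cfg, **top_kw)


@dataclass
class AblationReport:
    """Variant x subject PSNR table, optionally over several seeds."""

    variants: list
    seeds: list
    n_subjects: int
    psnr: dict  # (variant, seed) -> list of per-subject PSNRs

    def row(self, variant, seed):
        return self.psnr[(variant, seed)]

    def mean_psnr(self, variant, seed=None):
        if seed is not None:
            return float(np.mean(self.psnr[(variant, seed)]))
        return float(np.mean([np.mean(self.psnr[(variant, s)]) for s in self.seeds]))


def run_ablation(dataset, variants, cfg: TrainConfig, n_test: int = 5, seeds=None):
    """Train each named variant on a shared split and score per-subject PSNR.

    ``variants`` is a list of ``(name, overrides)`` pairs; every variant is
    trained with the same seed set so rows are directly comparable.  The
    last ``n_test`` images of a seeded shuffle are the test subjects.
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    images = list(dataset)
    if n_test < 1 or n_test >= len(images):
        raise ValueError("n_test must leave at least one training image")
    if seeds is None:
        seeds = [cfg.seed]

    perm = np.random.default_rng(int(cfg.seed) % (2**63)).permutation(len(images))
    test_imgs = [crop_to_even(images[i], cfg.network.scale) for i in perm[-n_test:]]
    train_imgs = [images[i] for i in perm[:-n_test]]
    test_pairs = [make_pair(im, cfg.network.scale) for im in test_imgs]

    table = {}
    for name, overrides in variants:
        vcfg = _apply_overrides(cfg, dict(overrides))
        for seed in seeds:
            model, _ = train(train_imgs, replace(vcfg, seed=int(seed)))
            table[(name, int(seed))] = [
                psnr(predict_slice(model, tp.lr), tp.hr) for tp in test_pairs
            ]
    return AblationReport(
        variants=[name for name, _ in variants],
        seeds=[int(s) for s in seeds],
        n_subjects=n_test,
        psnr=table,
    )
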