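"""Paired adversarial training of the contrast-synthesis GAN.

The objective is the pix2pix one: the generator minimizes a weighted sum of
the conditional GAN loss and the voxelwise L1 loss against the registered
post-contrast target, at a fixed 1:100 weighting.  The discriminator sees the
6-channel concatenation of condition (pre-contrast channels) and candidate
(real or synthesized post-contrast channels) and is trained with one-sided
label smoothing: the "real" target is 0.9, the "fake" target stays at 0.
Each epoch covers all 16-slice windows of all training volumes; one
discriminator step alternates with one generator step per window, optimized
with Adam (lr 2e-4, beta1 0.5) and a single x0.1 learning-rate step after the
first 10 epochs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import (
    Adam,
    Discriminator,
    Generator,
    ModelConfig,
    build_discriminator,
    build_generator,
)
from .windowing import DEFAULT_WINDOWS, MultiChannelVolume, make_three_channel

WINDOW_LENGTH = 16  # axial slices per training sample


@dataclass
class TrainingConfig:
    lambda_l1: float = 100.0
    adv_weight: float = 1.0
    lr: float = 2e-4
    beta1: float = 0.5
    decay_rate: float = 0.1
    decay_start_epoch: int = 10
    batch_size: int = 1
    epochs: int = 20
    label_smooth_real: float = 0.9
    max_shift_px: int = 50
    gan_mode: str = "bce"  # 'bce' (default) or 'lsgan'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if not (0 < self.label_smooth_real <= 1):
            raise ValueError("label_smooth_real must be in (0, 1]")
        if self.max_shift_px < 0:
            raise ValueError("max_shift_px must be >= 0")
        if self.gan_mode not in ("bce", "lsgan"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")


@dataclass
class TrainState:
    epoch: int = 0
    iteration: int = 0
    lr: float = 0.0
    checkpoint_paths: list[str] = field(default_factory=list)


def make_training_windows(volume: MultiChannelVolume | np.ndarray) -> list[np.ndarray]:
    """All N-15 contiguous 16-slice sub-volumes, cranial to caudal.

    Views into the parent array (no copies); input and target volumes must be
    windowed with the same starts so pairs stay registered.
    """
    data = volume.data if isinstance(volume, MultiChannelVolume) else volume
    n = data.shape[3]
    if n < WINDOW_LENGTH:
        raise ValueError(
            f"training requires at least {WINDOW_LENGTH} axial slices, got {n}")
    return [data[:, :, :, s: s + WINDOW_LENGTH] for s in range(n - WINDOW_LENGTH + 1)]


def random_shift_augment(
    input_window: np.ndarray,
    target_window: np.ndarray,
    max_shift_px: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One integer in-plane shift applied identically to input and target.

    (dx, dy) is drawn uniformly from [-max, max]^2; vacated pixels are filled
    with -1, the normalized window floor (air); the slice axis never shifts.
    Shifting the pair jointly preserves the voxelwise correspondence the L1
    loss relies on.
    """
    if input_window.shape != target_window.shape:
        raise ValueError("input/target window shapes differ")
    if max_shift_px == 0:
        return input_window, target_window
    dx = int(rng.integers(-max_shift_px, max_shift_px + 1))
    dy = int(rng.integers(-max_shift_px, max_shift_px + 1))

    def shift(a: np.ndarray) -> np.ndarray:
        out = np.full_like(a, -1.0)
        xs_src = slice(max(0, -dx), a.shape[1] - max(0, dx))
        xs_dst = slice(max(0, dx), a.shape[1] - max(0, -dx))
        ys_src = slice(max(0, -dy), a.shape[2] - max(0, dy))
        ys_dst = slice(max(0, dy), a.shape[2] - max(0, -dy))
        out[:, xs_dst, ys_dst, :] = a[:, xs_src, ys_src, :]
        return out

    return shift(input_window), shift(target_window)


def bce_with_logits(logits: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy of logits against a constant label."""
    x = np.asarray(logits, dtype=np.float64)
    return float(np.mean(np.maximum(x, 0) - x * target + np.log1p(np.exp(-np.abs(x)))))


def _bce_grad(logits: np.ndarray, target: float) -> np.ndarray:
    x = np.asarray(logits, dtype=np.float64)
    return ((1.0 / (1.0 + np.exp(-x)) - target) / x.size).astype(np.float32)


def _adv_loss_and_grad(logits: np.ndarray, target: float, mode: str):
    if mode == "bce":
        return bce_with_logits(logits, target), _bce_grad(logits, target)
    loss = float(np.mean((logits - target) ** 2))
    return loss, (2.0 * (logits - target) / logits.size).astype(np.float32)


def generator_loss(
    disc_logits_on_fake: np.ndarray,
    fake: np.ndarray,
    real: np.ndarray,
    lambda_l1: float = 100.0,
    adv_weight: float = 1.0,
    gan_mode: str = "bce",
) -> tuple[float, dict[str, float]]:
    """Total generator loss and its components.

    The adversarial term scores the discriminator's patch logits on the fake
    against the "real" label (non-smoothed); the L1 term is the mean absolute
    difference over all voxels and channels; total = adv_weight * adv +
    lambda_l1 * l1.
    """
    if fake.shape != real.shape:
        raise ValueError(f"fake/real shape mismatch: {fake.shape} vs {real.shape}")
    adv, _ = _adv_loss_and_grad(disc_logits_on_fake, 1.0, gan_mode)
    l1 = float(np.mean(np.abs(np.asarray(fake, np.float64) - np.asarray(real, np.float64))))
    total = adv_weight * adv + lambda_l1 * l1
    return total, {"adv": adv, "l1": l1, "weighted_l1": lambda_l1 * l1}


def discriminator_loss(
    logits_on_real: np.ndarray,
    logits_on_fake: np.ndarray,
    label_smooth_real: float = 0.9,
    gan_mode: str = "bce",
) -> float:
    """BCE of real logits against the smoothed label plus fake logits against 0.

    Smoothing is one-sided: only the real label moves below 1.
    """
    real, _ = _adv_loss_and_grad(logits_on_real, label_smooth_real, gan_mode)
    fake, _ = _adv_loss_and_grad(logits_on_fake, 0.0, gan_mode)
    return real + fake


def lr_schedule(epoch: int, config: TrainingConfig) -> float:
    """Piecewise-constant schedule: one multiplicative decay step.

    lr for epochs 1..decay_start_epoch, then lr * decay_rate for the rest.
    """
    if not (1 <= epoch <= config.epochs):
        raise ValueError(f"epoch {epoch} outside 1..{config.epochs}")
    if epoch <= config.decay_start_epoch:
        return config.lr
    return config.lr * config.decay_rate


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    history: pd.DataFrame
    state: TrainState


def _prepare_channels(pairs, windows):
    prepared = []
    for pair in pairs:
        if hasattr(pair, "ncct"):
            src, tgt = pair.ncct, pair.cect
        else:
            src, tgt = pair
        prepared.append(
            (make_three_channel(src, windows).data, make_three_channel(tgt, windows).data)
        )
    return prepared


def train(
    pairs,
    model_config: ModelConfig,
    training_config: TrainingConfig,
    windows=DEFAULT_WINDOWS,
    out_dir: str | None = None,
    progress: bool = False,
) -> TrainResult:
    """Alternating adversarial training over all 16-slice windows per epoch.

    ``pairs`` is a sequence of PhantomPair-like objects (``.ncct``/``.cect``)
    or (input, target) CTVolume tuples.  Fully reproducible for a fixed seed.
    """
    if len(pairs) == 0:
        raise ValueError("no training pairs provided")
    data = _prepare_channels(pairs, windows)
    for _, tgt in data:
        if tgt.shape[3] < WINDOW_LENGTH:
            raise ValueError("every training volume needs >= 16 slices")

    cfg = training_config
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(model_config, seed=int(rng.integers(2**31)))
    disc = build_discriminator(model_config, seed=int(rng.integers(2**31)))
    opt_g = Adam(gen.params(), lr=cfg.lr, beta1=cfg.beta1)
    opt_d = Adam(disc.params(), lr=cfg.lr, beta1=cfg.beta1)

    samples = [
        (vol_idx, start)
        for vol_idx, (src, _) in enumerate(data)
        for start in range(src.shape[3] - WINDOW_LENGTH + 1)
    ]
    state = TrainState()
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_schedule(epoch, cfg)
        opt_g.lr = lr
        opt_d.lr = lr
        state.epoch, state.lr = epoch, lr
        order = rng.permutation(len(samples))
        for si in order:
            vol_idx, start = samples[si]
            src, tgt = data[vol_idx]
            x = src[:, :, :, start: start + WINDOW_LENGTH]
            y = tgt[:, :, :, start: start + WINDOW_LENGTH]
            x, y = random_shift_augment(x, y, cfg.max_shift_px, rng)

            # --- discriminator step (fake is detached: no generator backward) ---
            fake = gen.forward(x, train=True)
            logits_real = disc.forward(np.concatenate([x, y], axis=0))
            loss_real, g_real = _adv_loss_and_grad(
                logits_real, cfg.label_smooth_real, cfg.gan_mode)
            disc.backward(g_real)
            logits_fake = disc.forward(np.concatenate([x, fake], axis=0))
            loss_fake, g_fake = _adv_loss_and_grad(logits_fake, 0.0, cfg.gan_mode)
            disc.backward(g_fake)
            d_loss = loss_real + loss_fake
            opt_d.step()
            opt_d.zero_grad()

            # --- generator step (reuses the cached generator activations) ---
            logits = disc.forward(np.concatenate([x, fake], axis=0))
            adv, g_logits = _adv_loss_and_grad(logits, 1.0, cfg.gan_mode)
            g_in = disc.backward(cfg.adv_weight * g_logits)
            opt_d.zero_grad()  # discriminator is frozen during this step
            diff = fake - y
            l1 = float(np.mean(np.abs(diff)))
            g_fake_total = (
                g_in[model_config.in_channels:]
                + cfg.lambda_l1 * np.sign(diff, dtype=np.float32) / diff.size
            )
            gen.backward(g_fake_total)
            opt_g.step()
            opt_g.zero_grad()

            state.iteration += 1
            g_total = cfg.adv_weight * adv + cfg.lambda_l1 * l1
            if not np.isfinite(g_total) or not np.isfinite(d_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} iteration {state.iteration}: "
                    f"G={g_total}, D={d_loss}")
            rows.append({
                "epoch": epoch, "iteration": state.iteration, "lr": lr,
                "d_loss": d_loss, "g_adv": adv, "g_l1": l1, "g_total": g_total,
            })
        if progress:
            recent = [r for r in rows if r["epoch"] == epoch]
            print(f"epoch {epoch}/{cfg.epochs}  lr {lr:.2e}  "
                  f"G {np.mean([r['g_total'] for r in recent]):.4f}  "
                  f"D {np.mean([r['d_loss'] for r in recent]):.4f}")
        if out_dir is not None:
            from .networks import save_weights

            os.makedirs(out_dir, exist_ok=True)
            ckpt = os.path.join(out_dir, f"generator_epoch{epoch:03d}.npz")
            save_weights(gen, ckpt)
            state.checkpoint_paths.append(ckpt)
            pd.DataFrame(rows).to_csv(os.path.join(out_dir, "losses.csv"), index=False)

    return TrainResult(generator=gen, discriminator=disc,
                       history=pd.DataFrame(rows), state=state)
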