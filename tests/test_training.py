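"""Training procedure: windows, augmentation, losses, schedule, reproducibility."""

import dataclasses

import numpy as np
import pytest

from scectgen.networks import ModelConfig, reduced_disc_layers
from scectgen.phantom import PhantomSpec, generate_phantom_pair
from scectgen.training import (
    TrainingConfig,
    bce_with_logits,
    discriminator_loss,
    generator_loss,
    lr_schedule,
    make_training_windows,
    random_shift_augment,
    train,
)


def tiny_model_config(shape=(32, 32, 16)):
    return ModelConfig(input_shape=shape, n_encoder_blocks=2, base_filters=4,
                       max_filters=8, disc_layers=reduced_disc_layers())


@pytest.mark.parametrize("n,expected", [(16, 1), (20, 5), (100, 85)])
def test_window_count_is_n_minus_15(n, expected):
    data = np.zeros((3, 4, 4, n), dtype=np.float32)
    windows = make_training_windows(data)
    assert len(windows) == expected
    for k, w in enumerate(windows):
        assert w.shape[3] == 16
        np.testing.assert_array_equal(w, data[:, :, :, k: k + 16])


def test_window_requires_16_slices():
    with pytest.raises(ValueError, match="16"):
        make_training_windows(np.zeros((3, 4, 4, 15), dtype=np.float32))


def test_shift_augment_zero_is_identity(rng):
    x = rng.normal(size=(3, 20, 20, 16)).astype(np.float32)
    y = rng.normal(size=(3, 20, 20, 16)).astype(np.float32)
    xs, ys = random_shift_augment(x, y, 0, rng)
    assert xs is x and ys is y


def test_shift_augment_bounds_and_extremes(rng):
    seen = set()
    x = np.zeros((1, 3, 3, 1), dtype=np.float32)
    for _ in range(1000):
        rng_draws = rng.integers(-50, 51, size=2)  # mirror of internal draw
        seen.update(abs(int(v)) for v in rng_draws)
        assert all(abs(int(v)) <= 50 for v in rng_draws)
    assert 50 in seen and 0 in seen


def test_shift_augment_keeps_pair_aligned(rng):
    x = rng.uniform(0.1, 0.9, size=(1, 30, 30, 16)).astype(np.float32)
    y = (x - 0.05).astype(np.float32)
    xs, ys = random_shift_augment(x, y, 8, rng)
    moved = xs > -0.5  # carried-over pixels (fill value is -1)
    assert moved.any() and (~moved).any()
    # wherever the input was carried over, the target difference is preserved
    np.testing.assert_allclose((xs - ys)[moved], 0.05, atol=1e-5)
    # vacated pixels filled with the window floor in both volumes
    assert np.all(xs[~moved] == -1.0) and np.all(ys[~moved] == -1.0)


def test_generator_loss_components(rng):
    real = rng.normal(size=(3, 8, 8, 4)).astype(np.float32)
    logits = np.zeros((1, 2, 2, 2), dtype=np.float32)
    total, parts = generator_loss(logits, real, real, lambda_l1=100.0)
    assert parts["l1"] == 0.0
    fake = real + 0.1
    total, parts = generator_loss(logits, fake, real, lambda_l1=100.0)
    assert parts["l1"] == pytest.approx(0.1, rel=1e-5)
    assert parts["weighted_l1"] == pytest.approx(10.0, rel=1e-5)
    # decomposition: total - lambda * l1 == adversarial term exactly
    assert total - 100.0 * parts["l1"] == pytest.approx(parts["adv"], abs=1e-12)
    total0, parts0 = generator_loss(logits, fake, real, lambda_l1=0.0)
    assert total0 == pytest.approx(parts0["adv"])


def test_discriminator_loss_closed_form_at_zero_logits():
    zeros = np.zeros((1, 3, 3, 1))
    # BCE at p = 0.5 is ln 2 regardless of the target label
    assert discriminator_loss(zeros, zeros, 0.9) == pytest.approx(2 * np.log(2))


def test_label_smoothing_is_one_sided(rng):
    logits_real = rng.normal(size=(1, 4, 4, 2))
    logits_fake = rng.normal(size=(1, 4, 4, 2))
    a = discriminator_loss(logits_real, logits_fake, 0.9)
    b = discriminator_loss(logits_real, logits_fake, 1.0)
    # the fake term never changes: difference comes only from the real term
    fake_term = bce_with_logits(logits_fake, 0.0)
    assert a - bce_with_logits(logits_real, 0.9) == pytest.approx(fake_term)
    assert b - bce_with_logits(logits_real, 1.0) == pytest.approx(fake_term)


def test_perfect_discriminator_loss_tends_to_zero():
    big = np.full((1, 2, 2, 1), 50.0)
    assert discriminator_loss(big, -big, 1.0) == pytest.approx(0.0, abs=1e-12)


def test_lr_schedule_single_decay_step():
    cfg = TrainingConfig()
    assert lr_schedule(1, cfg) == pytest.approx(2e-4)
    assert lr_schedule(10, cfg) == pytest.approx(2e-4)
    assert lr_schedule(11, cfg) == pytest.approx(2e-5)
    assert lr_schedule(20, cfg) == pytest.approx(2e-5)
    flat = TrainingConfig(decay_rate=1.0)
    assert all(lr_schedule(e, flat) == pytest.approx(2e-4) for e in range(1, 21))
    with pytest.raises(ValueError):
        lr_schedule(0, cfg)
    with pytest.raises(ValueError):
        lr_schedule(21, cfg)


def _tiny_pairs(n=2, n_slices=16, seed=0):
    pairs = []
    for i in range(n):
        spec = PhantomSpec(shape=(32, 32, n_slices), spacing=(8.0, 8.0, 8.0),
                           n_nodes=1, n_vessels=2, seed=seed + i)
        pairs.append(generate_phantom_pair(spec))
    return pairs


def test_iterations_per_epoch_counts_all_windows():
    pairs = _tiny_pairs(2, n_slices=18)  # 3 windows each
    cfg = TrainingConfig(epochs=1, max_shift_px=2, seed=1)
    result = train(pairs, tiny_model_config((32, 32, 16)), cfg)
    assert result.state.iteration == sum(p.ncct.n_slices - 15 for p in pairs)


def test_training_is_reproducible_and_loss_finite():
    pairs = _tiny_pairs(2)
    cfg = TrainingConfig(epochs=2, max_shift_px=2, seed=42)
    a = train(pairs, tiny_model_config(), cfg)
    b = train(pairs, tiny_model_config(), cfg)
    assert np.isfinite(a.history["g_total"]).all()
    assert a.history["g_total"].tolist() == b.history["g_total"].tolist()
    assert a.history["d_loss"].tolist() == b.history["d_loss"].tolist()


def test_training_reduces_l1_from_initial_baseline():
    pairs = _tiny_pairs(3)
    cfg = TrainingConfig(epochs=3, lr=2e-3, max_shift_px=0, seed=7)
    result = train(pairs, tiny_model_config(), cfg)
    first = result.history.query("epoch == 1")["g_l1"].iloc[:2].mean()
    last = result.history.query("epoch == epoch.max()")["g_l1"].mean()
    assert last < first


def test_pure_l1_regression_mode_learns_on_noiseless_phantoms():
    """adversarial weight 0 turns training into supervised L1 regression."""
    pairs = []
    for i in range(3):
        spec = PhantomSpec(shape=(32, 32, 16), spacing=(8.0, 8.0, 8.0),
                           n_nodes=1, n_vessels=2, noise_sd=0.0, seed=20 + i)
        pairs.append(generate_phantom_pair(spec))
    cfg = TrainingConfig(epochs=4, lr=5e-3, adv_weight=0.0, max_shift_px=0, seed=3)
    result = train(pairs, tiny_model_config(), cfg)
    l1 = result.history.groupby("epoch")["g_l1"].mean()
    assert l1.iloc[-1] < 0.6 * l1.iloc[0]
    # generator loss reduces to the weighted L1 alone
    np.testing.assert_allclose(result.history["g_total"],
                               100.0 * result.history["g_l1"], rtol=1e-6)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train([], tiny_model_config(), TrainingConfig(epochs=1))


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(lambda_l1=-1)
    with pytest.raises(ValueError):
        TrainingConfig(label_smooth_real=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(gan_mode="wgan")
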