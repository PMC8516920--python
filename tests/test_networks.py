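"""Generator/discriminator architecture contracts and receptive fields."""

import numpy as np
import pytest

from scectgen.networks import (
    ModelConfig,
    build_discriminator,
    build_generator,
    default_disc_layers,
    gradient_receptive_field,
    load_weights,
    receptive_field,
    reduced_model_config,
    save_weights,
)


@pytest.fixture(scope="module")
def reduced_gen():
    return build_generator(reduced_model_config(), seed=3)


def test_receptive_field_single_layer():
    assert receptive_field([((3, 3, 3), (1, 1, 1))]) == (3, 3, 3)
    assert receptive_field([]) == (1, 1, 1)


def test_receptive_field_2d_patchgan_recipe():
    # canonical 70-pixel stack: k=4 with strides 2,2,2,1,1
    layers = [((4, 4), (2, 2)), ((4, 4), (2, 2)), ((4, 4), (2, 2)),
              ((4, 4), (1, 1)), ((4, 4), (1, 1))]
    assert receptive_field(layers) == (70, 70)


def test_receptive_field_matches_brute_force_footprint_2d():
    # brute force: propagate an interval of influenced input positions
    def footprint(layers):
        lo, hi = 0, 0  # influenced input index range for output unit 0
        pos = 1
        for k, s in reversed(layers):
            hi = hi * s + (k - 1)
            lo = lo * s
            pos *= s
        return hi - lo + 1

    stacks = [
        [(4, 2), (4, 2), (4, 2), (4, 1), (4, 1)],
        [(3, 1), (3, 1)],
        [(4, 2), (3, 1)],
        [(2, 1), (2, 1), (2, 1)],
    ]
    for stack in stacks:
        analytic = receptive_field([((k, k, k), (s, s, s)) for k, s in stack])[0]
        assert analytic == footprint(stack)


def test_default_discriminator_receptive_field_70_70_4():
    disc = build_discriminator(ModelConfig(), seed=0)
    assert disc.receptive_field() == (70, 70, 4)


def test_default_discriminator_gradient_footprint():
    disc = build_discriminator(ModelConfig(), seed=0)
    assert gradient_receptive_field(disc, (80, 80, 6)) == (70, 70, 4)


def test_reduced_discriminator_footprint_matches_analytic():
    disc = build_discriminator(reduced_model_config(), seed=0)
    assert gradient_receptive_field(disc, (48, 48, 8)) == disc.receptive_field()


def test_discriminator_output_is_a_patch_grid(reduced_gen):
    disc = build_discriminator(reduced_model_config(), seed=2)
    x = np.random.default_rng(0).normal(size=(6, 64, 64, 16)).astype(np.float32)
    out = disc.forward(x, train=False)
    assert out.shape[0] == 1
    assert np.prod(out.shape[1:]) > 1  # many patch decisions, not one global


def test_discriminator_sensitive_to_candidate_swap():
    disc = build_discriminator(reduced_model_config(), seed=2)
    rng = np.random.default_rng(1)
    cond = rng.normal(size=(3, 64, 64, 16)).astype(np.float32)
    a = rng.normal(size=(3, 64, 64, 16)).astype(np.float32)
    b = rng.normal(size=(3, 64, 64, 16)).astype(np.float32)
    la = disc.forward(np.concatenate([cond, a]), train=False)
    lb = disc.forward(np.concatenate([cond, b]), train=False)
    assert not np.allclose(la, lb)


def test_generator_preserves_shape_and_tanh_range(reduced_gen):
    x = np.random.default_rng(0).normal(size=(3, 64, 64, 16)).astype(np.float32)
    y = reduced_gen.forward(x, train=False)
    assert y.shape == x.shape
    assert y.min() >= -1.0 and y.max() <= 1.0


def test_generator_full_scale_shape_contract():
    # 512 x 512 x 16 in -> 512 x 512 x 16 out (filters reduced to keep it fast)
    cfg = ModelConfig(base_filters=2, max_filters=4)
    gen = build_generator(cfg, seed=0)
    x = np.zeros((3, 512, 512, 16), dtype=np.float32)
    assert gen.forward(x, train=False).shape == x.shape


def test_zero_weights_give_zero_output(reduced_gen):
    gen = build_generator(reduced_model_config(), seed=9)
    for p in gen.params():
        p.data[...] = 0.0
    x = np.random.default_rng(0).normal(size=(3, 64, 64, 16)).astype(np.float32)
    np.testing.assert_array_equal(gen.forward(x, train=False), 0.0)


def test_incompatible_input_shape_names_axis():
    with pytest.raises(ValueError, match="axis x"):
        build_generator(ModelConfig(input_shape=(66, 64, 16), n_encoder_blocks=3))


def test_instance_norm_shift_invariance():
    from scectgen.nn import InstanceNorm3d

    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 8, 8, 4)).astype(np.float32)
    norm = InstanceNorm3d(4)
    np.testing.assert_allclose(
        norm.forward(x, train=False), norm.forward(x + 3.7, train=False),
        atol=1e-4)


def test_weight_save_load_round_trip(tmp_path, reduced_gen):
    gen = build_generator(reduced_model_config(), seed=5)
    path = tmp_path / "w.npz"
    save_weights(gen, path)
    other = build_generator(reduced_model_config(), seed=6)
    load_weights(other, path)
    x = np.random.default_rng(2).normal(size=(3, 64, 64, 16)).astype(np.float32)
    np.testing.assert_array_equal(
        gen.forward(x, train=False), other.forward(x, train=False))


def test_default_disc_stack_is_70x70x4_by_construction():
    assert receptive_field(default_disc_layers()) == (70, 70, 4)
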