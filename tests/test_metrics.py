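"""Similarity metrics: closed forms, oracle equivalence, degradation sweeps."""

import numpy as np
import pytest

from scectgen.metrics import (
    MS_SSIM_WEIGHTS,
    RandomConvFeatureExtractor,
    evaluate_similarity,
    evaluation_window,
    lpips,
    mae,
    median_iqr,
    ms_ssim,
    psnr,
    restrict_slices,
)
from scectgen.volume import CTVolume

from _oracles import ms_ssim_reference


@pytest.mark.parametrize("hu,expected", [(50.0, 0.5), (-125.0, 0.0),
                                         (225.0, 1.0), (400.0, 1.0),
                                         (-500.0, 0.0)])
def test_evaluation_window_maps_350_50_to_unit_interval(hu, expected):
    out = evaluation_window(np.array([[[hu]]]))
    assert out[0, 0, 0] == pytest.approx(expected)


def test_evaluation_window_monotone(rng):
    hu = np.sort(rng.uniform(-400, 400, size=200)).reshape(-1, 1, 1)
    out = evaluation_window(hu).ravel()
    assert np.all(np.diff(out) >= -1e-7)


def test_restrict_slices():
    v = np.arange(4 * 4 * 10).reshape(4, 4, 10)
    np.testing.assert_array_equal(restrict_slices(v, 0, 9), v)
    assert restrict_slices(v, 3, 3).shape == (4, 4, 1)
    assert restrict_slices(v, 2, 5).shape == (4, 4, 4)
    with pytest.raises(ValueError):
        restrict_slices(v, 5, 2)
    with pytest.raises(ValueError):
        restrict_slices(v, 0, 10)


def test_restrict_slices_from_phantom_aorta_extent(small_pair):
    from scectgen.phantom import aorta_slice_range

    lo, hi = aorta_slice_range(small_pair.masks)
    assert (lo, hi) == (2, 13)
    sub = restrict_slices(small_pair.ncct.hu, lo, hi)
    assert sub.shape[2] == hi - lo + 1


def test_mae_psnr_closed_forms(rng):
    a = rng.uniform(0, 255, size=(64, 64))
    assert mae(a, a) == 0.0
    assert psnr(a, a) == float("inf")
    d = 25.5
    b = a + d
    assert mae(a, b) == pytest.approx(d, rel=1e-9)
    assert psnr(a, b, 255.0) == pytest.approx(20 * np.log10(255.0 / d), rel=1e-9)
    assert mae(a, b) == mae(b, a)
    assert psnr(a, b) == psnr(b, a)


def test_ms_ssim_identity_is_one(rng):
    a = rng.uniform(0, 255, size=(128, 128))
    assert ms_ssim(a, a, 255.0) == pytest.approx(1.0, abs=1e-9)


def test_ms_ssim_matches_independent_reference(rng):
    for _ in range(10):
        base = rng.uniform(0, 255, size=(256, 256))
        other = np.clip(base + rng.normal(0, 20, size=base.shape), 0, 255)
        mine = ms_ssim(base, other, 255.0)
        ref = ms_ssim_reference(base, other, 255.0, MS_SSIM_WEIGHTS)
        assert mine == pytest.approx(ref, abs=1e-4)


def test_single_scale_ssim_matches_skimage(rng):
    from skimage.metrics import structural_similarity

    from scectgen.metrics import _ssim_cs_2d

    for _ in range(5):
        a = rng.uniform(0, 255, size=(96, 96))
        b = np.clip(a + rng.normal(0, 20, size=a.shape), 0, 255)
        mine, _ = _ssim_cs_2d(a, b, 255.0)
        ref = structural_similarity(a, b, data_range=255.0,
                                    gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False)
        assert mine == pytest.approx(ref, abs=1e-10)


def test_ms_ssim_decreases_with_noise(rng):
    base = rng.uniform(60, 200, size=(128, 128))
    values = []
    for sd in (5, 10, 20, 40):
        noisy = base + rng.normal(0, sd, size=base.shape)
        values.append(ms_ssim(base, noisy, 255.0))
    assert all(x > y for x, y in zip(values, values[1:]))


def test_ms_ssim_adapts_scales_for_small_images(rng):
    a = rng.uniform(0, 255, size=(64, 64))
    b = a + rng.normal(0, 10, size=a.shape)
    with pytest.warns(UserWarning, match="scales"):
        v = ms_ssim(a, b, 255.0)
    assert 0.0 <= v <= 1.0


def test_ms_ssim_symmetric(rng):
    a = rng.uniform(0, 255, size=(128, 128))
    b = a + rng.normal(0, 15, size=a.shape)
    assert ms_ssim(a, b, 255.0) == pytest.approx(ms_ssim(b, a, 255.0), abs=1e-9)


def test_lpips_identity_zero_and_symmetry(rng):
    ex = RandomConvFeatureExtractor(seed=0)
    a = rng.uniform(0, 1, size=(64, 64))
    b = rng.uniform(0, 1, size=(64, 64))
    assert lpips(a, a, ex) == 0.0
    assert lpips(a, b, ex) == pytest.approx(lpips(b, a, ex), rel=1e-5)
    assert lpips(a, b, ex) > 0.0


def test_lpips_increases_with_noise(rng):
    ex = RandomConvFeatureExtractor(seed=0)
    base = rng.uniform(0.2, 0.8, size=(64, 64))
    values = [lpips(base, base + rng.normal(0, sd, size=base.shape), ex)
              for sd in (0.02, 0.05, 0.1, 0.2)]
    assert all(x < y for x, y in zip(values, values[1:]))


def test_median_iqr_hand_case():
    med, (q1, q3) = median_iqr(list(range(1, 10)))
    assert med == 5.0 and (q1, q3) == (3.0, 7.0)


def test_evaluate_similarity_identity_and_dominance(small_pair):
    cect = small_pair.cect
    rep_perfect, rep_input = evaluate_similarity(
        cect, small_pair.ncct, cect, 2, 13)
    assert rep_perfect.medians["mae"] == 0.0
    assert rep_perfect.medians["ms_ssim"] == pytest.approx(1.0)
    assert rep_perfect.medians["lpips"] == 0.0
    # a volume strictly closer to the truth ranks better on every metric
    mid = CTVolume(hu=(small_pair.ncct.hu + cect.hu) / 2.0, spacing=cect.spacing)
    rep_mid, rep_far = evaluate_similarity(mid, small_pair.ncct, cect, 2, 13)
    assert rep_mid.medians["mae"] < rep_far.medians["mae"]
    assert rep_mid.medians["psnr"] > rep_far.medians["psnr"]
    assert rep_mid.medians["ms_ssim"] > rep_far.medians["ms_ssim"]
    assert rep_mid.medians["lpips"] < rep_far.medians["lpips"]


def test_evaluate_similarity_rejects_shape_mismatch(small_pair):
    bad = CTVolume(hu=small_pair.ncct.hu[:-2], spacing=small_pair.ncct.spacing)
    with pytest.raises(ValueError):
        evaluate_similarity(bad, small_pair.ncct, small_pair.cect)
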