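"""Technical image-similarity evaluation: MAE, PSNR, MS-SSIM, LPIPS.

All metrics are computed on mediastinal-windowed images (width 350 HU, level
50 HU) restricted to the axial slice range of interest (for phantoms, the
slices spanned by the aorta).  Windowed intensities are mapped to the 8-bit
0-255 display scale for MAE/PSNR so magnitudes are comparable to how such
values are conventionally reported; MS-SSIM and LPIPS are scale-free.
Metrics are computed per axial slice in 2D and pooled across slices; the
summary statistic is the median with interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

from .volume import CTVolume
from .windowing import WindowSpec, apply_window

EVALUATION_WINDOW = WindowSpec("evaluation_mediastinal", 350.0, 50.0)

#: Canonical 5-scale MS-SSIM weights.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def evaluation_window(volume) -> np.ndarray:
    """Apply the 350/50 evaluation window, remapped to [0, 1].

    -125 HU maps to 0 and 225 HU to 1; HU outside saturate.
    """
    normalized = apply_window(volume, EVALUATION_WINDOW)  # [-1, 1]
    return ((normalized + 1.0) / 2.0).astype(np.float32)


def restrict_slices(volume: np.ndarray, lo_index: int, hi_index: int) -> np.ndarray:
    """Keep axial slices lo..hi inclusive (the evaluation slice range)."""
    n = volume.shape[-1]
    if not (0 <= lo_index <= hi_index < n):
        raise ValueError(f"invalid slice range [{lo_index}, {hi_index}] for N={n}")
    return volume[..., lo_index: hi_index + 1]


def mae(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(np.asarray(a, np.float64) - np.asarray(b, np.float64))))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 255.0) -> float:
    """10 log10(range^2 / MSE) in dB; +inf for identical images."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((np.asarray(a, np.float64) - np.asarray(b, np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def _gaussian_kernel(win_size: int, sigma: float) -> np.ndarray:
    r = (win_size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def _ssim_cs_2d(a, b, data_range, win_size=11, sigma=1.5, k1=0.01, k2=0.03):
    """Mean SSIM and mean contrast-structure term of one 2D image pair.

    Gaussian-weighted local statistics (11 taps, sigma 1.5); the map is
    cropped by the filter radius so only fully supported pixels contribute.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if min(a.shape) < win_size:
        raise ValueError(f"image {a.shape} smaller than the {win_size}-tap window")
    kern = _gaussian_kernel(win_size, sigma)

    def filt(img):
        return correlate1d(correlate1d(img, kern, axis=0, mode="reflect"),
                           kern, axis=1, mode="reflect")

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = filt(a), filt(b)
    var_a = filt(a * a) - mu_a**2
    var_b = filt(b * b) - mu_b**2
    cov = filt(a * b) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    pad = (win_size - 1) // 2
    sl = (slice(pad, -pad), slice(pad, -pad))
    return float((lum * cs)[sl].mean()), float(cs[sl].mean())


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    return img[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def ms_ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float = 255.0,
    scale_weights=MS_SSIM_WEIGHTS,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Multiscale SSIM of a 2D pair (or a 3D pair, averaged over axial slices).

    Contrast/structure terms are combined over dyadic scales (2x average-pool
    downsampling between scales) with the luminance term at the coarsest
    scale; the scale count shrinks (with a warning, weights renormalized)
    when the image is too small for all requested scales.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 3:
        return float(np.mean([
            ms_ssim(a[:, :, k], b[:, :, k], data_range, scale_weights, win_size, sigma)
            for k in range(a.shape[2])
        ]))

    n_scales = len(scale_weights)
    max_scales = int(np.floor(np.log2(min(a.shape) / win_size))) + 1
    if max_scales < n_scales:
        warnings.warn(
            f"image {a.shape} supports only {max_scales} of {n_scales} "
            f"MS-SSIM scales; truncating and renormalizing weights")
        n_scales = max_scales
    if n_scales < 1:
        raise ValueError(f"image {a.shape} smaller than the SSIM window")
    weights = np.asarray(scale_weights[:n_scales], dtype=np.float64)
    weights = weights / weights.sum()

    result = 1.0
    ca, cb = a.astype(np.float64), b.astype(np.float64)
    for i in range(n_scales):
        ssim_mean, cs_mean = _ssim_cs_2d(ca, cb, data_range, win_size, sigma)
        if i < n_scales - 1:
            result *= max(cs_mean, 0.0) ** weights[i]
            ca, cb = _downsample2(ca), _downsample2(cb)
        else:
            result *= max(ssim_mean, 0.0) ** weights[i]
    return float(result)


class RandomConvFeatureExtractor:
    """Deterministic random-convolution feature pyramid for perceptual distance.

    A fixed-seed stack of strided 3x3 convolutions with ReLU.  It is not a
    pretrained backbone: it provides a reproducible multi-layer feature space
    for tests and offline use; a learned extractor can be plugged into
    :func:`lpips` at runtime.
    """

    def __init__(self, seed: int = 0, widths=(8, 16, 32)) -> None:
        from .nn import Conv3d, ReLU

        rng = np.random.default_rng(seed)
        self.layers = []
        in_ch = 1
        for w in widths:
            self.layers.append(
                (Conv3d(in_ch, w, (3, 3, 1), (2, 2, 1), (1, 1, 0), rng=rng,
                        init_std=0.2), ReLU())
            )
            in_ch = w

    def __call__(self, image: np.ndarray) -> list[np.ndarray]:
        h = np.asarray(image, dtype=np.float32)[None, :, :, None]
        feats = []
        for conv, relu in self.layers:
            h = relu.forward(conv.forward(h, train=False), train=False)
            feats.append(h[:, :, :, 0])
        return feats


_default_extractor: RandomConvFeatureExtractor | None = None


def default_feature_extractor() -> RandomConvFeatureExtractor:
    global _default_extractor
    if _default_extractor is None:
        _default_extractor = RandomConvFeatureExtractor(seed=0)
    return _default_extractor


def lpips(a: np.ndarray, b: np.ndarray, feature_extractor=None) -> float:
    """Perceptual distance: unit-normalized per-layer feature differences.

    For each extractor layer, feature vectors are L2-normalized along the
    channel axis, squared differences are averaged spatially, and the layer
    scores are summed.  Zero exactly for identical inputs; symmetric.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if feature_extractor is None:
        feature_extractor = default_feature_extractor()
    if a.ndim == 3:
        return float(np.mean([
            lpips(a[:, :, k], b[:, :, k], feature_extractor) for k in range(a.shape[2])
        ]))
    total = 0.0
    for fa, fb in zip(feature_extractor(a), feature_extractor(b)):
        na = fa / np.sqrt((fa**2).sum(axis=0, keepdims=True) + 1e-10)
        nb = fb / np.sqrt((fb**2).sum(axis=0, keepdims=True) + 1e-10)
        total += float(((na - nb) ** 2).sum(axis=0).mean())
    return total


def median_iqr(values) -> tuple[float, tuple[float, float]]:
    """Median and (Q1, Q3) with the linear-interpolation quartile convention."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=np.float64)
    if v.size == 0:
        return float("nan"), (float("nan"), float("nan"))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), (float(q1), float(q3))


@dataclass
class MetricReport:
    """Per-slice similarity metrics of one volume against the reference."""

    label: str
    per_slice: pd.DataFrame
    slice_range: tuple[int, int]
    window: WindowSpec = EVALUATION_WINDOW
    medians: dict = field(default_factory=dict)
    iqrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("mae", "psnr", "ms_ssim", "lpips"):
            med, iqr = median_iqr(self.per_slice[col])
            self.medians[col] = med
            self.iqrs[col] = iqr

    def summary(self) -> dict:
        return {
            "label": self.label,
            "slice_range": list(self.slice_range),
            "window": {"width": self.window.width, "level": self.window.level},
            "medians": dict(self.medians),
            "iqrs": {k: list(v) for k, v in self.iqrs.items()},
        }


def _windowed_255(volume) -> np.ndarray:
    return evaluation_window(volume) * 255.0


def evaluate_similarity(
    scect: CTVolume | np.ndarray,
    input_volume: CTVolume | np.ndarray,
    cect: CTVolume | np.ndarray,
    lo_index: int | None = None,
    hi_index: int | None = None,
    feature_extractor=None,
) -> tuple[MetricReport, MetricReport]:
    """Score synthetic and input volumes against the real contrast-enhanced one.

    Returns (sCECT report, input report): windowed to 350/50, restricted to
    the given slice range, with per-slice MAE/PSNR/MS-SSIM/LPIPS and
    median/IQR aggregation.
    """
    vols = [_windowed_255(v) for v in (scect, input_volume, cect)]
    if not (vols[0].shape == vols[1].shape == vols[2].shape):
        raise ValueError("the three volumes must be co-registered (same shape)")
    n = vols[0].shape[-1]
    lo = 0 if lo_index is None else lo_index
    hi = n - 1 if hi_index is None else hi_index
    pred, inp, truth = (restrict_slices(v, lo, hi) for v in vols)

    def per_slice(a, b, label):
        rows = []
        for k in range(a.shape[2]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append({
                    "slice": lo + k,
                    "mae": mae(a[:, :, k], b[:, :, k]),
                    "psnr": psnr(a[:, :, k], b[:, :, k], 255.0),
                    "ms_ssim": ms_ssim(a[:, :, k], b[:, :, k], 255.0),
                    "lpips": lpips(a[:, :, k] / 255.0, b[:, :, k] / 255.0,
                                   feature_extractor),
                })
        return MetricReport(label=label, per_slice=pd.DataFrame(rows),
                            slice_range=(lo, hi))

    return per_slice(pred, truth, "sCECT"), per_slice(inp, truth, "input")
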