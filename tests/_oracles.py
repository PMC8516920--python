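"""Independent brute-force reference implementations used as test oracles.

These deliberately take different computational routes from the package
(FFT-based valid convolution and explicit per-scale loops) so agreement is
evidence of correctness, not shared code.
"""

import numpy as np
from scipy.signal import fftconvolve


def gaussian_kernel_2d(win_size=11, sigma=1.5):
    r = (win_size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def ssim_cs_reference(a, b, data_range, win_size=11, sigma=1.5, k1=0.01, k2=0.03):
    """SSIM and contrast-structure means via 'valid' FFT convolution."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    w = gaussian_kernel_2d(win_size, sigma)

    def f(img):
        return fftconvolve(img, w, mode="valid")

    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a**2
    vb = f(b * b) - mu_b**2
    cov = f(a * b) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (va + vb + c2)
    return float((lum * cs).mean()), float(cs.mean())


def downsample2_reference(img):
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    out = np.zeros((h // 2, w // 2))
    for i in range(h // 2):
        for j in range(w // 2):
            out[i, j] = img[2 * i: 2 * i + 2, 2 * j: 2 * j + 2].mean()
    return out


def ms_ssim_reference(a, b, data_range, weights, win_size=11, sigma=1.5):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    weights = weights / weights.sum()
    value = 1.0
    for i, w in enumerate(weights):
        ssim_mean, cs_mean = ssim_cs_reference(a, b, data_range, win_size, sigma)
        if i == len(weights) - 1:
            value *= max(ssim_mean, 0.0) ** w
        else:
            value *= max(cs_mean, 0.0) ** w
            a, b = downsample2_reference(a), downsample2_reference(b)
    return value
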