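"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: dense 2-D
convolution with analytically sampled kernels for the separable Hessian,
an exhaustive histogram split for Otsu's threshold, and plain loops for
summary statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d


def gaussian_derivative_kernel(sigma: float, order: int, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with exact discrete moments.

    The zeroth-order kernel is a sampled Gaussian normalized to unit sum;
    derivative orders multiply it by the Hermite-polynomial factors of the
    analytic derivatives and are then corrected so the discrete operator
    annihilates constants and differentiates polynomials exactly (x -> 1
    for order 1, x**2 -> 2 for order 2).
    """
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        raw = -x / sigma**2 * g
        return raw / float(np.dot(raw, x))
    if order == 2:
        raw = (x**2 - sigma**2) / sigma**4 * g
        raw = raw - g * raw.sum()
        return raw * (2.0 / float(np.dot(raw, x**2)))
    raise ValueError(order)


def dense_hessian(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hessian entries by full 2-D convolution with outer-product kernels."""
    img = np.asarray(img, dtype=float)

    def conv(order_y: int, order_x: int) -> np.ndarray:
        ky = gaussian_derivative_kernel(sigma, order_y)
        kx = gaussian_derivative_kernel(sigma, order_x)
        kernel = np.outer(ky, kx)
        # convolution flips the kernel; odd-order kernels are antisymmetric
        return convolve2d(img, kernel[::-1, ::-1], mode="same", boundary="symm")

    ixx = conv(0, 2)
    iyy = conv(2, 0)
    ixy = conv(1, 1)
    return ixx, ixy, iyy


def brute_force_otsu(values: np.ndarray, nbins: int = 256) -> tuple[float, float, float]:
    """Exhaustive search over histogram bins for the Otsu threshold.

    Returns (threshold, its between-class variance, bin width).
    """
    values = np.asarray(values).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var = -1.0
    best_thr = centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_thr = centers[k - 1]
    return float(best_thr), float(best_var), float(edges[1] - edges[0])


def otsu_between_class_variance(values: np.ndarray, threshold: float, nbins: int = 256) -> float:
    """Between-class variance of a given split, from the same histogram."""
    values = np.asarray(values).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lower = centers <= threshold
    w0 = counts[lower].sum()
    w1 = counts[~lower].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[lower] * centers[lower]).sum() / w0
    mu1 = (counts[~lower] * centers[~lower]).sum() / w1
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def loop_mean_sd(values, ddof: int = 0) -> tuple[float, float]:
    """Mean and SD via an explicit loop (no numpy reductions)."""
    n = 0
    total = 0.0
    for v in values:
        total += v
        n += 1
    mean = total / n
    acc = 0.0
    for v in values:
        acc += (v - mean) ** 2
    sd = (acc / (n - ddof)) ** 0.5 if n > ddof else 0.0
    return mean, sd
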