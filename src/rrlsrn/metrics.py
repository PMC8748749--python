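"""Image quality metrics (PSNR, SSIM) and the mean/SD/CI summary used in
the evaluation tables.

PSNR is ``10 log10(range^2 / MSE)`` in decibels, with ``inf`` as the
sentinel for identical images.  SSIM is the Wang et al. structural
similarity index with an 11x11 Gaussian window (sigma 1.5), K1 = 0.01,
K2 = 0.03, population (weighted-mean) covariances, and edge-cropped
averaging.  The pipeline normalizes slices to [0, 1], so ``data_range``
defaults to 1.0.

Summaries report the sample mean, sample SD (n-1 denominator) and the
two-sided Student-t confidence interval ``mean +/- t * SD / sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import t as t_dist

__all__ = ["SummaryStats", "psnr", "ssim", "summarize"]


def _check_pair(a, b):
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 2:
        raise ValueError(f"expected 2D images, got shape {x.shape}")
    return x, y


def psnr(a, b, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images are identical."""
    x, y = _check_pair(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(
    a,
    b,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Mean local structural similarity in [-1, 1]."""
    x, y = _check_pair(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    if win_size % 2 == 0 or win_size < 3:
        raise ValueError("win_size must be an odd integer >= 3")
    if min(x.shape) < win_size:
        raise ValueError(
            f"image {x.shape} smaller than the {win_size}x{win_size} window"
        )
    radius = (win_size - 1) // 2
    truncate = radius / sigma

    def filt(im):
        return gaussian_filter(im, sigma, truncate=truncate)

    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
        (ux * ux + uy * uy + C1) * (vx + vy + C2)
    )
    return float(S[radius:-radius, radius:-radius].mean())


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD and two-sided confidence interval of a set of values."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int
    confidence: float = 0.95


def summarize(values, confidence: float = 0.95) -> SummaryStats:
    """Summarize per-subject metric values as mean, SD and Student-t CI."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values for a CI, got {arr.size}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    n = arr.size
    if not np.all(np.isfinite(arr)):
        # infinite-PSNR sentinel propagates: the spread is undefined
        return SummaryStats(
            mean=float(arr.mean()),
            sd=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            n=n,
            confidence=confidence,
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    tval = float(t_dist.ppf((1 + confidence) / 2, n - 1))
    half = tval * sd / np.sqrt(n)
    return SummaryStats(
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        n=n,
        confidence=confidence,
    )
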