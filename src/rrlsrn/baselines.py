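"""Classical comparison methods.

* ``cubic_spline_upsample`` fits a bicubic spline surface through the LR
  samples (pixel-center coordinates) and evaluates it on the fine grid.
* ``nmu_upsample`` is a compact non-local-means up-sampling scheme:
  starting from the bicubic interpolation it alternates non-local-means
  regularization (Gaussian-weighted patch similarity) with a subsampling
  consistency correction that adds back, on each scale x scale block, the
  difference between the LR value and the block mean of the current
  estimate.  The final correction step makes the output's block means
  match the LR input to floating-point accuracy.

``METHODS`` registers the baselines (plus plain bicubic) under the string
names the evaluation harness uses.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RectBivariateSpline
from skimage.restoration import denoise_nl_means

from .degradation import upsample_bicubic

__all__ = ["cubic_spline_upsample", "nmu_upsample", "METHODS"]


def cubic_spline_upsample(lr, scale: int = 2) -> np.ndarray:
    """Cubic-spline surface interpolation to ``scale`` times the size."""
    arr = np.asarray(lr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got {arr.shape}")
    if scale < 2:
        raise ValueError("scale must be >= 2")
    h, w = arr.shape
    ky = min(3, h - 1)
    kx = min(3, w - 1)
    spline = RectBivariateSpline(np.arange(h), np.arange(w), arr, kx=kx, ky=ky, s=0)
    fine_r = (np.arange(h * scale) + 0.5) / scale - 0.5
    fine_c = (np.arange(w * scale) + 0.5) / scale - 0.5
    return spline(fine_r, fine_c)


def _block_mean(img: np.ndarray, scale: int) -> np.ndarray:
    h, w = img.shape
    return img.reshape(h // scale, scale, w // scale, scale).mean(axis=(1, 3))


def nmu_upsample(
    lr,
    scale: int = 2,
    patch_radius: int = 1,
    search_radius: int = 5,
    h: float = 0.08,
    iterations: int = 4,
) -> np.ndarray:
    """Non-local-means up-sampling with block-mean consistency.

    ``patch_radius`` and ``search_radius`` are half-widths (default 3x3
    patches searched over an 11x11 neighborhood); ``h`` is the similarity
    bandwidth on the [0, 1] intensity scale.
    """
    arr = np.asarray(lr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got {arr.shape}")
    if patch_radius < 0 or search_radius < 1:
        raise ValueError("invalid radii")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if h <= 0:
        raise ValueError("h must be > 0")

    est = upsample_bicubic(arr, scale)
    for _ in range(iterations):
        est = denoise_nl_means(
            est,
            patch_size=2 * patch_radius + 1,
            patch_distance=search_radius,
            h=h,
            fast_mode=False,
            preserve_range=True,
        )
        # consistency: every scale x scale block must average to the LR value
        correction = arr - _block_mean(est, scale)
        est = est + np.kron(correction, np.ones((scale, scale)))
    return est


METHODS = {
    "bicubic": lambda lr, scale=2: upsample_bicubic(lr, scale),
    "cubic_spline": cubic_spline_upsample,
    "nmu": nmu_upsample,
}
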