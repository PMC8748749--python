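"""Degradation model: bicubic LR/HR pairing and patch sampling.

The pipeline treats super-resolution as recovering the residual

    r = y - u(kappa(y))

where ``y`` is the high-resolution slice, ``kappa`` the bicubic
down-sampling operator, ``u`` the bicubic up-sampling operator and
``z = u(kappa(y))`` the blurry interpolated image.  Both resamplers use
the separable Keys cubic kernel (a = -0.5, the conventional "bicubic"),
pixel-center alignment, edge replication at the borders, and per-output
weight normalization so constants are preserved exactly.  Down-sampling
widens the kernel by the scale factor (anti-aliased decimation); an
optional extra Gaussian pre-blur is exposed but off by default, since the
degradation is defined directly as bicubic decimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImagePair",
    "PatchBatch",
    "cubic_kernel",
    "downsample_bicubic",
    "upsample_bicubic",
    "make_pair",
    "crop_to_even",
    "sample_patches",
]


def cubic_kernel(x, a: float = -0.5):
    """Keys piecewise-cubic interpolation kernel.

    ``(a+2)|x|^3 - (a+3)|x|^2 + 1`` for |x| <= 1,
    ``a|x|^3 - 5a|x|^2 + 8a|x| - 4a`` for 1 < |x| < 2, else 0.
    """
    x = np.abs(np.asarray(x, dtype=np.float64))
    out = np.zeros_like(x)
    near = x <= 1.0
    far = (x > 1.0) & (x < 2.0)
    out[near] = (a + 2) * x[near] ** 3 - (a + 3) * x[near] ** 2 + 1
    out[far] = a * x[far] ** 3 - 5 * a * x[far] ** 2 + 8 * a * x[far] - 4 * a
    return out


def resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1D bicubic resampling operator mapping n_in samples to n_out.

    Output sample j is centred at input coordinate ``(j + 0.5) * ratio - 0.5``
    with ``ratio = n_in / n_out``.  When decimating (ratio > 1) the kernel is
    stretched by the ratio for anti-aliasing.  Out-of-range taps are clamped
    to the border sample (edge replication) and each row is normalized to
    sum to one.
    """
    ratio = n_in / n_out
    s = max(ratio, 1.0)
    support = 2.0 * s
    M = np.zeros((n_out, n_in), dtype=np.float64)
    for j in range(n_out):
        pos = (j + 0.5) * ratio - 0.5
        k0 = int(np.ceil(pos - support))
        k1 = int(np.floor(pos + support))
        ks = np.arange(k0, k1 + 1)
        w = cubic_kernel((ks - pos) / s)
        total = w.sum()
        if total == 0:  # pragma: no cover - cannot happen for support >= 2
            raise RuntimeError("degenerate resampling window")
        w = w / total
        np.add.at(M[j], np.clip(ks, 0, n_in - 1), w)
    return M


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def downsample_bicubic(img, scale: int = 2, pre_blur_sigma: float = 0.0) -> np.ndarray:
    """Bicubic decimation by an integer factor (the kappa*B operator).

    Dimensions must be divisible by ``scale``; callers crop first (see
    :func:`crop_to_even`).  ``pre_blur_sigma`` optionally applies an explicit
    Gaussian blur before decimation; the default models the degradation as a
    single anti-aliased bicubic decimation.
    """
    arr = _as_image(img)
    if scale < 2:
        raise ValueError(f"scale must be >= 2, got {scale}")
    h, w = arr.shape
    if h % scale or w % scale:
        raise ValueError(
            f"image dimensions {h}x{w} not divisible by scale {scale}; crop first"
        )
    if pre_blur_sigma > 0:
        arr = gaussian_filter(arr, pre_blur_sigma)
    Mr = resample_matrix(h, h // scale)
    Mc = resample_matrix(w, w // scale)
    return Mr @ arr @ Mc.T


def upsample_bicubic(img, scale: int = 2) -> np.ndarray:
    """Bicubic up-sampling by an integer factor (the ``u`` operator)."""
    arr = _as_image(img)
    if scale < 2:
        raise ValueError(f"scale must be >= 2, got {scale}")
    h, w = arr.shape
    Mr = resample_matrix(h, h * scale)
    Mc = resample_matrix(w, w * scale)
    return Mr @ arr @ Mc.T


@dataclass(frozen=True)
class ImagePair:
    """An aligned (HR, LR) pair with its interpolation and residual.

    ``residual + upsampled`` reconstructs ``hr`` exactly, pixelwise.
    """

    hr: np.ndarray
    lr: np.ndarray
    upsampled: np.ndarray
    residual: np.ndarray
    scale: int

    def __post_init__(self):
        sh, sl = self.hr.shape, self.lr.shape
        if sh != (self.scale * sl[0], self.scale * sl[1]):
            raise ValueError(f"hr {sh} is not {self.scale}x the lr shape {sl}")


def crop_to_even(img, scale: int = 2) -> np.ndarray:
    """Center-crop so both dimensions are divisible by ``scale``."""
    arr = _as_image(img)
    h, w = arr.shape
    nh, nw = h - h % scale, w - w % scale
    i0, j0 = (h - nh) // 2, (w - nw) // 2
    return arr[i0 : i0 + nh, j0 : j0 + nw]


def make_pair(hr, scale: int = 2) -> ImagePair:
    """Degrade an HR slice into its LR observation and residual decomposition."""
    arr = _as_image(hr)
    lr = downsample_bicubic(arr, scale)
    up = upsample_bicubic(lr, scale)
    residual = arr - up
    # the decomposition must be exact: store as hr the recomposition
    # upsampled + residual, which can differ from the input by at most one
    # ulp on isolated pixels where the subtraction rounded
    hr_stored = up + residual
    return ImagePair(hr=hr_stored, lr=lr, upsampled=up, residual=residual, scale=scale)


@dataclass(frozen=True)
class PatchBatch:
    """Co-located HR/LR training patches cut from one :class:`ImagePair`.

    ``offsets`` records the even (row, col) HR corner of each patch; the LR
    patch is the same window at half coordinates and half size.  Alignment is
    positional: patches are cut from the precomputed pair.
    """

    hr_patches: np.ndarray  # (count, p, p)
    lr_patches: np.ndarray  # (count, p//2, p//2)
    offsets: np.ndarray  # (count, 2), even ints
    count: int


def sample_patches(pair: ImagePair, patch_hr: int, count: int, seed: int) -> PatchBatch:
    """Uniformly sample ``count`` aligned patch pairs (with replacement).

    HR offsets are restricted to even coordinates so every LR patch is the
    co-located half-resolution window.
    """
    if patch_hr % 2:
        raise ValueError(f"patch_hr must be even, got {patch_hr}")
    h, w = pair.hr.shape
    if patch_hr > h or patch_hr > w:
        raise ValueError(f"patch {patch_hr} exceeds image {h}x{w}")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(int(seed) % (2**63))
    s = pair.scale
    max_i = (h - patch_hr) // 2
    max_j = (w - patch_hr) // 2
    rows = 2 * rng.integers(0, max_i + 1, size=count)
    cols = 2 * rng.integers(0, max_j + 1, size=count)
    p = patch_hr
    hr_p = np.stack([pair.hr[i : i + p, j : j + p] for i, j in zip(rows, cols)])
    lr_p = np.stack(
        [
            pair.lr[i // s : i // s + p // s, j // s : j // s + p // s]
            for i, j in zip(rows, cols)
        ]
    )
    return PatchBatch(
        hr_patches=hr_p,
        lr_patches=lr_p,
        offsets=np.stack([rows, cols], axis=1),
        count=count,
    )
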