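"""Synthetic 2D brain-like phantoms.

Piecewise-smooth compositions of rotated ellipses on a dark background,
optionally blurred at the boundaries and carrying band-limited texture in
the foreground.  They stand in for T1/T2 brain slices so the whole
super-resolution pipeline can be exercised without downloading MRI data:
the ellipse boundaries provide the sharp edges where interpolation loses
detail, and the texture provides recoverable high-frequency content.

Generation is a pure function of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]

#: Gaussian sigma (pixels) of the smoothing that band-limits the texture noise.
TEXTURE_SIGMA = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the ellipse-composition phantom.

    Attributes
    ----------
    height, width:
        Output grid size in pixels; at least 32 each.
    n_ellipses:
        Number of ellipses painted in order (later ones overwrite earlier
        ones, giving nested structures reminiscent of cortical ribbons).
    intensity_levels:
        Grey levels in [0, 1].  The first entry is the background; each
        ellipse draws its level uniformly from the remaining entries.
    texture_amplitude:
        Peak-to-peak amplitude of additive band-limited noise applied
        inside the painted foreground.  0 disables texture.
    edge_smoothing_sigma:
        Gaussian blur (pixels) applied to the painted label image;
        0 keeps hard edges.
    """

    height: int = 128
    width: int = 128
    n_ellipses: int = 6
    intensity_levels: tuple = (0.0, 0.25, 0.4, 0.55, 0.7, 0.85)
    texture_amplitude: float = 0.06
    edge_smoothing_sigma: float = 0.0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError(
                f"phantom dimensions must be >= 32, got {self.height}x{self.width}"
            )
        if self.n_ellipses < 1:
            raise ValueError("n_ellipses must be >= 1")
        levels = tuple(float(v) for v in self.intensity_levels)
        if len(levels) < 1:
            raise ValueError("at least one intensity level (background) is required")
        if any(v < 0.0 or v > 1.0 for v in levels):
            raise ValueError(f"intensity levels must lie in [0, 1], got {levels}")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        if self.edge_smoothing_sigma < 0:
            raise ValueError("edge_smoothing_sigma must be >= 0")
        object.__setattr__(self, "intensity_levels", levels)


def _rng(seed: int) -> np.random.Generator:
    # accept any integer seed, including negative ones
    return np.random.default_rng(int(seed) % (2**63))


def generate_phantom(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Generate one phantom slice.

    Returns a ``(height, width)`` float64 array with values in [0, 1].
    Identical ``(spec, seed)`` give bit-identical output.
    """
    if not isinstance(spec, PhantomSpec):
        spec = PhantomSpec(**spec)  # allow plain dicts from YAML configs
    rng = _rng(seed)
    h, w = spec.height, spec.width
    levels = spec.intensity_levels
    background = levels[0]
    foreground_levels = levels[1:] if len(levels) > 1 else levels

    img = np.full((h, w), background, dtype=np.float64)
    painted = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    min_dim = float(min(h, w))
    for _ in range(spec.n_ellipses):
        level = float(rng.choice(foreground_levels))
        a = rng.uniform(max(3.0, 0.08 * min_dim), 0.35 * min_dim)
        b = rng.uniform(max(3.0, 0.08 * min_dim), 0.35 * min_dim)
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        # half-extents of the rotated ellipse's bounding box, used as margins
        # so the ellipse stays fully inside the frame
        ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
        ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
        cx = rng.uniform(ex, w - 1 - ex) if w - 1 - ex > ex else (w - 1) / 2.0
        cy = rng.uniform(ey, h - 1 - ey) if h - 1 - ey > ey else (h - 1) / 2.0
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[mask] = level
        painted |= mask

    if spec.edge_smoothing_sigma > 0:
        img = gaussian_filter(img, spec.edge_smoothing_sigma)

    if spec.texture_amplitude > 0:
        noise = gaussian_filter(rng.standard_normal((h, w)), TEXTURE_SIGMA)
        span = noise.max() - noise.min()
        if span > 0:
            noise = (noise - noise.mean()) * (spec.texture_amplitude / span)
        img = img + noise * painted

    return np.clip(img, 0.0, 1.0)


def generate_dataset(n: int, spec: PhantomSpec, seed: int) -> list:
    """Generate ``n`` phantoms with per-item seeds derived from ``(seed, k)``."""
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    out = []
    for k in range(n):
        item_seed = int(
            np.random.SeedSequence((int(seed) % (2**63), k)).generate_state(1)[0]
        )
        out.append(generate_phantom(spec, item_seed))
    return out
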