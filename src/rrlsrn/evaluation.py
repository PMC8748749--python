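"""Evaluation harness: slice I/O, method comparison reports and error maps.

Volumes are read with nibabel (NIfTI) and sliced along a chosen axis;
single slices round-trip through 16-bit PNG.  Every volume is min-max
normalized to [0, 1] before degradation so PSNR/SSIM use a fixed data
range.  ``evaluate_methods`` runs the self-supervised protocol: each HR
slice is degraded to its LR observation internally, every registered
method reconstructs it, and PSNR/SSIM against the original HR slice are
aggregated per subject and then summarized as mean / SD / 95% CI.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .degradation import crop_to_even, make_pair
from .metrics import SummaryStats, psnr, ssim, summarize

__all__ = [
    "EvalReport",
    "load_volume_slices",
    "save_slice_png",
    "load_slice_png",
    "save_volume_nifti",
    "evaluate_methods",
    "error_map",
    "save_error_map",
    "report_to_csv",
    "format_report_text",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def load_volume_slices(path, axis: int = -1, normalization: str = "volume",
                       drop_blank: bool = False):
    """Load a NIfTI volume (or a directory of PNG slices) as a list of
    normalized 2D slices.

    ``normalization`` is ``"volume"`` (min-max over the whole volume, the
    default), ``"slice"`` (per slice) or ``"none"`` (keep stored values).
    ``drop_blank`` removes zero-variance slices.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise IOError(f"no PNG/TIFF slices found in directory {path}")
        slices = [np.asarray(iio.imread(p), dtype=np.float64) for p in files]
        vol = np.stack(slices, axis=-1)
    elif path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        try:
            vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
        except Exception as exc:  # pragma: no cover - corrupt input path
            raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
        if vol.ndim == 2:
            vol = vol[..., None]
        if vol.ndim != 3:
            raise IOError(f"expected a 2D/3D NIfTI volume, got shape {vol.shape}")
    else:
        raise IOError(
            f"unsupported format {path.suffix!r} (expected NIfTI .nii/.nii.gz "
            f"or a directory of PNG slices)"
        )

    if normalization == "volume":
        vol = _minmax(vol)
    axis = axis % vol.ndim
    slices = [np.take(vol, i, axis=axis) for i in range(vol.shape[axis])]
    if normalization == "slice":
        slices = [_minmax(s) for s in slices]
    elif normalization not in ("volume", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if drop_blank:
        slices = [s for s in slices if s.std() > 0]
    return slices


def save_slice_png(img, path, bits: int = 16):
    """Write a [0, 1] slice as an 8- or 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bits == 16:
        iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))
    elif bits == 8:
        iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))
    else:
        raise ValueError("bits must be 8 or 16")


def load_slice_png(path) -> np.ndarray:
    """Read a grayscale PNG back to a [0, 1] float slice."""
    arr = np.asarray(iio.imread(Path(path)), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., 0]
    peak = 65535.0 if arr.max() > 255 else 255.0
    return arr / peak


def save_volume_nifti(slices, path):
    """Stack 2D slices along the last axis and write a NIfTI volume."""
    import nibabel as nib

    vol = np.stack([np.asarray(s, dtype=np.float64) for s in slices], axis=-1)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-method PSNR/SSIM summaries plus the per-subject value table."""

    methods: list
    psnr_summary: dict  # method -> SummaryStats
    ssim_summary: dict  # method -> SummaryStats
    per_subject: dict  # (method, subject) -> {"psnr": float, "ssim": float}
    subjects: list
    errors: dict  # (method, subject) -> error message for failed cells


def evaluate_methods(hr_slices, methods, scale: int = 2, subject_ids=None,
                     data_range: float = 1.0) -> EvalReport:
    """Score reconstruction methods on HR slices via internal degradation.

    ``methods`` maps names to callables ``f(lr, scale) -> sr``.  Slices
    sharing a subject id are averaged before the across-subject summary
    (by default every slice is its own subject).
    """
    hr_slices = [crop_to_even(s, scale) for s in hr_slices]
    if not hr_slices:
        raise ValueError("need at least one HR slice")
    if not methods:
        raise ValueError("need at least one method")
    if subject_ids is None:
        subject_ids = list(range(len(hr_slices)))
    if len(subject_ids) != len(hr_slices):
        raise ValueError("subject_ids must match hr_slices in length")

    pairs = [make_pair(s, scale) for s in hr_slices]
    subjects = sorted(set(subject_ids), key=lambda s: subject_ids.index(s))

    per_subject, errors = {}, {}
    for name, fn in methods.items():
        # per-slice scores grouped by subject
        grouped = {s: {"psnr": [], "ssim": []} for s in subjects}
        for subject, pair in zip(subject_ids, pairs):
            try:
                sr = np.asarray(fn(pair.lr, scale), dtype=np.float64)
                if sr.shape != pair.hr.shape:
                    raise ValueError(
                        f"method returned shape {sr.shape}, expected {pair.hr.shape}"
                    )
                grouped[subject]["psnr"].append(psnr(sr, pair.hr, data_range))
                grouped[subject]["ssim"].append(ssim(sr, pair.hr, data_range))
            except Exception as exc:
                errors[(name, subject)] = str(exc)
        for subject in subjects:
            scores = grouped[subject]
            if scores["psnr"]:
                per_subject[(name, subject)] = {
                    "psnr": float(np.mean(scores["psnr"])),
                    "ssim": float(np.mean(scores["ssim"])),
                }

    def _summary(name, key):
        vals = [
            per_subject[(name, s)][key] for s in subjects if (name, s) in per_subject
        ]
        if len(vals) >= 2:
            return summarize(vals)
        v = vals[0] if vals else float("nan")
        return SummaryStats(mean=v, sd=0.0, ci_low=v, ci_high=v, n=len(vals))

    return EvalReport(
        methods=list(methods),
        psnr_summary={m: _summary(m, "psnr") for m in methods},
        ssim_summary={m: _summary(m, "ssim") for m in methods},
        per_subject=per_subject,
        subjects=subjects,
        errors=errors,
    )


def error_map(sr, hr) -> np.ndarray:
    """Pixelwise absolute reconstruction error |sr - hr|."""
    a = np.asarray(sr, dtype=np.float64)
    b = np.asarray(hr, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def save_error_map(err, path, cmap: str = "inferno", vmax: float = None):
    """Export an error map as a color-mapped 8-bit PNG."""
    import matplotlib

    arr = np.asarray(err, dtype=np.float64)
    top = float(arr.max()) if vmax is None else vmax
    scaled = arr / top if top > 0 else np.zeros_like(arr)
    rgba = matplotlib.colormaps[cmap](np.clip(scaled, 0.0, 1.0))
    iio.imwrite(Path(path), np.round(rgba[..., :3] * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

_FIELDS = ("metric", "method", "mean", "sd", "ci_low", "ci_high", "n")


def report_to_csv(report: EvalReport, path):
    """Write the mean/SD/CI table (one row per metric x method) as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIELDS)
        for metric, block in (("psnr", report.psnr_summary),
                              ("ssim", report.ssim_summary)):
            for method in report.methods:
                s = block[method]
                writer.writerow(
                    [metric, method, repr(float(s.mean)), repr(float(s.sd)),
                     repr(float(s.ci_low)), repr(float(s.ci_high)), s.n]
                )


def load_report_csv(path):
    """Re-parse a report CSV into {(metric, method): SummaryStats}."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[(row["metric"], row["method"])] = SummaryStats(
                mean=float(row["mean"]),
                sd=float(row["sd"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                n=int(row["n"]),
            )
    return out


def format_report_text(report: EvalReport) -> str:
    """Aligned plain-text mean/SD/CI table, one block per metric."""
    lines = []
    for metric, block in (("PSNR (dB)", report.psnr_summary),
                          ("SSIM", report.ssim_summary)):
        lines.append(metric)
        lines.append(f"  {'method':<14}{'mean':>10}{'SD':>10}{'95% CI':>22}")
        for method in report.methods:
            s = block[method]
            ci = f"[{s.ci_low:.4f}, {s.ci_high:.4f}]"
            lines.append(f"  {method:<14}{s.mean:>10.4f}{s.sd:>10.4f}{ci:>22}")
    return "\n".join(lines)
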