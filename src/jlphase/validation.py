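"""Microsphere-based accuracy validation of reconstructed OPD maps.

Spheres of known radius and index in index-known oil have an analytic
projected OPD (2·√(r² − ρ²)·Δn), so detecting them with a circular Hough
transform yields per-pixel ground truth wherever a sphere sits.  The
pixel-wise percentage error

    Err = (OPD_GT − OPD_reconstructed) / OPD_max · 100

is evaluated inside the detected-sphere mask (disks eroded by one pixel to
drop aliased edges), where ``OPD_max`` is the full-scale OPD of the
calibration reference (the fiber's on-axis value).  Frame statistics are
the mean of |Err| and the population std of signed Err.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from skimage.feature import canny
from skimage.transform import hough_circle

from .containers import OPDMap
from .phantoms import SphereSpec, sphere_opd_map

__all__ = [
    "DetectedCircle",
    "FrameErrorStats",
    "detect_spheres",
    "ground_truth_projection",
    "circles_mask",
    "error_stats",
    "sequence_report",
]


@dataclass
class DetectedCircle:
    """One circle found by the Hough detector: center (row, col) px, radius px."""

    center: tuple[float, float]
    radius: float
    score: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")


@dataclass
class FrameErrorStats:
    """Per-frame percentage-error summary over the validation mask."""

    frame_index: int
    mean_abs_err_pct: float
    std_err_pct: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        if not (np.isfinite(self.mean_abs_err_pct) and np.isfinite(self.std_err_pct)):
            raise ValueError("error statistics must be finite")


def _as_gray(arr) -> np.ndarray:
    values = arr.values if isinstance(arr, OPDMap) else np.asarray(arr, dtype=np.float64)
    if values.ndim == 3:
        values = values.mean(axis=-1)
    if values.ndim != 2:
        raise ValueError("expected a 2-D map or grayscale image")
    span = values.max() - values.min()
    if span > 0:
        values = (values - values.min()) / span
    return values


def _disk_overlap_frac(c1: DetectedCircle, c2: DetectedCircle) -> float:
    """Area of intersection of two disks over the smaller disk's area."""
    d = float(np.hypot(c1.center[0] - c2.center[0], c1.center[1] - c2.center[1]))
    r1, r2 = c1.radius, c2.radius
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        inter = np.pi * min(r1, r2) ** 2
    else:
        a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
        a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
        a3 = 0.5 * np.sqrt(
            (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
        )
        inter = a1 + a2 - a3
    return float(inter / (np.pi * min(r1, r2) ** 2))


def detect_spheres(
    arr,
    radius_range: tuple[int, int],
    max_circles: int | None = None,
    canny_sigma: float = 1.5,
    min_score: float = 0.3,
    max_overlap: float = 0.25,
) -> list[DetectedCircle]:
    """Circle-Hough sphere detection on an OPD map or grayscale image.

    Edges come from a Canny filter on the normalized input; circles are
    scored by normalized Hough accumulator response, greedily kept so that
    no accepted pair of disks overlaps by more than ``max_overlap`` of the
    smaller disk's area, and returned sorted by score.
    """
    gray = _as_gray(arr)
    r_lo, r_hi = int(radius_range[0]), int(radius_range[1])
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError("radius_range must satisfy 1 <= r_min <= r_max")
    if r_hi >= min(gray.shape):
        raise ValueError("radius_range exceeds image size")

    edges = canny(gray, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(r_lo, r_hi + 1)
    accum = hough_circle(edges, radii, normalize=True)

    # candidate peaks: strongest response per radius, then global greedy NMS
    candidates: list[DetectedCircle] = []
    for k, r in enumerate(radii):
        a = accum[k]
        flat = np.argsort(a.ravel())[::-1][:20]
        for f in flat:
            row, col = np.unravel_index(f, a.shape)
            score = float(a[row, col])
            if score < min_score:
                break
            candidates.append(DetectedCircle((float(row), float(col)), float(r), score))
    candidates.sort(key=lambda c: c.score, reverse=True)

    kept: list[DetectedCircle] = []
    for cand in candidates:
        if any(_disk_overlap_frac(cand, k) > max_overlap for k in kept):
            continue
        kept.append(cand)
        if max_circles is not None and len(kept) >= max_circles:
            break
    return kept


def ground_truth_projection(
    circles: list[DetectedCircle],
    shape: tuple[int, int],
    n_sphere: float = 1.592,
    n_oil: float = 1.5321,
    pixel_size: float = 1.0,
) -> OPDMap:
    """Analytic OPD projection of ideal spheres at the detected positions.

    Radii are converted from pixels to µm with ``pixel_size`` and the map
    is delegated to :func:`jlphase.phantoms.sphere_opd_map`.
    """
    spec = SphereSpec(
        centers=[c.center for c in circles],
        radii=[c.radius * pixel_size for c in circles],
        n_sphere=n_sphere,
        n_oil=n_oil,
    )
    return sphere_opd_map(spec, shape, pixel_size)


def circles_mask(
    circles: list[DetectedCircle], shape: tuple[int, int], erode_px: int = 1
) -> np.ndarray:
    """Union of detected disks, eroded to exclude aliased edge pixels."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for c in circles:
        mask |= (yy - c.center[0]) ** 2 + (xx - c.center[1]) ** 2 < c.radius**2
    for _ in range(erode_px):
        mask = binary_erosion(mask)
    return mask


def error_stats(
    gt: OPDMap,
    rec: OPDMap,
    opd_max: float,
    mask: np.ndarray,
    frame_index: int = 0,
) -> FrameErrorStats:
    """Pixel-wise percentage error between ground truth and reconstruction.

    Err = (gt − rec)/opd_max·100 per masked pixel; reports the mean of
    |Err| and the population standard deviation of signed Err.
    """
    if gt.values.shape != rec.values.shape:
        raise ValueError("ground truth and reconstruction shapes differ")
    if not opd_max > 0:
        raise ValueError("opd_max must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gt.values.shape:
        raise ValueError("mask shape differs from maps")
    if not mask.any():
        raise ValueError("mask is empty")
    err = (gt.values[mask] - rec.values[mask]) / opd_max * 100.0
    return FrameErrorStats(
        frame_index=frame_index,
        mean_abs_err_pct=float(np.abs(err).mean()),
        std_err_pct=float(err.std()),
        n_pixels=int(mask.sum()),
    )


def sequence_report(
    frames: list[tuple[OPDMap, OPDMap, np.ndarray]],
    opd_max: float,
) -> tuple[list[FrameErrorStats], float, float]:
    """Per-frame error statistics plus the sequence-level mean ± std.

    ``frames`` holds (ground truth, reconstruction, mask) triples.  The
    aggregate is the mean and population std of the per-frame mean |Err|.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    stats = [
        error_stats(gt, rec, opd_max, mask, frame_index=i)
        for i, (gt, rec, mask) in enumerate(frames)
    ]
    means = np.array([s.mean_abs_err_pct for s in stats])
    return stats, float(means.mean()), float(means.std())


def report_to_csv(stats: list[FrameErrorStats], path) -> None:
    pd.DataFrame(
        {
            "frame": [s.frame_index for s in stats],
            "mean_abs_err_pct": [s.mean_abs_err_pct for s in stats],
            "std_err_pct": [s.std_err_pct for s in stats],
            "n_pixels": [s.n_pixels for s in stats],
        }
    ).to_csv(path, index=False)


def summary_to_json(mean: float, std: float, n_frames: int, path) -> None:
    from pathlib import Path

    Path(path).write_text(
        json.dumps(
            {"mean_abs_err_pct": mean, "std_err_pct": std, "n_frames": n_frames},
            indent=2,
        )
    )
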