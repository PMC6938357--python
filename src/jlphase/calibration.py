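"""RGB↔OPD look-up table construction and its differentiable polynomial fit.

Calibration images a reference object of known phase profile (here a
cylindrical fiber) and tabulates the mean interference color per OPD bin.
The resulting table traces a parametric curve in RGB space; because
interference colors repeat with fading saturation every order, the curve
nearly self-intersects, which is the fundamental ambiguity of color-coded
phase measurement.  A per-channel polynomial fit of the table (order ≤ 10)
makes the color-vs-OPD relation differentiable so gradient-based inversion
can run through it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OPDMap, RGBImage

__all__ = [
    "CalibrationCurve",
    "PolyLUT",
    "build_lut",
    "fit_poly_lut",
    "evaluate_lut",
    "ambiguity_report",
]

MAX_POLY_ORDER = 10

#: Default calibration range: three interference orders at 546 nm.
DEFAULT_OPD_RANGE = (0.0, 3.0 * 546.0)
DEFAULT_N_BINS = 50


@dataclass
class CalibrationCurve:
    """Tabulated mean RGB color per OPD bin.

    ``counts`` records how many reference pixels fell in each bin; bins
    filled by interpolation carry count 0.
    """

    opd_bins: np.ndarray
    mean_rgb: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.opd_bins = np.asarray(self.opd_bins, dtype=np.float64)
        self.mean_rgb = np.asarray(self.mean_rgb, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.opd_bins.ndim != 1:
            raise ValueError("opd_bins must be 1-D")
        if np.any(np.diff(self.opd_bins) <= 0):
            raise ValueError("opd_bins must be strictly increasing")
        if self.mean_rgb.shape != (self.opd_bins.size, 3):
            raise ValueError("mean_rgb must be (n_bins, 3)")
        if self.counts.shape != self.opd_bins.shape or np.any(self.counts < 0):
            raise ValueError("counts must be non-negative, one per bin")
        if not np.all(np.isfinite(self.mean_rgb)):
            raise ValueError("mean_rgb must be finite for every bin")

    def __len__(self) -> int:
        return self.opd_bins.size

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "opd_nm": self.opd_bins,
                "r": self.mean_rgb[:, 0],
                "g": self.mean_rgb[:, 1],
                "b": self.mean_rgb[:, 2],
                "count": self.counts,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(
            df["opd_nm"].to_numpy(),
            df[["r", "g", "b"]].to_numpy(),
            df["count"].to_numpy(),
        )


@dataclass
class PolyLUT:
    """Per-channel polynomial parametrization of the calibration curve.

    Coefficients are stored in ascending power order on the rescaled
    variable ``x = (opd − mid)/half ∈ [−1, 1]`` over ``domain`` for
    numerical conditioning; evaluation is clamped to the domain.
    """

    coeffs_r: np.ndarray
    coeffs_g: np.ndarray
    coeffs_b: np.ndarray
    domain: tuple[float, float]
    order: int

    def __post_init__(self) -> None:
        for name in ("coeffs_r", "coeffs_g", "coeffs_b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.order < 0 or self.order > MAX_POLY_ORDER:
            raise ValueError(f"polynomial order must be in [0, {MAX_POLY_ORDER}]")
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("domain must be finite with opd_min < opd_max")

    @property
    def _mid_half(self) -> tuple[float, float]:
        lo, hi = self.domain
        return (lo + hi) / 2.0, (hi - lo) / 2.0

    def to_scaled(self, opd: np.ndarray) -> np.ndarray:
        mid, half = self._mid_half
        return (np.asarray(opd, dtype=np.float64) - mid) / half

    def to_json(self, path) -> None:
        payload = {
            "coeffs_r": self.coeffs_r.tolist(),
            "coeffs_g": self.coeffs_g.tolist(),
            "coeffs_b": self.coeffs_b.tolist(),
            "domain": list(self.domain),
            "order": self.order,
            "basis": "power, ascending, on (opd - mid)/half with mid/half from domain",
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "PolyLUT":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["coeffs_r"]),
            np.array(payload["coeffs_g"]),
            np.array(payload["coeffs_b"]),
            tuple(payload["domain"]),
            int(payload["order"]),
        )


def build_lut(
    image: RGBImage,
    reference: OPDMap,
    n_bins: int = DEFAULT_N_BINS,
    opd_range: tuple[float, float] = DEFAULT_OPD_RANGE,
    binning_mode: str = "equal-opd",
) -> CalibrationCurve:
    """Tabulate mean RGB per OPD bin from a reference measurement.

    ``equal-opd`` uses uniformly spaced bins over ``opd_range``;
    ``equal-count`` uses quantile edges of the reference OPD distribution so
    every bin averages about the same number of pixels — useful because a
    cylindrical reference samples OPD very unevenly.  Bins are half-open
    [lo, hi), the last closed.  Empty bins are filled by linear
    interpolation between non-empty neighbors and flagged with count 0.
    """
    if image.values.shape[:2] != reference.values.shape:
        raise ValueError(
            f"image shape {image.values.shape[:2]} != reference shape {reference.values.shape}"
        )
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    lo, hi = opd_range
    if not lo < hi:
        raise ValueError("opd_range must satisfy lo < hi")

    opd = reference.values.ravel()
    rgb = image.values.reshape(-1, 3)
    in_range = (opd >= lo) & (opd <= hi)
    if not np.any(in_range):
        raise ValueError("no reference pixel falls inside opd_range")
    opd, rgb = opd[in_range], rgb[in_range]

    if binning_mode == "equal-opd":
        edges = np.linspace(lo, hi, n_bins + 1)
    elif binning_mode == "equal-count":
        edges = np.quantile(opd, np.linspace(0.0, 1.0, n_bins + 1))
        edges[0], edges[-1] = lo, hi
        # an OPD atom (e.g. a constant background) collapses quantile edges;
        # keep one bin at the atom and spread duplicates up to the next
        # distinct edge
        if np.any(np.diff(edges) <= 0):
            uniq = np.unique(edges)
            if uniq.size < 2:
                raise ValueError(
                    "equal-count binning degenerate: reference OPD values are "
                    "effectively constant over opd_range"
                )
            k = 0
            fixed = edges.copy()
            while k < n_bins:
                j = k
                while j + 1 <= n_bins and edges[j + 1] <= fixed[k]:
                    j += 1
                if j > k:
                    nxt = edges[j + 1] if j + 1 <= n_bins else hi
                    fixed[k : j + 2] = np.linspace(fixed[k], nxt, j - k + 2)
                k = j + 1
            edges = fixed
            if np.any(np.diff(edges) <= 0):
                raise ValueError(
                    "equal-count binning produced degenerate edges; reference "
                    "OPD values are too discrete for this many bins"
                )
    else:
        raise ValueError(f"unknown binning_mode {binning_mode!r}")

    # half-open [lo, hi) bins, last bin closed
    idx = np.searchsorted(edges, opd, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins)
    mean_rgb = np.full((n_bins, 3), np.nan)
    for c in range(3):
        sums = np.bincount(idx, weights=rgb[:, c], minlength=n_bins)
        np.divide(sums, counts, out=mean_rgb[:, c], where=counts > 0)

    centers = (edges[:-1] + edges[1:]) / 2.0

    empty = counts == 0
    if np.all(empty):
        raise ValueError("every bin is empty")
    if np.any(empty):
        filled = ~empty
        for c in range(3):
            mean_rgb[empty, c] = np.interp(
                centers[empty], centers[filled], mean_rgb[filled, c]
            )
    return CalibrationCurve(centers, mean_rgb, counts)


def fit_poly_lut(
    curve: CalibrationCurve, order: int = MAX_POLY_ORDER, weighted: bool = False
) -> PolyLUT:
    """Least-squares polynomial fit per channel of the LUT bin means.

    By default every bin counts equally: each bin mean is already an
    average, and a cylindrical reference samples OPD so unevenly (the
    chord density diverges at the axis and the background piles into the
    zero bin) that count weighting would starve the low-OPD arc of the
    curve.  Interpolated (count-0) bins participate too — they are the
    linear gap-fill across the reference's sampling holes and keep the
    polynomial constrained there.  ``weighted=True`` switches to
    count-weighted least squares (interpolated bins then drop out).
    Requires at least ``order + 1`` non-empty bins.
    """
    if order < 1 or order > MAX_POLY_ORDER:
        raise ValueError(f"order must be in [1, {MAX_POLY_ORDER}]")
    nonempty = int(np.count_nonzero(curve.counts))
    if nonempty < order + 1:
        raise ValueError(
            f"need at least {order + 1} non-empty bins for order {order}, have {nonempty}"
        )
    domain = (float(curve.opd_bins[0]), float(curve.opd_bins[-1]))
    mid, half = (domain[0] + domain[1]) / 2.0, (domain[1] - domain[0]) / 2.0
    x = (curve.opd_bins - mid) / half
    # numpy applies weights to residuals, so sqrt gives (count-)weighted LSQ
    if weighted:
        w = np.sqrt(curve.counts.astype(np.float64))
    else:
        w = np.ones_like(x)
    coeffs = [
        np.polynomial.polynomial.polyfit(x, curve.mean_rgb[:, c], deg=order, w=w)
        for c in range(3)
    ]
    return PolyLUT(coeffs[0], coeffs[1], coeffs[2], domain, order)


def evaluate_lut(lut: PolyLUT, opd) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the polynomial LUT and its derivative at the given OPDs.

    Returns ``(rgb, drgb_dopd)`` with a trailing channel axis.  OPD is
    clamped to the LUT domain; outside the domain the value is held at the
    nearest edge and the derivative is zero.  Values are clipped to [0, 1]
    on output; the derivative is that of the unclipped polynomial.
    """
    rgb, drgb = evaluate_lut_raw(lut, opd)
    return np.clip(rgb, 0.0, 1.0), drgb


def evaluate_lut_raw(lut: PolyLUT, opd) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`evaluate_lut` but without the [0, 1] clip on values.

    The smooth (unclipped) values keep the inversion loss and its analytic
    gradient exactly consistent, which the optimizer relies on.
    """
    opd = np.asarray(opd, dtype=np.float64)
    lo, hi = lut.domain
    inside = (opd >= lo) & (opd <= hi)
    x = lut.to_scaled(np.clip(opd, lo, hi))
    _, half = lut._mid_half
    rgb = np.empty(opd.shape + (3,))
    drgb = np.empty(opd.shape + (3,))
    for c, coeffs in enumerate((lut.coeffs_r, lut.coeffs_g, lut.coeffs_b)):
        rgb[..., c] = np.polynomial.polynomial.polyval(x, coeffs)
        dcoeffs = np.polynomial.polynomial.polyder(coeffs)
        drgb[..., c] = np.polynomial.polynomial.polyval(x, dcoeffs) / half
    drgb[~inside] = 0.0
    return rgb, drgb


def ambiguity_report(
    curve: CalibrationCurve, rgb_distance_threshold: float
) -> list[tuple[float, float, float]]:
    """Near self-intersections of the 3-D parametric color curve.

    Scans all bin pairs more than two bin-widths apart in OPD and reports
    those whose Euclidean RGB distance falls below the threshold, sorted
    ascending by distance — the OPD pairs a noisy pixel can be confused
    between.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 bins")
    opd = curve.opd_bins
    bin_width = float(np.mean(np.diff(opd)))
    dists = np.linalg.norm(curve.mean_rgb[:, None, :] - curve.mean_rgb[None, :, :], axis=-1)
    sep = np.abs(opd[:, None] - opd[None, :])
    ii, jj = np.nonzero(
        (sep > 2.0 * bin_width) & (dists < rgb_distance_threshold) & (opd[:, None] < opd[None, :])
    )
    pairs = [(float(opd[i]), float(opd[j]), float(dists[i, j])) for i, j in zip(ii, jj)]
    pairs.sort(key=lambda t: t[2])
    return pairs
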