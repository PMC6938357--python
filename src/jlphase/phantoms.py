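"""Ground-truth OPD phantoms: cylindrical fiber, microsphere fields, cell blobs.

These reproduce the calibration and validation objects used with the
instrument: a tapered glass fiber of known diameter and index embedded in
index-matched medium (the look-up-table reference), polymer microspheres in
immersion oil (the accuracy benchmark), and smooth cell-like blobs.  A
transparent object of thickness ``d`` and index ``n_O`` in a medium of
index ``n_R`` contributes an optical path difference ``OPD = d·(n_O −
n_R)``; for cylinders and spheres ``d`` is the chord length through the
body, evaluated at pixel centers without anti-aliasing.

Geometry is specified in µm, OPD is returned in nm (factor 1000 applied at
map construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import OPDMap

__all__ = [
    "FiberSpec",
    "SphereSpec",
    "fiber_opd_map",
    "sphere_opd_map",
    "cell_phantom",
    "random_sphere_field",
]

UM_TO_NM = 1000.0


@dataclass
class FiberSpec:
    """Cylindrical reference fiber in an index-matched medium.

    The default parameters are a telecom fiber tapered to 38 µm diameter
    (effective index 1.4585) in a glycerol/water mixture (1.4140), whose
    on-axis OPD spans three interference orders at 546 nm.

    ``taper`` optionally gives the end-to-end diameter ratio along the fiber
    axis (1.0 = uniform, the default behavior).
    """

    diameter: float = 38.0
    n_fiber: float = 1.4585
    n_medium: float = 1.4140
    angle: float = 0.0
    taper: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if not self.n_fiber > self.n_medium:
            raise ValueError("n_fiber must exceed n_medium (positive OPD convention)")
        if self.taper is not None and not self.taper > 0:
            raise ValueError("taper ratio must be positive")

    @property
    def max_opd(self) -> float:
        """On-axis OPD at full diameter, nm: diameter·Δn."""
        return self.diameter * (self.n_fiber - self.n_medium) * UM_TO_NM


@dataclass
class SphereSpec:
    """Field of microspheres in immersion oil.

    Defaults are PMMA spheres (n = 1.592) in matching oil (n = 1.5321);
    the center OPD of a sphere of radius r is 2·r·Δn.
    """

    centers: list = field(default_factory=list)
    radii: list = field(default_factory=list)
    n_sphere: float = 1.592
    n_oil: float = 1.5321

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii must have equal length")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if not self.n_sphere > self.n_oil:
            raise ValueError("n_sphere must exceed n_oil (positive OPD convention)")

    def max_opd(self) -> float:
        """Largest center OPD in the field, nm: max over spheres of 2·r·Δn."""
        if not self.radii:
            return 0.0
        return 2.0 * max(self.radii) * (self.n_sphere - self.n_oil) * UM_TO_NM


def _pixel_grid(shape: tuple[int, int], pixel_size: float):
    h, w = shape
    rows = (np.arange(h) + 0.5) * pixel_size
    cols = (np.arange(w) + 0.5) * pixel_size
    return np.meshgrid(rows, cols, indexing="ij")


def fiber_opd_map(
    spec: FiberSpec, shape: tuple[int, int], pixel_size: float = 1.0
) -> OPDMap:
    """Projected OPD of a cylindrical fiber through the image center.

    For perpendicular distance ``u`` (µm) from the fiber axis the chord
    length is ``2·√(r² − u²)``, so ``OPD(u) = 2·√(r² − u²)·Δn·1000`` nm for
    ``|u| < r`` and 0 outside.  The axis runs through the image center at
    ``spec.angle`` degrees from the row direction.
    """
    h, w = shape
    r_um = spec.diameter / 2.0
    if spec.diameter / pixel_size < 2.0:
        raise ValueError("fiber must span at least 2 pixels at this pixel size")
    if spec.diameter > min(h, w) * pixel_size:
        raise ValueError("fiber is wider than the image")

    yy, xx = _pixel_grid(shape, pixel_size)
    cy, cx = h * pixel_size / 2.0, w * pixel_size / 2.0
    theta = np.deg2rad(spec.angle)
    # axis direction (row, col); u = perpendicular signed distance, s = along axis
    ar, ac = np.cos(theta), np.sin(theta)
    u = -(yy - cy) * ac + (xx - cx) * ar
    if spec.taper is not None and spec.taper != 1.0:
        s = (yy - cy) * ar + (xx - cx) * ac
        half_span = max(h, w) * pixel_size / 2.0
        scale = 1.0 + (spec.taper - 1.0) * (s + half_span) / (2.0 * half_span)
        radius = r_um * np.clip(scale, 0.0, None)
    else:
        radius = r_um
    chord_sq = radius**2 - u**2
    opd = np.where(chord_sq > 0, 2.0 * np.sqrt(np.clip(chord_sq, 0, None)), 0.0)
    opd *= (spec.n_fiber - spec.n_medium) * UM_TO_NM
    return OPDMap(opd, pixel_size)


def sphere_opd_map(
    spec: SphereSpec,
    shape: tuple[int, int],
    pixel_size: float = 1.0,
    strict: bool = False,
) -> OPDMap:
    """Projected OPD of a microsphere field.

    Per sphere, ``OPD(ρ) = 2·√(r² − ρ²)·Δn·1000`` nm for in-plane distance
    ``ρ < r`` from the center; overlapping spheres add their optical paths
    unless ``strict`` is set, in which case overlaps (and out-of-bounds
    spheres) raise.
    """
    h, w = shape
    opd = np.zeros(shape, dtype=np.float64)
    dn = spec.n_sphere - spec.n_oil
    yy, xx = _pixel_grid(shape, pixel_size)
    covered = np.zeros(shape, dtype=bool)
    for (row, col), r_um in zip(spec.centers, spec.radii):
        cy, cx = (row + 0.5) * pixel_size, (col + 0.5) * pixel_size
        r_px = r_um / pixel_size
        if row - r_px < -0.5 or row + r_px > h - 0.5 or col - r_px < -0.5 or col + r_px > w - 0.5:
            raise ValueError(f"sphere at ({row}, {col}) with radius {r_um} µm exceeds image bounds")
        rho_sq = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = rho_sq < r_um**2
        if strict and np.any(covered & inside):
            raise ValueError("overlapping spheres rejected in strict mode")
        covered |= inside
        chord = 2.0 * np.sqrt(np.clip(r_um**2 - rho_sq, 0, None))
        opd += np.where(inside, chord * dn * UM_TO_NM, 0.0)
    return OPDMap(opd, pixel_size)


def random_sphere_field(
    shape: tuple[int, int],
    pixel_size: float = 1.0,
    n_spheres: int = 5,
    radius_range_um: tuple[float, float] = (8.0, 12.0),
    seed: int = 0,
    min_gap_px: float = 2.0,
    n_sphere: float = 1.592,
    n_oil: float = 1.5321,
) -> SphereSpec:
    """Random non-overlapping sphere field for validation experiments.

    Spheres are placed by rejection sampling with at least ``min_gap_px``
    clearance between rims and full containment in the image.  Same seed ⇒
    identical field.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_spheres):
        r_um = rng.uniform(*radius_range_um)
        r_px = r_um / pixel_size
        for _ in range(200):
            cand = (
                rng.uniform(r_px + min_gap_px, h - r_px - min_gap_px),
                rng.uniform(r_px + min_gap_px, w - r_px - min_gap_px),
            )
            ok = all(
                (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2
                > (r_px + rr / pixel_size + min_gap_px) ** 2
                for c, rr in zip(centers, radii)
            )
            if ok:
                centers.append(cand)
                radii.append(r_um)
                break
    return SphereSpec(centers=centers, radii=radii, n_sphere=n_sphere, n_oil=n_oil)


def cell_phantom(
    shape: tuple[int, int],
    pixel_size: float = 1.0,
    n_blobs: int = 5,
    opd_peak: float = 500.0,
    smoothness: float = 0.15,
    seed: int = 0,
) -> OPDMap:
    """Smooth, non-negative cell-like OPD blob field, peak scaled to opd_peak.

    A stand-in for adherent cells, whose OPD typically stays below one
    wavelength: a sum of ``n_blobs`` random anisotropic Gaussian bumps with
    width ~ ``smoothness``·min(H, W) pixels, rescaled so the maximum equals
    ``opd_peak`` nm.  Same seed ⇒ identical map.
    """
    if not opd_peak > 0:
        raise ValueError("opd_peak must be positive")
    h, w = shape
    opd = np.zeros(shape, dtype=np.float64)
    if n_blobs == 0:
        return OPDMap(opd, pixel_size)
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    base = smoothness * min(h, w)
    for _ in range(n_blobs):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        sy = base * rng.uniform(0.5, 1.5)
        sx = base * rng.uniform(0.5, 1.5)
        amp = rng.uniform(0.3, 1.0)
        opd += amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    opd *= opd_peak / opd.max()
    return OPDMap(opd, pixel_size)
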