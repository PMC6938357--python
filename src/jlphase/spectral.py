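"""White-light two-beam interference forward model.

Between crossed polarizer and analyser, a retardation (optical path
difference, OPD) produces the transmittance ``sin²(π·OPD/λ)``: zero OPD
gives the dark background, and the colors of the Michel-Levy chart arise
because every wavelength of the source contributes its own transmitted
intensity.  A camera channel ``c`` therefore records

    V_c = ∫ S(λ) · Q_c(λ) · sin²(π·OPD/λ) dλ

with ``S`` the relative source spectrum and ``Q_c`` the channel
sensitivity.  The integral is evaluated with trapezoidal weights over a
discrete wavelength grid.

The module also simulates two acquisition artifacts of the Jamin-Lebedeff
design: the ghost image (an attenuated, laterally sheared duplicate added
by the reference beam crossing the specimen) and additive sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import OPDMap, RGBImage

__all__ = [
    "SpectralGrid",
    "SourceSpectrum",
    "ChannelSensitivity",
    "interference_transmittance",
    "render_rgb",
    "michel_levy_strip",
    "add_ghost",
    "add_noise",
]

#: Default wavelength grid: visible band, fine enough for a smooth integrand.
DEFAULT_WAVELENGTHS = np.arange(380.0, 781.0, 5.0)

#: Default channel centers (nm) and Gaussian standard width (nm).
DEFAULT_CHANNEL_CENTERS = (610.0, 540.0, 465.0)
DEFAULT_CHANNEL_WIDTH = 60.0


@dataclass
class SpectralGrid:
    """Ordered wavelength samples, nm, restricted to 300–900 nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("SpectralGrid requires at least 2 wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] < 300.0 or self.wavelengths[-1] > 900.0:
            raise ValueError("wavelengths must lie within [300, 900] nm")

    def __len__(self) -> int:
        return self.wavelengths.size

    def trapezoid_weights(self) -> np.ndarray:
        """Composite trapezoidal quadrature weights for this grid."""
        w = np.empty_like(self.wavelengths)
        d = np.diff(self.wavelengths)
        w[0] = d[0] / 2.0
        w[-1] = d[-1] / 2.0
        w[1:-1] = (d[:-1] + d[1:]) / 2.0
        return w


@dataclass
class SourceSpectrum:
    """Relative spectral power of the illumination on a wavelength grid."""

    grid: SpectralGrid
    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.shape != self.grid.wavelengths.shape:
            raise ValueError("power must have one value per grid wavelength")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if not np.any(self.power > 0):
            raise ValueError("spectral power must not be all zero")

    @classmethod
    def flat(cls, wavelengths: np.ndarray | None = None) -> "SourceSpectrum":
        """Uniform white source over the given (default visible) grid."""
        grid = SpectralGrid(DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths)
        return cls(grid, np.ones(len(grid)))

    @classmethod
    def monochromatic(
        cls, wavelength: float, halfwidth: float = 1.0
    ) -> "SourceSpectrum":
        """Narrow source: power 1 at ``wavelength``, 0 at ±``halfwidth``."""
        grid = SpectralGrid(
            np.array([wavelength - halfwidth, wavelength, wavelength + halfwidth])
        )
        return cls(grid, np.array([0.0, 1.0, 0.0]))

    def resample(self, grid: SpectralGrid) -> "SourceSpectrum":
        power = np.interp(grid.wavelengths, self.grid.wavelengths, self.power)
        return SourceSpectrum(grid, power)


@dataclass
class ChannelSensitivity:
    """Per-wavelength R, G, B sensitivities of the imaging device in [0, 1]."""

    grid: SpectralGrid
    q_red: np.ndarray
    q_green: np.ndarray
    q_blue: np.ndarray

    def __post_init__(self) -> None:
        for name in ("q_red", "q_green", "q_blue"):
            q = np.asarray(getattr(self, name), dtype=np.float64)
            if q.shape != self.grid.wavelengths.shape:
                raise ValueError(f"{name} must have one value per grid wavelength")
            if q.min() < 0 or q.max() > 1:
                raise ValueError(f"{name} values must lie in [0, 1]")
            setattr(self, name, q)
        # a channel may be absent (all-zero, e.g. an idealized single-color
        # sensor) but a sensor with no response at all is rejected
        if not (np.any(self.q_red > 0) or np.any(self.q_green > 0) or np.any(self.q_blue > 0)):
            raise ValueError("at least one channel must have a positive sensitivity")

    @classmethod
    def gaussian(
        cls,
        wavelengths: np.ndarray | None = None,
        centers: tuple[float, float, float] = DEFAULT_CHANNEL_CENTERS,
        width: float = DEFAULT_CHANNEL_WIDTH,
    ) -> "ChannelSensitivity":
        """Gaussian R/G/B channels (default centers 610/540/465 nm, std 60 nm)."""
        grid = SpectralGrid(DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths)
        lam = grid.wavelengths
        q = [np.exp(-0.5 * ((lam - c) / width) ** 2) for c in centers]
        return cls(grid, *q)

    @property
    def stacked(self) -> np.ndarray:
        """Sensitivities as an (n_wavelengths, 3) array in R, G, B order."""
        return np.stack([self.q_red, self.q_green, self.q_blue], axis=1)

    def resample(self, grid: SpectralGrid) -> "ChannelSensitivity":
        lam_new, lam_old = grid.wavelengths, self.grid.wavelengths
        return ChannelSensitivity(
            grid,
            np.interp(lam_new, lam_old, self.q_red),
            np.interp(lam_new, lam_old, self.q_green),
            np.interp(lam_new, lam_old, self.q_blue),
        )


def interference_transmittance(opd, wavelength):
    """Crossed-polarizer transmitted fraction sin²(π·OPD/λ).

    Periodic in ``opd`` with period ``wavelength``; zero at integer multiples
    of the wavelength (dark background at OPD = 0) and maximal at half-wave
    retardation.  ``opd`` may be an array; ``wavelength`` must be positive.
    """
    wavelength = np.asarray(wavelength, dtype=np.float64)
    if np.any(wavelength <= 0):
        raise ValueError("wavelength must be positive")
    opd = np.asarray(opd, dtype=np.float64)
    return np.sin(np.pi * opd / wavelength) ** 2


def _common_grid(
    source: SourceSpectrum, sens: ChannelSensitivity
) -> tuple[SourceSpectrum, ChannelSensitivity]:
    """Bring source and sensitivities onto one grid (resample onto overlap)."""
    if np.array_equal(source.grid.wavelengths, sens.grid.wavelengths):
        return source, sens
    lo = max(source.grid.wavelengths[0], sens.grid.wavelengths[0])
    hi = min(source.grid.wavelengths[-1], sens.grid.wavelengths[-1])
    if hi <= lo:
        raise ValueError("source and sensitivity wavelength grids do not overlap")
    merged = np.union1d(source.grid.wavelengths, sens.grid.wavelengths)
    merged = merged[(merged >= lo) & (merged <= hi)]
    grid = SpectralGrid(merged)
    return source.resample(grid), sens.resample(grid)


def render_rgb(
    opd_map: OPDMap,
    source: SourceSpectrum | None = None,
    sens: ChannelSensitivity | None = None,
    normalize: bool = True,
) -> RGBImage:
    """Render the interference-color image of an OPD map.

    Per pixel and channel the spectrum-weighted transmittance is summed
    over the wavelength grid with trapezoidal weights.  With ``normalize``
    each channel is divided by its maximum achievable value
    ``Σ_λ S(λ)·Q_c(λ)·Δλ`` so that outputs lie in [0, 1] (a channel whose
    integral is zero renders as zero).
    """
    if source is None:
        source = SourceSpectrum.flat()
    if sens is None:
        sens = ChannelSensitivity.gaussian()
    source, sens = _common_grid(source, sens)

    lam = source.grid.wavelengths
    # per-wavelength, per-channel weight S(λ)·Q_c(λ)·Δλ  → (n_lam, 3)
    weight = (source.power * source.grid.trapezoid_weights())[:, None] * sens.stacked

    opd = opd_map.values
    out = np.zeros(opd.shape + (3,), dtype=np.float64)
    # accumulate over wavelengths to keep memory at O(H·W·3)
    for k in range(lam.size):
        t = np.sin(np.pi * opd / lam[k]) ** 2
        out += t[..., None] * weight[k]

    if normalize:
        denom = weight.sum(axis=0)
        for c in range(3):
            if denom[c] > 0:
                out[..., c] /= denom[c]
        np.clip(out, 0.0, 1.0, out=out)
    return RGBImage(out, opd_map.pixel_size)


def michel_levy_strip(
    opd_max: float,
    n_steps: int,
    source: SourceSpectrum | None = None,
    sens: ChannelSensitivity | None = None,
    normalize: bool = True,
) -> RGBImage:
    """Interference colors for OPD linearly spaced in [0, opd_max].

    Returns a 1 × n_steps color strip — a rendered Michel-Levy chart row.
    """
    if not opd_max > 0:
        raise ValueError("opd_max must be positive")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    ramp = np.linspace(0.0, opd_max, n_steps)[None, :]
    return render_rgb(OPDMap(ramp), source, sens, normalize=normalize)


def add_ghost(
    image: RGBImage,
    shear_px: tuple[int, int],
    attenuation: float,
    pre_blur: float = 0.0,
) -> RGBImage:
    """Superpose the attenuated, sheared ghost copy of the image.

    The Jamin-Lebedeff reference beam also traverses the specimen, adding a
    darker duplicate displaced by the beam shear.  Modeled as
    ``clip(image + attenuation·shift(image, shear_px), 0, 1)`` with
    zero-filled borders; ``shear_px`` is a (rows, cols) offset.  An optional
    Gaussian ``pre_blur`` (px) softens the copy; astigmatic blur of the real
    instrument is not modeled.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must lie in [0, 1]")
    dr, dc = int(shear_px[0]), int(shear_px[1])
    h, w = image.values.shape[:2]
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"shear {shear_px} exceeds image shape {(h, w)}")
    ghost = image.values
    if pre_blur > 0:
        ghost = ndimage.gaussian_filter(ghost, sigma=(pre_blur, pre_blur, 0))
    shifted = np.zeros_like(ghost)
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    shifted[dst_r, dst_c] = ghost[src_r, src_c]
    out = np.clip(image.values + attenuation * shifted, 0.0, 1.0)
    return RGBImage(out, image.pixel_size)


def add_noise(image: RGBImage, sigma: float, seed: int) -> RGBImage:
    """Add i.i.d. Gaussian sensor noise, clipped to [0, 1]; seeded."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image.values + rng.normal(0.0, sigma, size=image.values.shape)
    return RGBImage(np.clip(noisy, 0.0, 1.0), image.pixel_size)
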