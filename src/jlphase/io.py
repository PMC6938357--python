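"""File I/O: images, OPD maps, spectral curves, de-Bayering.

Measurement images are 8/16-bit PNG or TIFF; raw sensor mosaics are
single-channel TIFFs demosaiced here with bilinear interpolation.  All
color processing downstream assumes linear intensity, so sRGB-encoded
sources can be linearized on read.  OPD maps travel as 32-bit float TIFF
in nm, with the scale recorded in the image description tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .containers import OPDMap, RGBImage
from .spectral import ChannelSensitivity, SourceSpectrum, SpectralGrid

__all__ = [
    "read_rgb_image",
    "write_rgb_image",
    "read_opd_tiff",
    "write_opd_tiff",
    "debayer",
    "load_source_csv",
    "load_sensitivity_csv",
    "save_source_csv",
    "save_sensitivity_csv",
]

BAYER_PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")

# bilinear demosaic kernels: green sites form a quincunx, red/blue a square grid
_KERNEL_G = np.array([[0.0, 0.25, 0.0], [0.25, 1.0, 0.25], [0.0, 0.25, 0.0]])
_KERNEL_RB = np.array([[0.25, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 0.25]])


def _srgb_to_linear(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


def _scale_to_unit(arr: np.ndarray, path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path} (need 8- or 16-bit)")


def read_rgb_image(path, assume_gamma: bool = False, pixel_size: float = 1.0) -> RGBImage:
    """Read an 8/16-bit PNG/TIFF color image as a linear [0, 1] RGBImage.

    With ``assume_gamma`` the values are sRGB-decoded after scaling, for
    sources that were not acquired in a linear (RAW-derived) pipeline.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path} is not a 3-channel image (shape {arr.shape})")
    values = _scale_to_unit(arr, path)
    if assume_gamma:
        values = _srgb_to_linear(values)
    return RGBImage(values, pixel_size)


def write_rgb_image(path, image: RGBImage, apply_gamma: bool = False) -> None:
    """Write an RGBImage as 16-bit TIFF or 8-bit PNG.

    TIFF round-trips to within one 16-bit quantization step (1/65535);
    PNG, limited to 8 bits per channel for color data here, to 1/255.
    """
    path = Path(path)
    values = image.values
    if apply_gamma:
        values = _linear_to_srgb(values)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(values * 65535.0).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(values * 255.0).astype(np.uint8))


def read_opd_tiff(path, pixel_size: float | None = None) -> OPDMap:
    """Read a 32-bit float TIFF OPD map (nm); pixel size from metadata if present."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(np.float64)
        if pixel_size is None:
            pixel_size = 1.0
            desc = tif.pages[0].tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    pixel_size = float(meta.get("pixel_size_um", 1.0))
                except (ValueError, TypeError):
                    pass
    return OPDMap(arr, pixel_size)


def write_opd_tiff(path, opd_map: OPDMap) -> None:
    """Write an OPD map as 32-bit float TIFF with units/scale metadata."""
    meta = json.dumps({"units": "nm", "pixel_size_um": opd_map.pixel_size})
    tifffile.imwrite(Path(path), opd_map.values.astype(np.float32), description=meta)


def debayer(mosaic: np.ndarray, pattern: str, pixel_size: float = 1.0) -> RGBImage:
    """Bilinear demosaic of a single-channel Bayer mosaic in [0, 1].

    ``pattern`` names the color of the top-left 2×2 quad, e.g. RGGB.
    Output has the same H×W as the mosaic.
    """
    pattern = pattern.upper()
    if pattern not in BAYER_PATTERNS:
        raise ValueError(f"unknown Bayer pattern {pattern!r}; expected one of {BAYER_PATTERNS}")
    mosaic = np.asarray(mosaic, dtype=np.float64)
    if mosaic.ndim != 2:
        raise ValueError("mosaic must be single-channel (2-D)")
    h, w = mosaic.shape
    if h % 2 or w % 2:
        raise ValueError(f"mosaic dimensions must be even, got {mosaic.shape}")

    offsets = {ch: (i // 2, i % 2) for i, ch in enumerate(pattern)}
    out = np.zeros((h, w, 3), dtype=np.float64)
    for c, ch in enumerate("RGB"):
        site = np.zeros((h, w), dtype=np.float64)
        norm = np.zeros((h, w), dtype=np.float64)
        for i, p in enumerate(pattern):
            if p != ch:
                continue
            r0, c0 = i // 2, i % 2
            site[r0::2, c0::2] = mosaic[r0::2, c0::2]
            norm[r0::2, c0::2] = 1.0
        kernel = _KERNEL_G if ch == "G" else _KERNEL_RB
        num = ndimage.convolve(site, kernel, mode="mirror")
        den = ndimage.convolve(norm, kernel, mode="mirror")
        out[:, :, c] = num / den
    return RGBImage(np.clip(out, 0.0, 1.0), pixel_size)


def load_source_csv(path) -> SourceSpectrum:
    """Load a source spectrum from CSV with header ``wavelength_nm,value``."""
    df = pd.read_csv(path)
    grid = SpectralGrid(df["wavelength_nm"].to_numpy())
    return SourceSpectrum(grid, df["value"].to_numpy())


def save_source_csv(path, source: SourceSpectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": source.grid.wavelengths, "value": source.power}
    ).to_csv(path, index=False)


def load_sensitivity_csv(path) -> ChannelSensitivity:
    """Load channel sensitivities from CSV with header ``wavelength_nm,r,g,b``."""
    df = pd.read_csv(path)
    grid = SpectralGrid(df["wavelength_nm"].to_numpy())
    return ChannelSensitivity(
        grid, df["r"].to_numpy(), df["g"].to_numpy(), df["b"].to_numpy()
    )


def save_sensitivity_csv(path, sens: ChannelSensitivity) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": sens.grid.wavelengths,
            "r": sens.q_red,
            "g": sens.q_green,
            "b": sens.q_blue,
        }
    ).to_csv(path, index=False)
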