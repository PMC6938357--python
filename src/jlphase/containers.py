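"""Core image containers: OPD maps and linear-intensity RGB images.

All OPD values are in nanometres, all geometry (pixel size) in micrometres.
Color arithmetic throughout the package is linear in intensity; gamma
handling is confined to file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OPDMap", "RGBImage"]


@dataclass
class OPDMap:
    """2-D scalar field of optical path difference.

    Parameters
    ----------
    values : ndarray of shape (H, W)
        Optical path difference per pixel, nm.
    pixel_size : float
        Lateral sampling, µm per pixel.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"OPDMap requires a 2-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OPDMap values must be finite")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "OPDMap":
        return OPDMap(self.values.copy(), self.pixel_size)


@dataclass
class RGBImage:
    """Linear-intensity color image with values in [0, 1].

    Parameters
    ----------
    values : ndarray of shape (H, W, 3)
        Per-channel intensities, dimensionless, in [0, 1].
    pixel_size : float
        Lateral sampling, µm per pixel.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"RGBImage requires an (H, W, 3) array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RGBImage values must be finite")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("RGBImage values must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "RGBImage":
        return RGBImage(self.values.copy(), self.pixel_size)
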