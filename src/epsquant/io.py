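"""Micrograph input and pixel-size calibration.

SEM micrographs arrive as 8- or 16-bit TIFF/PNG rasters, optionally RGB.
They are converted to grayscale, min-max normalized to [0, 1], and paired
with a microns-per-pixel scale looked up from an explicit JSON calibration
sidecar (``{"image_name.tif": pixels_per_micron, ...}``).  The scale for an
image is ``1 / pixels_per_micron[name]``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import imageio.v3 as iio

logger = logging.getLogger(__name__)

__all__ = [
    "Micrograph",
    "ScaleCalibration",
    "CalibrationError",
    "FormatError",
    "to_grayscale",
    "load_micrograph",
]

#: ITU-R 709 luma weights used to collapse RGB to a single channel.
_LUMA_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


class CalibrationError(KeyError):
    """Image name missing from the calibration table, or invalid scale."""


class FormatError(ValueError):
    """Raster layout not supported (not 2-D grayscale or 3-channel RGB)."""


@dataclass
class Micrograph:
    """A calibrated 2-D grayscale intensity field.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with intensities in [0, 1].
    name : str
        Image identifier (used for calibration lookup and reporting).
    scale : float or None
        Microns per pixel; ``None`` until calibrated.
    """

    pixels: np.ndarray
    name: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("Micrograph pixels must be a nonempty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Micrograph intensities must be finite")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("Micrograph intensities must lie in [0, 1]")
        if self.scale is not None and not self.scale > 0:
            raise CalibrationError("scale must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        """Image height M in pixels."""
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        """Image width N in pixels."""
        return self.pixels.shape[1]

    def require_scale(self) -> float:
        """Return the micron-per-pixel scale, failing loudly if uncalibrated."""
        if self.scale is None:
            raise CalibrationError(
                f"micrograph {self.name!r} has no pixel-size calibration"
            )
        return self.scale


@dataclass
class ScaleCalibration:
    """Pixels-per-micron lookup for a set of images.

    An unknown image name is an error, never a silent default.
    """

    pixels_per_micron: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.pixels_per_micron.items():
            if not (np.isfinite(value) and value > 0):
                raise CalibrationError(
                    f"pixels_per_micron for {name!r} must be strictly positive,"
                    f" got {value!r}"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleCalibration":
        with open(path) as fh:
            table = json.load(fh)
        return cls(pixels_per_micron={str(k): float(v) for k, v in table.items()})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(self.pixels_per_micron), fh, indent=2, sort_keys=True)

    def scale_for(self, name: str) -> float:
        """Microns per pixel for *name*: 1 / pixels_per_micron[name]."""
        try:
            ppm = self.pixels_per_micron[name]
        except KeyError:
            raise CalibrationError(
                f"image {name!r} has no entry in the calibration table"
            ) from None
        return 1.0 / ppm


def to_grayscale(raster: np.ndarray) -> np.ndarray:
    """Collapse an RGB raster to one channel; pass 2-D input through.

    3-channel input is combined with fixed luminance weights
    (0.2125, 0.7154, 0.0721).  Any other channel count is a format error.
    """
    raster = np.asarray(raster)
    if raster.ndim == 2:
        return raster
    if raster.ndim == 3 and raster.shape[-1] == 3:
        return raster.astype(float) @ _LUMA_WEIGHTS
    raise FormatError(
        f"expected a 2-D raster or 3-channel RGB, got shape {raster.shape}"
    )


def normalize_intensity(pixels: np.ndarray, name: str = "") -> np.ndarray:
    """Min-max normalize to [0, 1]; constant images map to all zeros."""
    pixels = np.asarray(pixels, dtype=float)
    lo = pixels.min()
    hi = pixels.max()
    if hi == lo:
        msg = f"image {name!r} has zero dynamic range; normalized to all zeros"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def load_micrograph(
    path: str | Path, calibration: ScaleCalibration | None = None
) -> Micrograph:
    """Read a TIFF/PNG micrograph, grayscale it, normalize, and calibrate.

    Parameters
    ----------
    path : path
        Single-channel or RGB raster, 8- or 16-bit.
    calibration : ScaleCalibration, optional
        When given, the file's basename must have an entry; the returned
        micrograph carries ``scale = 1 / pixels_per_micron[name]``.

    Returns
    -------
    Micrograph
        Intensities min-max normalized to [0, 1].
    """
    path = Path(path)
    raw = iio.imread(path)
    # Drop an alpha channel if present; 4-channel PNGs are common.
    if raw.ndim == 3 and raw.shape[-1] == 4:
        raw = raw[..., :3]
    gray = to_grayscale(raw)
    name = path.name
    scale = calibration.scale_for(name) if calibration is not None else None
    return Micrograph(
        pixels=normalize_intensity(gray, name=name), name=name, scale=scale
    )
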