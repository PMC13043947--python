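"""Color-space conversions shared by the normalization methods and metrics.

Two working spaces are used throughout the package:

* **Optical density (OD).**  By the Beer-Lambert law a pixel transmitting
  intensity ``I`` against incident light ``i0`` has per-channel density
  ``-log10(I / i0)``.  Stains absorb light independently, so their
  contributions add linearly in OD; this is what makes stain deconvolution
  a linear-algebra problem.

* **Ruderman lαβ.**  A decorrelated log-LMS space: RGB is mapped through a
  cone-response matrix to LMS, logged, and rotated onto a luminance axis
  ``l`` and two chroma axes ``α`` (yellow-blue) and ``β`` (red-green).
  Because the channels are nearly statistically independent for natural
  images, per-channel moment matching (the Reinhard transfer) is effective
  here.

Both spaces use base-10 logarithms so that histograms built from either are
on a consistent scale.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidImageError

__all__ = [
    "DEFAULT_I0",
    "OD_INTENSITY_FLOOR",
    "LMS_FLOOR",
    "rgb_to_od",
    "od_to_rgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "read_image",
    "write_image",
]

#: Reference white intensity for 8-bit rasters.
DEFAULT_I0 = 255.0

#: Intensity floor (in levels) applied before the OD logarithm so the map is
#: finite at pixel value 0.  Half a quantization level: integer pixel values
#: >= 1 are mapped exactly, and the floored value still rounds back to 0.
OD_INTENSITY_FLOOR = 0.5

#: Floor applied to LMS responses before the logarithm (RGB = 0 maps to
#: log10(1e-6) = -6 rather than -inf).
LMS_FLOOR = 1e-6

# Ruderman/Reinhard RGB->LMS coupling.  Rows are rescaled to unit sum so
# that achromatic pixels (R = G = B) produce exactly equal LMS responses and
# therefore alpha = beta = 0; the published constants only satisfy this to
# three decimals.
_M = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
RGB_TO_LMS = _M / _M.sum(axis=1, keepdims=True)
LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)

# Fixed orthogonal-scaling rotation from log-LMS to (l, alpha, beta).
LAB_FROM_LOGLMS = np.array(
    [
        [1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0)],
        [1.0 / np.sqrt(6.0), 1.0 / np.sqrt(6.0), -2.0 / np.sqrt(6.0)],
        [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
    ]
)
LOGLMS_FROM_LAB = np.linalg.inv(LAB_FROM_LOGLMS)


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 raster with values in [0, 255]; return float64 view."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(
            f"expected an H x W x 3 RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidImageError("image must have at least one pixel")
    arr = arr.astype(np.float64, copy=False)
    if not np.all(np.isfinite(arr)):
        raise InvalidImageError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 255.0:
        raise InvalidImageError("pixel values must lie in [0, 255]")
    return arr


def rgb_to_od(img: np.ndarray, i0: float = DEFAULT_I0) -> np.ndarray:
    """Convert an RGB image to optical density.

    ``od = -log10(max(v, floor) / i0)`` per channel, where the floor keeps
    the logarithm finite at 0.  The map is monotone decreasing in pixel
    value; a pixel equal to ``i0`` has density exactly 0.

    Parameters
    ----------
    img
        H x W x 3 raster with values in [0, 255] (integer or real valued).
    i0
        Incident (white) intensity, > 0.

    Returns
    -------
    H x W x 3 float array of nonnegative densities.
    """
    if not np.isscalar(i0) or not np.isfinite(i0) or i0 <= 0:
        raise InvalidImageError(f"i0 must be a positive real, got {i0!r}")
    arr = _validate_rgb(img)
    od = -np.log10(np.maximum(arr, OD_INTENSITY_FLOOR) / float(i0))
    # Values above i0 (possible when i0 < 255 is supplied) saturate at 0.
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, i0: float = DEFAULT_I0) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``clamp(round(i0 * 10**(-od)), 0, 255)``."""
    arr = np.asarray(od, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(
            f"expected an H x W x 3 OD array, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidImageError("OD contains non-finite values")
    if arr.min() < 0.0:
        raise InvalidImageError("OD must be nonnegative")
    pixels = np.rint(float(i0) * np.power(10.0, -arr))
    return np.clip(pixels, 0, 255).astype(np.uint8)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert RGB to Ruderman lαβ.

    Applies the cone-response matrix, takes ``log10`` of the (floored) LMS
    responses, and rotates onto the decorrelated axes.  Channel order in
    the returned H x W x 3 array is ``(l, alpha, beta)``.
    """
    arr = _validate_rgb(img)
    lms = arr @ RGB_TO_LMS.T
    loglms = np.log10(np.maximum(lms, LMS_FLOOR))
    return loglms @ LAB_FROM_LOGLMS.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Exact algebraic inverse of :func:`rgb_to_lab`, clamped to [0, 255]."""
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(
            f"expected an H x W x 3 lab array, got shape {arr.shape}"
        )
    loglms = arr @ LOGLMS_FROM_LAB.T
    lms = np.power(10.0, loglms)
    rgb = lms @ LMS_TO_RGB.T
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG or TIFF raster.

    Alpha channels and non-RGB rasters are rejected rather than silently
    converted, because the whole pipeline treats color values as physical
    transmittance measurements.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:
        raise InvalidImageError(
            f"{path}: image has an alpha channel; flatten it to RGB first"
        )
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InvalidImageError(
            f"{path}: expected an RGB raster, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise InvalidImageError(
            f"{path}: expected 8-bit samples, got dtype {arr.dtype}"
        )
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an 8-bit RGB raster; format inferred from the extension."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(_validate_rgb(arr)), 0, 255).astype(np.uint8)
    else:
        _validate_rgb(arr)
    iio.imwrite(Path(path), arr)
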