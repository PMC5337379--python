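"""Calibrated image I/O.

Raster images of dispersed powder carry no physical scale of their own, so
every image entering the pipeline is wrapped in a :class:`CalibratedImage`
that records the micrometres-per-pixel scale factor and the contrast
polarity of the acquisition device.  Flatbed scans show bright particles on
a dark background; SEM backscattered-electron (BSE) images show low-atomic-
number organic particles dark against a brighter mica substrate.  The
package works internally in a single canonical polarity (particles bright),
so BSE images are inverted on ingest by :func:`normalize_polarity`.

Scanner resolution in dots per inch maps to a scale factor via
``25400 / dpi`` μm per pixel (25.4 mm per inch).  SEM scale factors depend
on the instrument's magnification calibration and must be supplied
directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from os import PathLike

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Polarity",
    "CalibratedImage",
    "dpi_to_scale",
    "load_image",
    "save_image",
    "normalize_polarity",
]

MICRONS_PER_INCH = 25400.0


class Polarity(enum.Enum):
    """Which side of the intensity axis the particles occupy."""

    PARTICLES_BRIGHT = "bright"
    PARTICLES_DARK = "dark"


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D greyscale image with a physical scale attached.

    Parameters
    ----------
    pixels
        2-D intensity array, either 8-bit integers in [0, 255] or floats.
    scale
        Physical size of one pixel in micrometres; must be positive.
    polarity
        Whether particles are brighter or darker than the background.
    """

    pixels: np.ndarray
    scale: float
    polarity: Polarity = Polarity.PARTICLES_BRIGHT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(
                f"pixels must be a 2-D array of at least 2x2, got shape {px.shape}"
            )
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def dpi_to_scale(dpi: float) -> float:
    """Convert a scanner resolution in dots per inch to μm per pixel.

    ``dpi_to_scale(600)`` gives 42.33 μm/px, the scale of a standard
    600 dpi flatbed scan.
    """
    if not dpi > 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return MICRONS_PER_INCH / float(dpi)


def _to_grey(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to greyscale by channel averaging."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[:, :, :3]
        grey = rgb.mean(axis=2)
        if np.issubdtype(arr.dtype, np.integer):
            grey = np.rint(grey).astype(arr.dtype)
        return grey
    raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")


def load_image(
    path: str | PathLike,
    scale: float,
    polarity: Polarity = Polarity.PARTICLES_BRIGHT,
) -> CalibratedImage:
    """Read a TIFF/PNG/BMP raster and attach scale and polarity.

    RGB inputs are converted to greyscale by averaging the colour
    channels; greyscale inputs are passed through unchanged.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    arr = iio.imread(path)
    return CalibratedImage(_to_grey(np.asarray(arr)), float(scale), polarity)


def save_image(img: CalibratedImage, path: str | PathLike) -> None:
    """Write the pixel grid as an 8-bit greyscale raster (format by suffix)."""
    px = img.pixels
    if not np.issubdtype(px.dtype, np.integer):
        px = np.rint(np.clip(px, 0, 255))
    iio.imwrite(path, px.astype(np.uint8))


def normalize_polarity(img: CalibratedImage) -> CalibratedImage:
    """Return the image in canonical particles-bright polarity.

    Dark-particle (BSE) images are inverted, ``v -> max - v``: 255 - v for
    integer images, reflection about the value range for float images.
    Bright-particle images are returned unchanged.  The operation is an
    involution on dark-polarity 8-bit images.
    """
    if img.polarity is Polarity.PARTICLES_BRIGHT:
        return img
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer):
        inv = (255 - px.astype(np.int64)).astype(px.dtype)
    else:
        inv = (px.max() + px.min()) - px
    return replace(img, pixels=inv, polarity=Polarity.PARTICLES_BRIGHT)
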