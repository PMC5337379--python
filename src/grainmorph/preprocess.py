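"""Denoising, thresholding, hole filling and component labelling.

The segmentation front end: a Gaussian filter removes acquisition noise, a
single global Otsu threshold binarizes the whole frame (particles must
already be in the canonical bright polarity), interior holes caused by
intensity variation within large particles are filled according to a
depth criterion, and connected components below a minimum pixel area are
discarded as ultrafine debris.

Morphological erosion/dilation/opening/closing are deliberately absent:
they change particle size, which is not acceptable when the goal is
dimensional measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import CalibratedImage

__all__ = [
    "ParticleMask",
    "LabelMap",
    "gaussian_denoise",
    "otsu_threshold",
    "binarize",
    "fill_holes",
    "label_components",
    "area_filter",
]

# 8-connectivity for foreground, 4-connectivity for background holes: the
# complementary pair that avoids topological paradoxes on the pixel grid.
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)

DEFAULT_SIGMA = 1.0
DEFAULT_TAU_HOLE = 3.0
DEFAULT_MIN_AREA = 4


@dataclass(frozen=True)
class ParticleMask:
    """Binary foreground mask with the physical scale of its source image."""

    mask: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class LabelMap:
    """Integer-labelled particle map: 0 = background, 1..count = particles."""

    labels: np.ndarray
    count: int
    scale: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self) -> ParticleMask:
        return ParticleMask(self.labels > 0, self.scale)


def gaussian_denoise(img: CalibratedImage, sigma: float = DEFAULT_SIGMA) -> CalibratedImage:
    """Convolve with a normalized Gaussian kernel (reflective borders).

    ``sigma`` is in pixels; 0 is the identity.  Integer images are
    filtered in floating point and rounded back so the intensity range is
    preserved.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img
    px = img.pixels
    out = ndimage.gaussian_filter(px.astype(np.float64), sigma=sigma, mode="reflect")
    if np.issubdtype(px.dtype, np.integer):
        out = np.rint(out).astype(px.dtype)
    return CalibratedImage(out, img.scale, img.polarity)


def _histogram_256(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin intensity histogram plus the threshold value of each bin edge.

    8-bit images use the natural integer bins; real-valued images are
    linearly quantized onto 256 bins spanning their value range.  The
    returned ``edges[t]`` is the intensity threshold corresponding to
    splitting after bin ``t``.
    """
    if np.issubdtype(px.dtype, np.integer):
        vals = px.astype(np.int64).ravel()
        if vals.min() < 0 or vals.max() > 255:
            raise ValueError("integer images must be 8-bit (values in [0, 255])")
        hist = np.bincount(vals, minlength=256).astype(np.float64)
        edges = np.arange(256, dtype=np.float64)
        return hist, edges
    lo, hi = float(px.min()), float(px.max())
    q = np.clip(((px - lo) / (hi - lo) * 256.0).astype(np.int64), 0, 255)
    hist = np.bincount(q.ravel(), minlength=256).astype(np.float64)
    # threshold after bin t = upper edge of bin t in original units
    edges = lo + (np.arange(256, dtype=np.float64) + 1.0) * (hi - lo) / 256.0
    return hist, edges


def otsu_threshold(img: CalibratedImage) -> float:
    """Global threshold maximizing between-class variance (Otsu's method).

    The between-class variance ``w0*w1*(mu0 - mu1)**2`` is evaluated for
    every one of the 256 candidate split points of the intensity
    histogram; ties go to the smallest threshold.  Foreground is the class
    strictly above the returned value.
    """
    px = img.pixels
    if np.all(px == px.flat[0]):
        raise ValueError("constant image has no Otsu threshold")
    hist, edges = _histogram_256(px)
    total = hist.sum()
    p = hist / total
    bin_vals = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * bin_vals)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu / w0
        mu1 = (mu_total - mu) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=0.0)  # t = 255 leaves one class empty
    t_idx = int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer
    return float(edges[t_idx])


def binarize(img: CalibratedImage, threshold: float) -> ParticleMask:
    """Foreground mask of pixels strictly brighter than the threshold."""
    return ParticleMask(img.pixels > threshold, img.scale)


def fill_holes(pm: ParticleMask, tau_hole: float = DEFAULT_TAU_HOLE) -> ParticleMask:
    """Fill interior holes that sit deep inside their particle.

    A hole is a 4-connected background component not connected to the
    image border.  Holes are binarization artifacts when they lie well
    inside a particle, but near the particle edge they can be genuine
    concavities of the silhouette; the depth of a hole is therefore
    measured as the Euclidean distance from the hole to the nearest
    outer-boundary pixel of the enclosing particle, and only holes at
    depth >= ``tau_hole`` pixels are filled.  ``tau_hole = 0`` fills every
    hole (classical hole filling).  The output mask is a superset of the
    input and the operation is idempotent.
    """
    if tau_hole < 0:
        raise ValueError(f"tau_hole must be >= 0, got {tau_hole}")
    mask = pm.mask
    filled = ndimage.binary_fill_holes(mask, structure=_STRUCT4)
    holes = filled & ~mask
    if not holes.any():
        return pm
    if tau_hole == 0:
        return ParticleMask(filled, pm.scale)
    # outer boundary = filled-foreground pixels 8-adjacent to the exterior
    exterior = ~filled
    near_ext = ndimage.binary_dilation(exterior, structure=_STRUCT8)
    outer_boundary = filled & near_ext
    # distance from every pixel to the nearest outer-boundary pixel
    dist = ndimage.distance_transform_edt(~outer_boundary)
    hole_labels, n_holes = ndimage.label(holes, structure=_STRUCT4)
    out = mask.copy()
    if n_holes:
        # depth of a hole = distance of its closest pixel to the boundary
        depths = ndimage.minimum(dist, hole_labels, index=np.arange(1, n_holes + 1))
        for h, depth in zip(range(1, n_holes + 1), np.atleast_1d(depths)):
            if depth >= tau_hole:
                out[hole_labels == h] = True
    return ParticleMask(out, pm.scale)


def label_components(pm: ParticleMask) -> LabelMap:
    """8-connected component labelling of the foreground."""
    labels, count = ndimage.label(pm.mask, structure=_STRUCT8)
    return LabelMap(labels.astype(np.int32), int(count), pm.scale)


def area_filter(lm: LabelMap, min_area: int = DEFAULT_MIN_AREA) -> LabelMap:
    """Drop particles smaller than ``min_area`` pixels and relabel.

    The default of 4 pixels discards ultrafine debris below the reliable
    measurement limit.  Survivors are renumbered 1..count in raster-scan
    order of first occurrence.
    """
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    labels = lm.labels
    if lm.count == 0:
        return lm
    areas = np.bincount(labels.ravel(), minlength=lm.count + 1)
    keep = np.flatnonzero(areas[1:] >= min_area) + 1
    flat = labels.ravel()
    first_idx = np.full(lm.count + 1, flat.size, dtype=np.int64)
    # first occurrence of each label in raster order
    uniq, uidx = np.unique(flat, return_index=True)
    first_idx[uniq] = uidx
    keep = keep[np.argsort(first_idx[keep], kind="stable")]
    remap = np.zeros(lm.count + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelMap(remap[labels], int(keep.size), lm.scale)
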