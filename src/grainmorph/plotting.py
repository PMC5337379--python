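"""Optional static plots: labelled overlays and sorted distribution curves.

Everything here is presentation only; the CSV outputs are the canonical
artifacts and no analysis result depends on this module.
"""

from __future__ import annotations

from os import PathLike

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from skimage.color import label2rgb

from .calibration import CalibratedImage
from .distributions import distribution_curve
from .morphometry import ParticleMeasurement
from .preprocess import LabelMap

__all__ = ["save_overlay", "plot_distribution_curves"]


def save_overlay(
    image: CalibratedImage, lm: LabelMap, path: str | PathLike
) -> None:
    """Write a PNG of the image with each labelled particle tinted."""
    px = image.pixels.astype(np.float64)
    rng = px.max() - px.min()
    grey = (px - px.min()) / (rng if rng else 1.0)
    rgb = label2rgb(lm.labels, image=grey, bg_label=0, alpha=0.35)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_distribution_curves(
    measurements: list[ParticleMeasurement], path: str | PathLike
) -> None:
    """Sorted length/width/AR curves versus particle rank, one panel each."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, dim, unit in zip(axes, ("length", "width", "ar"), ("um", "um", "-")):
        curve = distribution_curve(measurements, dim)
        ax.plot(curve.ranks, curve.values, lw=1)
        if curve.semilog:
            ax.set_yscale("log")
        ax.set_xlabel("particle rank")
        ax.set_ylabel(f"{dim} [{unit}]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
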