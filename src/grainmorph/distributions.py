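"""Aggregation of per-particle measurements into summary statistics.

A sieved size class is summarized by the arithmetic means and sample
standard deviations of particle length, width and aspect ratio.  The mean
AR is the mean of the per-particle ratios — not the ratio of mean length
to mean width, which is a different (and biased) quantity.  Full
distributions are reported the empirical way: each dimension sorted
ascending against particle rank, which is how overlapping size classes
are compared on a semilog axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .morphometry import ParticleMeasurement

__all__ = [
    "SizeClassSummary",
    "DistributionCurve",
    "summarize",
    "distribution_curve",
    "mass_fraction_table",
    "subsample",
]


@dataclass(frozen=True)
class SizeClassSummary:
    """Mean +- SD of length, width and AR for one size class."""

    class_label: str
    n: int
    mean_length: float
    sd_length: float
    mean_width: float
    sd_width: float
    mean_ar: float
    sd_ar: float


@dataclass(frozen=True)
class DistributionCurve:
    """One dimension of all particles, sorted ascending vs. rank 1..n.

    ``semilog`` advises plotting the value axis on a log scale, which is
    the conventional display for particle size data spanning decades.
    """

    dimension: str
    ranks: np.ndarray
    values: np.ndarray
    semilog: bool = True


def _sd(x: np.ndarray) -> float:
    """Sample standard deviation (n-1); defined as 0 for a single value."""
    if x.size == 1:
        warnings.warn("standard deviation of a single particle reported as 0",
                      stacklevel=3)
        return 0.0
    return float(np.std(x, ddof=1))


def summarize(
    measurements: list[ParticleMeasurement], class_label: str = ""
) -> SizeClassSummary:
    """Summary statistics of one size class of particles."""
    if not measurements:
        raise ValueError("cannot summarize an empty measurement list")
    l = np.array([m.length_um for m in measurements])
    w = np.array([m.width_um for m in measurements])
    ar = np.array([m.aspect_ratio for m in measurements])
    return SizeClassSummary(
        class_label=class_label,
        n=len(measurements),
        mean_length=float(l.mean()),
        sd_length=_sd(l),
        mean_width=float(w.mean()),
        sd_width=_sd(w),
        mean_ar=float(ar.mean()),
        sd_ar=_sd(ar),
    )


_DIMENSIONS = {
    "length": lambda m: m.length_um,
    "width": lambda m: m.width_um,
    "ar": lambda m: m.aspect_ratio,
}


def distribution_curve(
    measurements: list[ParticleMeasurement], dimension: str
) -> DistributionCurve:
    """Sorted-ascending distribution of one dimension vs. particle rank."""
    if not measurements:
        raise ValueError("cannot build a distribution from an empty list")
    try:
        getter = _DIMENSIONS[dimension]
    except KeyError:
        raise ValueError(
            f"dimension must be one of {sorted(_DIMENSIONS)}, got {dimension!r}"
        ) from None
    values = np.sort(np.array([getter(m) for m in measurements]))
    ranks = np.arange(1, values.size + 1)
    return DistributionCurve(dimension, ranks, values, semilog=dimension != "ar")


def mass_fraction_table(
    class_masses: list[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Mass percentages of sieve classes; percentages sum to 100."""
    masses = np.array([m for _, m in class_masses], dtype=float)
    if (masses < 0).any():
        raise ValueError("masses must be non-negative")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    pct = masses / total * 100.0
    return [(label, float(p)) for (label, _), p in zip(class_masses, pct)]


def subsample(
    measurements: list[ParticleMeasurement], n: int, seed: int
) -> list[ParticleMeasurement]:
    """Seeded random subsample of ``n`` particles (all if fewer available)."""
    if n >= len(measurements):
        return list(measurements)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(measurements), size=n, replace=False))
    return [measurements[i] for i in idx]
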