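"""Synthetic powder scenes with exact ground truth.

No reference micrographs ship with this package, so every pipeline stage
is exercised on rendered scenes whose particle dimensions are known by
construction.  The generator emulates the two acquisition modes the
pipeline supports: flatbed-scanner contrast (bright particles, grey 200,
on a dark background, grey 60) and SEM backscattered-electron contrast
(dark organic particles on a brighter mica substrate — the same two grey
levels, swapped).  Contrast is uniform within a particle, which is
precisely what BSE imaging provides; secondary-electron edge halos are not
modelled.  Additive Gaussian noise with a seeded generator stands in for
detector noise.

Shapes are convex and elongated (rectangles, capsules, ellipses, discs)
with aspect ratios around 1-4, mimicking needle-like knife-milled straw
fragments.  Dispersed populations are placed by rejection sampling with a
minimum 5 px gap — the singulated arrangement of a well-prepared sample —
while touching-particle fixtures are constructed deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibratedImage, Polarity

__all__ = [
    "ShapeSpec",
    "SyntheticScene",
    "render_scene",
    "sample_population",
    "make_touching_pair",
    "make_touching_ellipse_pair",
]

BG_GREY = 200
FG_GREY = 60
MIN_GAP_PX = 5.0
_EPS = 1e-9

_KINDS = ("rectangle", "ellipse", "capsule", "disc")


@dataclass(frozen=True)
class ShapeSpec:
    """Ground truth for one rendered particle.

    ``center`` is (row, col); ``orientation`` is the major-axis direction
    in radians in the (x=col, y=-row) frame; ``true_length`` and
    ``true_width`` are the physical pixel extents the particle should
    measure as.
    """

    kind: str
    center: tuple[float, float]
    orientation: float
    true_length: float
    true_width: float
    grey: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (self.true_length >= self.true_width >= 1):
            raise ValueError(
                f"need true_length >= true_width >= 1, got "
                f"{self.true_length} x {self.true_width}"
            )


@dataclass
class SyntheticScene:
    """A rendered image together with the shapes that produced it."""

    image: CalibratedImage
    truth: list[ShapeSpec]
    touching_pairs: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0
    meta: dict = field(default_factory=dict)


def _shape_pixels(spec: ShapeSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixel centres covered by the shape."""
    l, w = spec.true_length, spec.true_width
    rc, cc = spec.center
    radius = np.hypot(l, w) / 2.0 + 1
    r0 = max(int(np.floor(rc - radius)), 0)
    r1 = min(int(np.ceil(rc + radius)) + 1, shape[0])
    c0 = max(int(np.floor(cc - radius)), 0)
    c1 = min(int(np.ceil(cc + radius)) + 1, shape[1])
    rr, cch = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x = cch - cc
    y = -(rr - rc)
    cos_t, sin_t = np.cos(spec.orientation), np.sin(spec.orientation)
    u = x * cos_t + y * sin_t
    v = -x * sin_t + y * cos_t
    # Flat-sided shapes sample pixel centres over the closed interval of
    # half-extent (l-1)/2, which is exact under the +1 px footprint model.
    # Curved shapes have no alignment phase to exploit, so they sample the
    # full continuous silhouette, whose covered-centre caliper extent is
    # l-1 on average — unbiased under the same footprint model.
    if spec.kind == "rectangle":
        inside = (np.abs(u) <= (l - 1) / 2.0 + _EPS) & (
            np.abs(v) <= (w - 1) / 2.0 + _EPS
        )
    elif spec.kind in ("ellipse", "disc"):
        a = max(l / 2.0, _EPS)
        b = max(w / 2.0, _EPS)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + _EPS
    else:  # capsule: rectangle body capped by half-discs
        body = max((l - w) / 2.0, 0.0)
        du = np.maximum(np.abs(u) - body, 0.0)
        inside = np.hypot(du, v) <= w / 2.0 + _EPS
    return rr[inside], cch[inside]


def render_scene(
    specs: list[ShapeSpec],
    size: tuple[int, int],
    polarity: Polarity = Polarity.PARTICLES_DARK,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> SyntheticScene:
    """Rasterize shapes onto a uniform background and add detector noise.

    ``polarity`` selects the contrast convention: ``PARTICLES_DARK``
    renders BSE-like scenes (particles grey 60 on background 200),
    ``PARTICLES_BRIGHT`` the scanner convention (greys swapped).  Noise is
    additive Gaussian, clipped to [0, 255]; identical seeds give
    bit-identical images.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    dark = polarity is Polarity.PARTICLES_DARK
    bg = BG_GREY if dark else FG_GREY
    fg_default = FG_GREY if dark else BG_GREY
    img = np.full(size, bg, dtype=np.float64)
    for spec in specs:
        l = spec.true_length
        rc, cc = spec.center
        radius = l / 2.0
        if (
            rc - radius < -0.5
            or cc - radius < -0.5
            or rc + radius > size[0] - 0.5
            or cc + radius > size[1] - 0.5
        ):
            raise ValueError(f"shape at {spec.center} does not fit in image {size}")
        rr, cch = _shape_pixels(spec, size)
        img[rr, cch] = fg_default if spec.grey is None else spec.grey
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=CalibratedImage(pixels, scale, polarity),
        truth=list(specs),
        seed=seed,
    )


def _segment_of(spec: ShapeSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Medial segment endpoints (in (x, y=-row)) and covering radius.

    The returned radius makes the capsule around the segment circumscribe
    the silhouette: curved kinds fit inside the w/2 capsule exactly, while
    a rectangle's corners reach w/sqrt(2) from the segment ends.
    """
    rc, cc = spec.center
    c = np.array([cc, -rc])
    d = np.array([np.cos(spec.orientation), np.sin(spec.orientation)])
    half = max((spec.true_length - spec.true_width) / 2.0, 0.0)
    radius = spec.true_width / 2.0
    if spec.kind == "rectangle":
        radius *= np.sqrt(2.0)
    return c - half * d, c + half * d, radius


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between two 2-D segments."""

    def point_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        return float(np.linalg.norm(p - (a + t * ab)))

    def ccw(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    # proper intersection => distance 0
    d1, d2 = ccw(p2, q2, p1), ccw(p2, q2, q1)
    d3, d4 = ccw(p1, q1, p2), ccw(p1, q1, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(
        point_seg(p1, p2, q2),
        point_seg(q1, p2, q2),
        point_seg(p2, p1, q1),
        point_seg(q2, p1, q1),
    )


def sample_population(
    n: int,
    length_range: tuple[float, float] = (20.0, 200.0),
    ar_range: tuple[float, float] = (1.0, 4.0),
    seed: int = 0,
    canvas: tuple[int, int] = (3072, 3072),
    kinds: tuple[str, ...] = ("rectangle", "capsule"),
    min_gap: float = MIN_GAP_PX,
    max_tries_per_shape: int = 500,
) -> list[ShapeSpec]:
    """Sample a dispersed, non-touching population of elongated shapes.

    Lengths are uniform over ``length_range`` (pixels) and aspect ratios
    uniform over ``ar_range``; widths follow as l/AR (floored at 3 px so
    every shape survives rasterization).  Placement is rejection sampling
    enforcing at least ``min_gap`` px between particle surfaces, i.e. a
    singulated arrangement.  Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length_range[0] > length_range[1] or ar_range[0] > ar_range[1]:
        raise ValueError("ranges must be (lo, hi) with lo <= hi")
    if ar_range[0] < 1:
        raise ValueError("aspect ratios below 1 are not defined")
    rng = np.random.default_rng(seed)
    placed: list[ShapeSpec] = []
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    for _ in range(n):
        # dimensions are drawn once per shape and never resampled, so the
        # length/AR distributions are exactly the requested uniforms;
        # rejection applies to the placement only
        l = float(rng.uniform(*length_range))
        ar = float(rng.uniform(*ar_range))
        w = min(max(l / ar, 3.0), l)
        kind = str(rng.choice(kinds))
        margin = l / 2.0 + 2.0
        if canvas[0] <= 2 * margin or canvas[1] <= 2 * margin:
            raise RuntimeError(f"canvas {canvas} too small for shapes of length {l:.0f}")
        for attempt in range(max_tries_per_shape):
            rc = float(rng.uniform(margin, canvas[0] - margin))
            cc = float(rng.uniform(margin, canvas[1] - margin))
            theta = float(rng.uniform(0.0, np.pi))
            spec = ShapeSpec(kind, (rc, cc), theta, l, w)
            p1, q1, hw1 = _segment_of(spec)
            if all(
                _segment_distance(p1, q1, p2, q2) >= hw1 + hw2 + min_gap
                for p2, q2, hw2 in segments
            ):
                placed.append(spec)
                segments.append((p1, q1, hw1))
                break
        else:
            raise RuntimeError(
                f"could not place shape {len(placed) + 1}/{n} after "
                f"{max_tries_per_shape} tries; use a larger canvas or "
                "fewer/smaller shapes"
            )
    return placed


def make_touching_pair(
    r1: float,
    r2: float,
    overlap_frac: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    polarity: Polarity = Polarity.PARTICLES_DARK,
) -> SyntheticScene:
    """Two discs merged at a neck: the canonical touching-particle fixture.

    Centre distance is ``(r1 + r2) * (1 - overlap_frac)``, so the discs
    interpenetrate slightly and render as one connected component.  The
    analytic neck width (the chord through the two boundary intersection
    points) is recorded in ``meta['neck_width_px']``.
    """
    if not 0 < overlap_frac < 0.5:
        raise ValueError(f"overlap_frac must be in (0, 0.5), got {overlap_frac}")
    rng = np.random.default_rng(seed)
    d = (r1 + r2) * (1.0 - overlap_frac)
    theta = float(rng.uniform(0.0, np.pi))
    extent = int(np.ceil(2 * max(r1, r2) + d)) + 24
    size = (extent, extent)
    mid = (extent / 2.0, extent / 2.0)
    dr, dc = -np.sin(theta), np.cos(theta)  # (row, col) step of direction theta
    c1 = (mid[0] - dr * d / 2.0, mid[1] - dc * d / 2.0)
    c2 = (mid[0] + dr * d / 2.0, mid[1] + dc * d / 2.0)
    specs = [
        ShapeSpec("disc", c1, 0.0, 2 * r1, 2 * r1),
        ShapeSpec("disc", c2, 0.0, 2 * r2, 2 * r2),
    ]
    scene = render_scene(specs, size, polarity, noise_sd, seed)
    scene.touching_pairs = [(0, 1)]
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    neck = 2.0 * float(np.sqrt(max(r1 * r1 - x1 * x1, 0.0)))
    scene.meta["neck_width_px"] = neck
    scene.meta["center_distance_px"] = d
    return scene


def make_touching_ellipse_pair(
    l1: float,
    w1: float,
    l2: float,
    w2: float,
    overlap_frac: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    polarity: Polarity = Polarity.PARTICLES_DARK,
) -> SyntheticScene:
    """Two coaxial ellipses touching tip to tip.

    The major axes share a random direction and the tips interpenetrate by
    ``overlap_frac`` of the smaller minor axis, mimicking agglomerated
    elongated grains.  Used by the separation benchmark.
    """
    if not 0 < overlap_frac < 0.5:
        raise ValueError(f"overlap_frac must be in (0, 0.5), got {overlap_frac}")
    rng = np.random.default_rng(seed)
    theta = float(rng.uniform(0.0, np.pi))
    ov = overlap_frac * min(w1, w2)
    d = (l1 + l2) / 2.0 - ov
    extent = int(np.ceil(l1 + l2 + max(w1, w2))) + 24
    size = (extent, extent)
    mid = (extent / 2.0, extent / 2.0)
    dr, dc = -np.sin(theta), np.cos(theta)
    c1 = (mid[0] - dr * d / 2.0, mid[1] - dc * d / 2.0)
    c2 = (mid[0] + dr * d / 2.0, mid[1] + dc * d / 2.0)
    specs = [
        ShapeSpec("ellipse", c1, theta, l1, w1),
        ShapeSpec("ellipse", c2, theta, l2, w2),
    ]
    scene = render_scene(specs, size, polarity, noise_sd, seed)
    scene.touching_pairs = [(0, 1)]
    scene.meta["overlap_px"] = ov
    return scene
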