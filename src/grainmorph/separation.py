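"""Separation of touching particles via boundary concavity (wedge) points.

Powder particles that touch in the image are labelled as one connected
component and would be measured as one oversized grain.  Where two convex
grains meet, the silhouette of their union has a pair of concave "wedge"
points — the re-entrant corners at either end of the contact neck.  This
module finds those points on the traced outline using a discrete k-cosine
curvature estimate, pairs them up, and cuts the component along the
straight chord between each pair.  Unlike erosion-based splitting, cutting
a one-pixel chord leaves the particle dimensions essentially untouched.

Pipeline per component: trace the outer contour (Moore neighbour tracing,
counter-clockwise), compute the k-cosine and a concave/convex flag at every
contour point, keep sharp concave points as wedge candidates (non-maximum
suppression within +-k contour steps), admit candidate pairs whose chord
stays inside the particle and is short relative to the particle size, and
greedily cut the shortest admissible chords.  The whole procedure repeats
on the newly created components until no admissible pair remains.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as bresenham_line

from .preprocess import LabelMap, ParticleMask, _STRUCT8

__all__ = [
    "Boundary",
    "WedgePair",
    "SeparationParams",
    "SplitReport",
    "trace_boundary",
    "curvature_kcos",
    "find_wedge_pairs",
    "split_particles",
]

logger = logging.getLogger(__name__)

# Moore neighbourhood in clockwise screen order (row axis points down).
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


@dataclass
class Boundary:
    """Closed outer contour of one particle.

    ``points`` is an (n, 2) array of (row, col) pixel coordinates ordered
    counter-clockwise (in the mathematical sense of the (x=col, y=-row)
    frame), starting at the topmost-then-leftmost pixel of the component.
    ``curvature`` and ``concave`` are filled by :func:`curvature_kcos`.
    """

    points: np.ndarray
    curvature: np.ndarray | None = None
    concave: np.ndarray | None = None
    k: int | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class WedgePair:
    """Two wedge-point indices into a contour and the chord length between them."""

    a: int
    b: int
    split_length: float


@dataclass(frozen=True)
class SeparationParams:
    """Tunable knobs of the wedge-point splitter.

    wedge_k
        Support offset of the k-cosine curvature estimate, in contour
        steps.  Small k is noisy; large k blurs nearby necks together.
    cos_min
        Sharpness floor for wedge candidates.  The k-cosine is +1 for a
        needle-sharp notch and -1 on a straight run, so ``cos_min`` bounds
        the admissible wedge opening angle from above.  Contact wedges
        between convex grains — even bluntly merged ones — read above
        about -0.8 on the k=5 chords, while the shallow staircase
        concavities of a rasterized convex outline read below -0.97; the
        default -0.85 sits between the two populations.
    max_split_frac
        Longest admissible chord as a fraction of the particle's
        equivalent-circle diameter; rules out cuts across the grain body.
    max_iter
        Cap on the split-and-relabel fixpoint iteration.
    """

    wedge_k: int = 5
    cos_min: float = -0.85
    max_split_frac: float = 0.6
    max_iter: int = 10


@dataclass
class SplitReport:
    """Bookkeeping from one :func:`split_particles` run."""

    n_pairs: int = 0
    removed_pixels: list[tuple[int, int]] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True


def _trace_mask_boundary(region: np.ndarray) -> np.ndarray:
    """Moore-neighbour contour trace of a single 8-connected component.

    ``region`` must be a boolean array with a one-pixel ``False`` border
    containing one component.  Returns the closed outer contour as (n, 2)
    coordinates in clockwise screen order, starting at the topmost-then-
    leftmost pixel; termination by Jacob's stopping criterion (the start
    pixel is re-entered from the same backtrack pixel).
    """
    rows, cols = np.nonzero(region)
    start = (int(rows[0]), int(cols[0]))  # raster order => topmost-then-leftmost
    if len(rows) == 1:
        return np.array([start])

    b0 = (start[0], start[1] - 1)  # west neighbour, background by construction
    contour = []
    p, b = start, b0
    seen: set = set()
    max_steps = 8 * len(rows) + 16
    for _ in range(max_steps):
        # the walk is a deterministic map on (pixel, backtrack) states, so
        # the first repeated state closes exactly one tour of the contour
        if (p, b) in seen:
            break
        seen.add((p, b))
        contour.append(p)
        i = _MOORE_INDEX[(b[0] - p[0], b[1] - p[1])]
        moved = False
        for j in range(1, 9):
            d = _MOORE[(i + j) % 8]
            c = (p[0] + d[0], p[1] + d[1])
            if region[c]:
                p = c
                moved = True
                break
            b = c  # last background pixel examined becomes the new backtrack
        if not moved:  # isolated pixel (cannot happen for len > 1)
            break
    return np.asarray(contour)


def _orient_ccw(points: np.ndarray) -> np.ndarray:
    """Reverse the contour if needed so traversal is counter-clockwise.

    Orientation is judged by the shoelace area in the (x=col, y=-row)
    frame; the start point is kept first.
    """
    if len(points) < 3:
        return points
    x = points[:, 1].astype(np.float64)
    y = -points[:, 0].astype(np.float64)
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        points = np.vstack([points[:1], points[1:][::-1]])
    return points


def trace_boundary(lm: LabelMap, label: int) -> Boundary:
    """Trace the closed outer contour of particle ``label``, counter-clockwise."""
    if label < 1 or label > lm.count:
        raise KeyError(f"label {label} not in map with count {lm.count}")
    objs = ndimage.find_objects(lm.labels, max_label=lm.count)
    sl = objs[label - 1]
    if sl is None:
        raise KeyError(f"label {label} has no pixels")
    region = np.pad(lm.labels[sl] == label, 1)
    offset = np.array([sl[0].start - 1, sl[1].start - 1])
    pts = _trace_mask_boundary(region) + offset
    return Boundary(_orient_ccw(pts))


def curvature_kcos(bd: Boundary, k: int = SeparationParams.wedge_k) -> Boundary:
    """Annotate a contour with k-cosine curvature and concavity flags.

    At point i the k-cosine is the cosine of the angle between the chords
    to the points k steps behind and k steps ahead (cyclic): +1 at a
    needle-sharp corner, -1 on a straight run.  A point is flagged concave
    when the traversal turns clockwise there (negative z cross product in
    the (x=col, y=-row) frame on a counter-clockwise contour), i.e. the
    corner re-enters the particle.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(bd.points)
    if n <= 2 * k:
        raise ValueError(f"boundary of length {n} too short for k={k}")
    pts = np.column_stack(
        [bd.points[:, 1].astype(np.float64), -bd.points[:, 0].astype(np.float64)]
    )
    back = np.roll(pts, k, axis=0) - pts  # p_{i-k} - p_i
    fwd = np.roll(pts, -k, axis=0) - pts  # p_{i+k} - p_i
    nb = np.linalg.norm(back, axis=1)
    nf = np.linalg.norm(fwd, axis=1)
    ok = (nb > 0) & (nf > 0)
    cosang = np.full(n, -1.0)
    np.divide(np.sum(back * fwd, axis=1), nb * nf, out=cosang, where=ok)
    cosang = np.clip(cosang, -1.0, 1.0)
    # turn direction: cross of (p_i - p_{i-k}) x (p_{i+k} - p_i)
    u, v = -back, fwd
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    concave = ok & (cross < 0)
    return Boundary(bd.points, curvature=cosang, concave=concave, k=k)


def _nms_candidates(bd: Boundary, cos_min: float) -> list[int]:
    """Sharp concave contour indices, non-maxima within +-k steps suppressed."""
    n = len(bd.points)
    k = bd.k
    cand = set(np.flatnonzero(bd.concave & (bd.curvature >= cos_min)).tolist())
    keep = []
    for i in sorted(cand):
        ci = bd.curvature[i]
        best = True
        for off in range(-k, k + 1):
            j = (i + off) % n
            if j == i or j not in cand:
                continue
            cj = bd.curvature[j]
            if cj > ci or (cj == ci and j < i):
                best = False
                break
        if best:
            keep.append(i)
    return keep


def find_wedge_pairs(
    bd: Boundary,
    mask: ParticleMask,
    cos_min: float = SeparationParams.cos_min,
    max_split_frac: float = SeparationParams.max_split_frac,
) -> list[WedgePair]:
    """Pair up wedge candidates into admissible split chords.

    ``mask`` must cover exactly the particle whose contour ``bd`` traces
    (its pixel sum is used as the particle area).  A pair is admissible
    when the two candidates are more than 2k contour steps apart, the
    Bresenham chord between them stays inside the particle, and the chord
    is no longer than ``max_split_frac`` times the particle's
    equivalent-circle diameter.  Admissible pairs are selected greedily by
    ascending chord length (true contact necks are the narrowest interior
    chords), each candidate used at most once.
    """
    if bd.curvature is None or bd.k is None:
        raise ValueError("curvature not computed; call curvature_kcos first")
    n = len(bd.points)
    k = bd.k
    cand = _nms_candidates(bd, cos_min)
    if len(cand) < 2:
        return []
    area = float(mask.mask.sum())
    max_len = max_split_frac * 2.0 * np.sqrt(area / np.pi)
    admissible: list[WedgePair] = []
    for a, b in itertools.combinations(cand, 2):
        sep = abs(a - b)
        if min(sep, n - sep) <= 2 * k:
            continue
        pa, pb = bd.points[a], bd.points[b]
        length = float(np.hypot(float(pa[0] - pb[0]), float(pa[1] - pb[1])))
        if length > max_len:
            continue
        rr, cc = bresenham_line(int(pa[0]), int(pa[1]), int(pb[0]), int(pb[1]))
        if not mask.mask[rr, cc].all():
            continue
        admissible.append(WedgePair(a, b, length))
    admissible.sort(key=lambda w: (w.split_length, w.a, w.b))
    used: set[int] = set()
    chosen = []
    for w in admissible:
        if w.a in used or w.b in used:
            continue
        chosen.append(w)
        used.update((w.a, w.b))
    return chosen


def _cut_component(
    region: np.ndarray, bd: Boundary, pairs: list[WedgePair]
) -> list[tuple[int, int]]:
    """Erase split chords from ``region`` in place; return the erased pixels.

    Chords are one pixel wide (Bresenham).  If the two halves remain one
    8-connected component because foreground leaks diagonally across a
    diagonal step of the chord, the chord is locally thickened into a
    4-connected background line, which 8-connected foreground cannot
    cross.  A cut that would erase the entire component is undone.
    """
    removed: list[tuple[int, int]] = []
    for w in pairs:
        pa, pb = bd.points[w.a], bd.points[w.b]
        n_before = int(ndimage.label(region, structure=_STRUCT8)[1])
        rr, cc = bresenham_line(int(pa[0]), int(pa[1]), int(pb[0]), int(pb[1]))
        was_fg = region[rr, cc].copy()
        region[rr, cc] = False
        removed_here = [
            (int(r), int(c)) for r, c, f in zip(rr, cc, was_fg) if f
        ]
        n_after = int(ndimage.label(region, structure=_STRUCT8)[1])
        if n_after <= n_before:
            extra = [
                (int(rr[i + 1]), int(cc[i]))
                for i in range(len(rr) - 1)
                if rr[i + 1] != rr[i] and cc[i + 1] != cc[i]
            ]
            for r, c in extra:
                if region[r, c]:
                    region[r, c] = False
                    removed_here.append((r, c))
        if not region.any():
            for r, c in removed_here:
                region[r, c] = True
            continue
        removed.extend(removed_here)
    return removed


def split_particles(
    lm: LabelMap,
    pm: ParticleMask,
    params: SeparationParams = SeparationParams(),
    return_report: bool = False,
) -> LabelMap | tuple[LabelMap, SplitReport]:
    """Split touching particles along wedge-pair chords, to a fixpoint.

    Each component's contour is searched for wedge pairs; every selected
    pair's chord is erased from the foreground and the map is relabelled.
    The procedure repeats on the new components until no admissible pair
    exists or ``max_iter`` is reached.  The particle count never
    decreases, and the only foreground pixels lost are the recorded split
    chord pixels.
    """
    mask = pm.mask.copy()
    labels = lm.labels
    count = lm.count
    report = SplitReport()
    for it in range(params.max_iter):
        report.iterations = it + 1
        any_split = False
        objs = ndimage.find_objects(labels, max_label=count)
        for k_label in range(1, count + 1):
            sl = objs[k_label - 1]
            if sl is None:
                continue
            region = np.pad(labels[sl] == k_label, 1)
            if region.sum() < 2 * params.wedge_k + 3:
                continue
            pts = _orient_ccw(_trace_mask_boundary(region))
            if len(pts) <= 2 * params.wedge_k:
                continue
            bd = curvature_kcos(Boundary(pts), params.wedge_k)
            pairs = find_wedge_pairs(
                bd, ParticleMask(region, pm.scale), params.cos_min, params.max_split_frac
            )
            if not pairs:
                continue
            removed = _cut_component(region, bd, pairs)
            if not removed:
                continue
            any_split = True
            report.n_pairs += len(pairs)
            off_r, off_c = sl[0].start - 1, sl[1].start - 1
            for r, c in removed:
                gr, gc = r + off_r, c + off_c
                mask[gr, gc] = False
                report.removed_pixels.append((gr, gc))
        if not any_split:
            break
        new_labels, count = ndimage.label(mask, structure=_STRUCT8)
        labels = new_labels.astype(np.int32)
    else:
        report.converged = False
        logger.warning(
            "split_particles hit max_iter=%d before convergence", params.max_iter
        )
    if report.n_pairs == 0:
        result = LabelMap(lm.labels, lm.count, lm.scale)
    else:
        result = LabelMap(labels, int(count), lm.scale)
    return (result, report) if return_report else result
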