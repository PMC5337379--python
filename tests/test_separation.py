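"""Boundary tracing, k-cosine curvature and wedge-point splitting."""

import numpy as np
import pytest

from grainmorph.calibration import normalize_polarity
from grainmorph.preprocess import (
    ParticleMask,
    area_filter,
    binarize,
    fill_holes,
    label_components,
    otsu_threshold,
)
from grainmorph.separation import (
    Boundary,
    SeparationParams,
    curvature_kcos,
    find_wedge_pairs,
    split_particles,
    trace_boundary,
)
from grainmorph.synth import make_touching_pair, ShapeSpec, render_scene


def _label(mask):
    return label_components(ParticleMask(np.asarray(mask, dtype=bool), 1.0))


def _scene_labels(scene, sigma=1.0):
    from grainmorph.preprocess import gaussian_denoise

    img = gaussian_denoise(normalize_polarity(scene.image), sigma)
    mask = fill_holes(binarize(img, otsu_threshold(img)), 3.0)
    return label_components(mask)


class TestTraceBoundary:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        bd = trace_boundary(_label(mask), 1)
        assert len(bd) == 1
        np.testing.assert_array_equal(bd.points, [[2, 3]])

    def test_filled_3x3_square(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        bd = trace_boundary(_label(mask), 1)
        assert len(bd) == 8
        # starts at topmost-then-leftmost pixel
        np.testing.assert_array_equal(bd.points[0], [2, 2])
        # closed: successive points (and last-to-first) are 8-adjacent
        diffs = np.abs(np.diff(np.vstack([bd.points, bd.points[:1]]), axis=0))
        assert (diffs.max(axis=1) == 1).all()
        # 4-edge boundary pixels of the square are exactly its 8 outer pixels
        assert {tuple(p) for p in bd.points} == {
            (r, c) for r in range(2, 5) for c in range(2, 5) if (r, c) != (3, 3)
        }

    def test_membership_oracle_on_random_blob(self):
        rng = np.random.default_rng(4)
        blob = rng.random((30, 30)) < 0.55
        lm = label_components(fill_holes(ParticleMask(blob, 1.0), 0.0))
        # pick the largest hole-free component
        areas = np.bincount(lm.labels.ravel())
        label = int(np.argmax(areas[1:]) + 1)
        bd = trace_boundary(lm, label)
        comp = lm.labels == label
        traced = {tuple(p) for p in bd.points}
        H, W = comp.shape
        for r, c in traced:
            neigh_bg = any(
                not (0 <= r + dr < H and 0 <= c + dc < W) or not comp[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            )
            assert comp[r, c] and neigh_bg
        # every foreground pixel with a background 4-neighbour is on the trace
        for r in range(H):
            for c in range(W):
                if not comp[r, c]:
                    continue
                edge4 = any(
                    not (0 <= r + dr < H and 0 <= c + dc < W) or not comp[r + dr, c + dc]
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                )
                if edge4:
                    assert (r, c) in traced

    def test_missing_label_raises(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(KeyError):
            trace_boundary(_label(mask), 2)


class TestCurvature:
    def test_disc_has_no_sharp_concavities(self):
        spec = ShapeSpec("disc", (25.0, 25.0), 0.0, 30, 30)
        lm = _scene_labels(render_scene([spec], (50, 50)))
        bd = curvature_kcos(trace_boundary(lm, 1), 5)
        # raster staircase produces shallow concave points (~ -1); none may
        # approach wedge sharpness
        if bd.concave.any():
            assert bd.curvature[bd.concave].max() < -0.9

    def test_straight_run_is_cos_minus_one(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        bd = curvature_kcos(trace_boundary(_label(mask), 1), 3)
        # a mid-edge point: support points collinear
        mid = next(
            i for i, p in enumerate(bd.points) if p[0] == 5 and 10 <= p[1] <= 18
        )
        assert bd.curvature[mid] == pytest.approx(-1.0)
        assert not bd.concave[mid]

    def test_too_short_boundary_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:4] = True
        bd = trace_boundary(_label(mask), 1)
        with pytest.raises(ValueError):
            curvature_kcos(bd, 5)

    def test_dumbbell_neck_carries_maximal_concave_curvature(self):
        scene = make_touching_pair(15, 15, 0.2, seed=1)
        lm = _scene_labels(scene)
        assert lm.count == 1
        bd = curvature_kcos(trace_boundary(lm, 1), 5)
        conc = np.flatnonzero(bd.concave)
        assert len(conc) >= 2
        # the two sharpest concave points must lie on the neck chord: their
        # distance equals the analytic neck width within 2 px
        best = conc[np.argsort(bd.curvature[conc])][-2:]
        p, q = bd.points[best[0]], bd.points[best[1]]
        dist = float(np.hypot(*(p - q).astype(float)))
        assert dist == pytest.approx(scene.meta["neck_width_px"], abs=2.0)


class TestFindWedgePairs:
    def test_convex_particle_has_no_pairs(self):
        spec = ShapeSpec("rectangle", (20.5, 30.5), 0.3, 40, 14)
        lm = _scene_labels(render_scene([spec], (42, 62)))
        bd = curvature_kcos(trace_boundary(lm, 1), 5)
        assert find_wedge_pairs(bd, lm.mask()) == []

    def test_dumbbell_yields_one_neck_pair(self):
        scene = make_touching_pair(15, 15, 0.2, seed=1)
        lm = _scene_labels(scene)
        bd = curvature_kcos(trace_boundary(lm, 1), 5)
        pairs = find_wedge_pairs(bd, lm.mask())
        assert len(pairs) == 1
        assert pairs[0].split_length == pytest.approx(
            scene.meta["neck_width_px"], abs=2.0
        )

    def test_three_disc_chain_yields_two_pairs(self):
        r, f = 15.0, 0.2
        d = 2 * r * (1 - f)
        centers = [(40.0, 40.0 + i * d) for i in range(3)]
        specs = [ShapeSpec("disc", c, 0.0, 2 * r, 2 * r) for c in centers]
        scene = render_scene(specs, (80, int(80 + 2 * d)))
        lm = _scene_labels(scene)
        assert lm.count == 1
        bd = curvature_kcos(trace_boundary(lm, 1), 5)
        pairs = find_wedge_pairs(bd, lm.mask())
        assert len(pairs) == 2


class TestSplitParticles:
    def test_isolated_convex_particles_unchanged(self):
        specs = [
            ShapeSpec("rectangle", (20.5, 25.5), 0.0, 30, 10),
            ShapeSpec("ellipse", (60.0, 60.0), 1.0, 36, 14),
        ]
        lm = _scene_labels(render_scene(specs, (100, 100)))
        assert lm.count == 2
        out, rep = split_particles(lm, lm.mask(), return_report=True)
        assert out.count == 2
        assert rep.n_pairs == 0
        np.testing.assert_array_equal(out.labels, lm.labels)

    def test_dumbbell_splits_one_into_two(self):
        scene = make_touching_pair(15, 15, 0.2, seed=2)
        lm = _scene_labels(scene)
        assert lm.count == 1
        out = split_particles(lm, lm.mask())
        assert out.count == 2

    def test_foreground_deficit_equals_recorded_split_pixels(self):
        scene = make_touching_pair(15, 12, 0.25, seed=3)
        lm = _scene_labels(scene)
        before = int((lm.labels > 0).sum())
        out, rep = split_particles(lm, lm.mask(), return_report=True)
        after = int((out.labels > 0).sum())
        assert before - after == len(rep.removed_pixels)
        assert len(set(rep.removed_pixels)) == len(rep.removed_pixels)
        # bound: each pair erases at most a thickened Bresenham chord
        if rep.n_pairs:
            max_len = max(
                np.hypot(15 + 12, 15 + 12), 1
            )  # generous geometric bound for this scene
            assert len(rep.removed_pixels) <= rep.n_pairs * 2 * (max_len + 1)

    def test_count_never_decreases(self):
        rng = np.random.default_rng(8)
        for seed in rng.integers(0, 2**31 - 1, size=5):
            scene = make_touching_pair(
                float(rng.uniform(10, 18)),
                float(rng.uniform(10, 18)),
                float(rng.uniform(0.05, 0.35)),
                seed=int(seed),
            )
            lm = _scene_labels(scene)
            out = split_particles(lm, lm.mask())
            assert out.count >= lm.count

    def test_no_component_below_min_area_after_refilter(self):
        scene = make_touching_pair(15, 15, 0.2, seed=4)
        lm = _scene_labels(scene)
        out = area_filter(split_particles(lm, lm.mask()), 4)
        areas = np.bincount(out.labels.ravel())[1:]
        assert (areas >= 4).all()


def test_touching_ellipse_pair_recovery_rate():
    """>= 90% of random touching ellipse pairs resolve into exactly two
    particles with dimensions within 3 px of ground truth."""
    from grainmorph.pipeline import run_synth_benchmark

    rep = run_synth_benchmark(kind="touching_pairs", n_scenes=50, seed=7)
    assert rep["resolved_to_two"] >= 45
    assert rep["success_rate"] >= 0.9
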