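"""Shared fixtures: heavy synthetic scenes are rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from grainmorph.calibration import Polarity
from grainmorph.pipeline import PipelineConfig, canvas_for, run_pipeline
from grainmorph.synth import render_scene, sample_population

POPULATION_SEED = 42
POPULATION_N = 300


@pytest.fixture(scope="session")
def bse_config() -> PipelineConfig:
    return PipelineConfig(polarity=Polarity.PARTICLES_DARK)


def _render_population(noise_sd: float):
    specs = sample_population(POPULATION_N, seed=POPULATION_SEED)
    scene = render_scene(
        specs,
        canvas_for(specs),
        Polarity.PARTICLES_DARK,
        noise_sd=noise_sd,
        seed=POPULATION_SEED,
    )
    return specs, scene


@pytest.fixture(scope="session")
def population_clean(bse_config):
    """300 dispersed rectangles/capsules, noise-free, plus pipeline output."""
    specs, scene = _render_population(0.0)
    result = run_pipeline(scene.image, bse_config)
    return specs, scene, result


@pytest.fixture(scope="session")
def population_noisy(bse_config):
    """Same population rendered with additive Gaussian noise, sd 10 grey."""
    specs, scene = _render_population(10.0)
    result = run_pipeline(scene.image, bse_config)
    return specs, scene, result


def recovery_errors(specs, result, scale: float) -> np.ndarray:
    """Per-particle worst-dimension |measured - true| in pixels."""
    from grainmorph.pipeline import match_to_truth

    matched = match_to_truth(result.label_map, result.measurements, specs)
    return np.array(
        [
            max(
                abs(m.length_um / scale - s.true_length),
                abs(m.width_um / scale - s.true_width),
            )
            for s, m in matched
        ]
    )
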