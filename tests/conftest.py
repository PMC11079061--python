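"""Shared fixtures: deterministic RNGs and small synthetic scenes."""

import numpy as np
import pytest

from dielniche.synthetic import (
    ARCHETYPES, SceneSpec, SpeciesSpec, default_scene_spec, shift_mixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160322)


@pytest.fixture
def small_scene_spec():
    """Three-species scene at reduced event scale, for fast pipeline tests."""
    arch = ARCHETYPES
    species = [
        SpeciesSpec("nightjar_deer", arch["nocturnal"],
                    shift_mixture(arch["nocturnal"], 0.1), 40, 40),
        SpeciesSpec("dawnrunner", arch["crepuscular"],
                    shift_mixture(arch["crepuscular"], 0.2), 60, 60),
        SpeciesSpec("noon_sheep", arch["diurnal"],
                    shift_mixture(arch["diurnal"], 0.8), 45, 45),
    ]
    return SceneSpec(species=species, n_sites=20)


@pytest.fixture(scope="session")
def demo_scene():
    """The packaged six-species demo scene, generated once per session."""
    from dielniche.synthetic import generate_scene

    spec = default_scene_spec()
    frame, truth = generate_scene(spec, np.random.default_rng(11))
    return spec, frame, truth
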