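"""Shared fixtures: small, quickly-rendered synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from spermorph.synth import GeometryRanges, SceneSpec, make_scene

#: thick-part ranges used for desk-scale scenes, so that every part is
#: several pixels wide at pixel sizes around 0.2 um/px
THICK_RANGES = GeometryRanges(
    tail_width_um=(0.9, 1.1),
    mid_width_um=(0.7, 0.9),
    tail_length_um=(12.0, 16.0),
)


def tiny_scene_spec(seed: int, **overrides) -> SceneSpec:
    kwargs = dict(width=144, height=112, count_range=(2, 2), pixel_size_um=0.2,
                  blur_sigma_px=0.8, noise_sd=0.01, seed=seed, ranges=THICK_RANGES)
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Four small two-sperm scenes with thick parts (desk-scale training set)."""
    return [make_scene(tiny_scene_spec(seed)) for seed in range(4)]


@pytest.fixture(scope="session")
def single_sperm_scene():
    spec = SceneSpec(width=420, height=420, count_range=(1, 1), pixel_size_um=0.2,
                     blur_sigma_px=0.0, noise_sd=0.0, seed=11, ranges=THICK_RANGES)
    return make_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
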