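"""Shared fixtures: small phantom configs and rendered samples."""

from __future__ import annotations

import numpy as np
import pytest

from shrapod import PhantomConfig, generate_phantom
from shrapod.model import ArchSpec, TrainConfig
from shrapod.synth.phantom import render_phantom


def tiny_phantom_config(**kwargs) -> PhantomConfig:
    """A 96 px profile small enough for fast network tests."""
    defaults = dict(image_size=96, px_per_mm=2.0, rng_seed=123)
    defaults.update(kwargs)
    return PhantomConfig(**defaults)


def tiny_arch(**kwargs) -> ArchSpec:
    defaults = dict(input_size=96, width=0.1)
    defaults.update(kwargs)
    return ArchSpec(**defaults)


@pytest.fixture(scope="session")
def desk_config() -> PhantomConfig:
    return PhantomConfig.desk(rng_seed=7)


@pytest.fixture(scope="session")
def desk_image(desk_config):
    return generate_phantom(desk_config, 0)


@pytest.fixture(scope="session")
def desk_render(desk_config):
    """(pixels, boxes, masks, meta) of one deterministic desk frame."""
    rng = np.random.default_rng(np.random.SeedSequence([desk_config.rng_seed, 0]))
    return render_phantom(desk_config, rng)


@pytest.fixture(scope="session")
def tiny_images():
    cfg = tiny_phantom_config()
    return [generate_phantom(cfg, i) for i in range(8)]
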