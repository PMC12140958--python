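"""Shared fixtures: a desk-scale phantom configuration and cached cine loops.

The "fast" configuration keeps the benchtop geometry (50-mm sac, 2.5-mm
wall) but renders fewer, coarser frames so unit tests that exercise
tracking stay quick; tests of full-accuracy behavior build their own loops.
"""

from __future__ import annotations

import numpy as np
import pytest

from wallstrain import (
    PhantomConfig,
    build_mesh,
    generate_cine,
    synthetic_contours,
)

try:  # keep hypothesis-based property tests reproducible
    from hypothesis import settings

    settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def fast_config() -> PhantomConfig:
    return PhantomConfig(
        frames_per_cycle=16,
        image_size=128,
        pixel_spacing=0.5,
        scatterer_density=30.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def fast_cine(fast_config):
    return generate_cine(fast_config)


@pytest.fixture(scope="session")
def fast_mesh(fast_config):
    inner, outer = synthetic_contours(fast_config)
    return build_mesh(inner, outer, target_edge=1.25)
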