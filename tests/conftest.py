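"""Shared fixtures: simulated scenes reused across the suite.

All fixtures are deterministic (fixed seeds) and generated in memory at test
time by the package's own simulator.
"""

from __future__ import annotations

import numpy as np
import pytest

import sonoqa as sq


@pytest.fixture(scope="session")
def identity_lut() -> sq.GrayMapLUT:
    return sq.GrayMapLUT.identity()


@pytest.fixture(scope="session")
def contrast_scene():
    """Default contrast phantom scene: image, ground truth, phantom model."""
    cfg = sq.default_contrast_config()
    image, truth = sq.simulate_gel_image(cfg, seed=11)
    return cfg, image, truth, sq.phantom_model_for(cfg)


@pytest.fixture(scope="session")
def dop_pair():
    cfg = sq.default_dop_config()
    gel, truth = sq.simulate_gel_image(cfg, seed=21)
    air = sq.simulate_air_image(cfg, seed=22)
    return cfg, gel, air, truth


@pytest.fixture(scope="session")
def resolution_scene():
    cfg = sq.default_resolution_config()
    image, truth = sq.simulate_gel_image(cfg, seed=31)
    return cfg, image, truth, sq.phantom_model_for(cfg)


@pytest.fixture(scope="session")
def resolution_calibration(resolution_scene):
    cfg = resolution_scene[0]
    return sq.ContrastResponseResult(
        slope=cfg.compression_slope, intercept=0.0, r_squared=1.0, per_target=[]
    )


@pytest.fixture()
def flat_image():
    """Uniform mid-gray image with plausible spacing."""

    def make(value: int = 100, shape=(64, 64), **kwargs) -> sq.BModeImage:
        return sq.BModeImage(
            pixels=np.full(shape, value, dtype=np.int64),
            axial_spacing=kwargs.pop("axial_spacing", 0.1),
            lateral_spacing=kwargs.pop("lateral_spacing", 0.1),
            **kwargs,
        )

    return make
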