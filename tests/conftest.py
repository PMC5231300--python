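"""Shared fixtures: desk-scale phantom configurations and processed volumes.

Unit tests run on a reduced 300 x 64 x 64 grid (same pitches and layer stack
as the default phantom, smaller field sampling) so the whole suite stays fast;
the acceptance tests use the full default geometry.
"""

import dataclasses

import numpy as np
import pytest

import psoct_iop as P
from psoct_iop.phantom import ONHConfig, default_geometry


def make_small_config(**overrides) -> P.PhantomConfig:
    cfg = P.PhantomConfig(geometry=default_geometry(300, 64, 64))
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_cfg() -> P.PhantomConfig:
    return make_small_config()


@pytest.fixture(scope="session")
def clean_cfg(small_cfg) -> P.PhantomConfig:
    """Speckle-free but with the additive noise floor (deterministic signal)."""
    return dataclasses.replace(
        small_cfg, noise=P.NoiseConfig(speckle=False, include_floor=True)
    )


@pytest.fixture(scope="session")
def flat_noiseless_cfg(small_cfg) -> P.PhantomConfig:
    """Strictly noiseless, flat ILM (no pit/canal), integer-aligned surfaces."""
    return dataclasses.replace(
        small_cfg.noiseless(), onh=ONHConfig(pit_depth_um=0.0, canal_radius_um=1e-9)
    )


@pytest.fixture(scope="session")
def speckled_vol(small_cfg):
    return P.generate_volume(small_cfg, 95, seed=1)


@pytest.fixture(scope="session")
def clean_vol(clean_cfg):
    return P.generate_volume(clean_cfg, 95, seed=0)


@pytest.fixture(scope="session")
def processed_speckled(speckled_vol):
    vol, truth = speckled_vol
    return P.process_volume(vol, None, None), truth


@pytest.fixture(scope="session")
def processed_clean(clean_vol):
    vol, truth = clean_vol
    return P.process_volume(vol, None, None), truth
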