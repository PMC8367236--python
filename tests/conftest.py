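"""Shared fixtures: small phantoms sized for fast tests.

The small geometry keeps the 8 x 6 mm retinal field of the full phantom but
samples it coarsely, so pixel pitches (and hence lesion pixel counts) scale
accordingly.
"""

from __future__ import annotations

import numpy as np
import pytest

from psoctfib import ScanGeometry
from psoctfib.phantom import (
    PhantomSpec,
    LesionPatch,
    RpeSpec,
    generate_phantom,
)

SMALL_GEOMETRY = ScanGeometry(nx=96, ny=32, nz=320)


def make_small_spec(**overrides) -> PhantomSpec:
    base = dict(
        geometry=SMALL_GEOMETRY,
        z_ilm_px=40,
        z_reference_px=150,
        lesions=(LesionPatch(radius_mm=1.2),),
        rpe=RpeSpec(offset_px=45, thickness_px=12),
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return make_small_spec()


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """Default small phantom: one lesion, speckle and noise on."""
    return generate_phantom(small_spec, seed=7)


@pytest.fixture(scope="session")
def clean_cornea_lesion_phantom():
    """Noise-free phantom: cornea + lesion only (no RNFL/HFL/RPE/speckle).

    Single-layer anterior stack, so single-step compensation is exact and
    posterior retarder parameters are recovered to numerical precision.
    """
    spec = make_small_spec(
        rnfl=None, hfl=None, rpe=None, speckle=False, noise_std=0.0
    )
    return generate_phantom(spec, seed=3)


@pytest.fixture(scope="session")
def clean_two_layer_phantom():
    """Noise-free phantom with cornea + HFL over a lesion (no RNFL/RPE)."""
    spec = make_small_spec(rnfl=None, rpe=None, speckle=False, noise_std=0.0)
    return generate_phantom(spec, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
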