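"""Shared fixtures: small cohorts, a fitted copula, desk-scale phantoms and a calibration.

Everything is generated programmatically at test time with fixed seeds;
session scope amortizes the expensive fits and noise-field builds.
"""

from __future__ import annotations

import numpy as np
import pytest

from breastvit.cohort import FixtureSpec, generate_cohort_frame
from breastvit.phantom import PhantomSpec, build_phantom
from breastvit.population import fit_copula
from breastvit.texture import calibrate_density

#: small grid used throughout the unit tests (2 mm voxels keep builds ~1 s)
SMALL_SHAPE = (110, 60, 30)
SMALL_VOXEL_MM = 2.0
SF_LEVELS = (0.93, 0.96, 0.99, 1.02, 1.05)


@pytest.fixture(scope="session")
def cohort_frame():
    """Synthetic cohort of 4000 women from the published copula parameters."""
    return generate_cohort_frame(FixtureSpec(n=4000, seed=2024))


@pytest.fixture(scope="session")
def fitted(cohort_frame):
    """t-copula fitted to the session cohort."""
    return fit_copula(cohort_frame)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=SMALL_SHAPE, voxel_mm=SMALL_VOXEL_MM, volume_cm3=500.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec, seed=42)


@pytest.fixture(scope="session")
def calibration(small_spec):
    """SF→VBD calibration on the small grid (5 levels, 3 seeds per level)."""
    return calibrate_density(small_spec, SF_LEVELS, n_phantoms=3, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
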