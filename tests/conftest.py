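"""Shared fixtures: small phantoms reused across the suite.

All fixtures are generated programmatically; grids are kept small (short cord
lengths at the native voxel spacing) so the suite runs quickly while every
geometric quantity stays in physical mm units.
"""

import numpy as np
import pytest

from cordseg.io import gradient_magnitude
from cordseg.phantom import (CenterlineParams, PhantomConfig,
                             RootletArtifacts, generate_phantom)
from cordseg.profiles import build_template_db


def clean_cylinder_config(radius=4.2, nz=80, seed=7):
    """Straight, noise-free, artifact-free constant-radius phantom."""
    L = (nz - 1) * 0.3
    return PhantomConfig(
        grid_shape=(63, 63, nz),
        centerline_params=CenterlineParams(amplitude_mm=0.0),
        radius_profile=((0.0, radius), (L, radius)),
        noise_sd=0.0,
        rootlet_artifacts=RootletArtifacts(count=0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_case():
    return generate_phantom(clean_cylinder_config())


@pytest.fixture(scope="session")
def clean_grad(clean_case):
    return gradient_magnitude(clean_case.volume)


@pytest.fixture(scope="session")
def clean_db(clean_case, clean_grad):
    return build_template_db(clean_grad, clean_case.truth_mask,
                             subject_id="clean")


@pytest.fixture(scope="session")
def curved_case():
    """Curved, noisy phantom with rootlet streaks: the realistic condition."""
    cfg = PhantomConfig(
        grid_shape=(63, 63, 80),
        centerline_params=CenterlineParams(amplitude_mm=1.5,
                                           wavelength_mm=60.0),
        radius_profile=((0.0, 3.9), (12.0, 4.5), (23.7, 4.0)),
        seed=11,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
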