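"""Shared fixtures: all inputs are generated, nothing is read from disk."""

import logging

import numpy as np
import pytest

import retispec as r
from retispec.calibration import PolynomialExpansion, expand
from retispec.core import Colorimetry

logging.getLogger("retispec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid():
    return r.default_grid()


@pytest.fixture(scope="session")
def cam(grid):
    return r.default_camera(grid, noise_sd=0.01, seed=1)


@pytest.fixture(scope="session")
def noise_free_cam(grid):
    return r.default_camera(grid, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def patches(grid, cam):
    return r.photograph_patches(r.make_colorchecker(grid, seed=1), cam)


@pytest.fixture(scope="session")
def clean_patches(grid, noise_free_cam):
    return r.photograph_patches(r.make_colorchecker(grid, seed=1), noise_free_cam)


@pytest.fixture(scope="session")
def model(patches):
    return r.fit_calibration(patches, k=12)


@pytest.fixture(scope="session")
def exact_patches(grid):
    """Patch set whose reference XYZ is exactly an order-3 polynomial of
    the (linear) camera triplet: the exactly representable oracle system."""
    rng = np.random.default_rng(7)
    exp3 = PolynomialExpansion(order=3)
    rgb_linear = rng.uniform(0.05, 0.95, size=(24, 3))
    M_true = rng.normal(0.0, 0.3, size=(3, exp3.n_terms))
    xyz = expand(rgb_linear, exp3) @ M_true.T
    refl = rng.uniform(0.0, 1.0, size=(24, grid.n_bands))
    patch = r.ColorPatchSet(reflectance=refl, reference_xyz=xyz, grid=grid,
                            colorimetry=Colorimetry(grid=grid), rgb=rgb_linear)
    return patch, M_true


@pytest.fixture(scope="session")
def small_phantom(cam):
    return r.make_phantom("Dementia", "D001", "OD", cam=cam, seed=3, size=64)


@pytest.fixture(scope="session")
def tiny_cohort():
    return r.make_cohort({g: (6, 12) for g in r.GROUPS}, seed=2)
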