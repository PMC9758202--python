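"""Shared fixtures: canonical parameter sets and cached model curves."""

import numpy as np
import pytest

from mochafrap import theory

# Boundary strength (h*R = 0.44465) whose half-bleach dip is 0.300; solved
# once from the series by bisection and used as the programmed ground truth
# of the synthetic-data round trips.
Q_DIP_030 = 0.4446479388545468


@pytest.fixture(scope="session")
def llps_params_dip030():
    """Semi-permeable circle with a programmed dip depth of 0.30."""
    R = 2.0
    return theory.LLPSModelParams(R=R, D_app=0.05, h=Q_DIP_030 / R)


@pytest.fixture(scope="session")
def free_params():
    return theory.FreeDiffusionParams(R_C=1.0, R_L=6.0, D_app=1.0)


@pytest.fixture(scope="session")
def free_curve(free_params):
    return theory.free_diffusion_curves(free_params)


@pytest.fixture(scope="session")
def llps_curve_dip030(llps_params_dip030):
    return theory.llps_curves(llps_params_dip030)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
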