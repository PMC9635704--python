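import numpy as np
import pytest

from fractcm import (
    DoseSchedule,
    ErlangTCMParameters,
    FractionalTCMParameters,
    GrowthParameters,
    MLDelayParameters,
    PKParameters,
    SolverConfig,
    scaled_concentration,
    solve_pk,
)

# reference study values: growth, PK, dosing, and the two fitted models
FITTED_ERLANG = dict(eta=0.37847, k1=0.54379, n=4)
FITTED_FRACTIONAL = dict(alpha=0.945, eta=0.24657, tau=3.6852)


@pytest.fixture(scope="session")
def growth():
    return GrowthParameters()


@pytest.fixture(scope="session")
def pk_params():
    return PKParameters()


@pytest.fixture(scope="session")
def doses():
    return DoseSchedule.daily(10, 4.5e7, 13.0)


@pytest.fixture(scope="session")
def concentration(pk_params, doses):
    """Paper-regimen plasma concentration in PD units (C/1e4)."""
    return scaled_concentration(solve_pk(pk_params, doses))


@pytest.fixture(scope="session")
def erlang_params(growth):
    return ErlangTCMParameters(growth=growth, **FITTED_ERLANG)


@pytest.fixture(scope="session")
def fractional_params(growth):
    f = FITTED_FRACTIONAL
    return FractionalTCMParameters(
        growth=growth, eta=f["eta"],
        delay=MLDelayParameters(f["alpha"], f["tau"]))


@pytest.fixture(scope="session")
def cfg_coarse():
    """Coarse grid for cheap unit tests (accuracy checked elsewhere)."""
    return SolverConfig(t_start=0.0, t_end=60.0, step=2.0**-5)


@pytest.fixture(scope="session")
def cfg_paper():
    """The reference grid: h = 2^-8 over the 60-day study window."""
    return SolverConfig(t_start=0.0, t_end=60.0, step=2.0**-8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
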