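import numpy as np
import pytest

import pulselv as pl
from pulselv import cli_io, densities, gfpk


@pytest.fixture(scope="session")
def fig1_params():
    cfg = cli_io.load_config(cli_io.fixture_path("fig1"))
    return cli_io.params_from_config(cfg)


@pytest.fixture(scope="session")
def fig2_config():
    return cli_io.load_config(cli_io.fixture_path("fig2"))


@pytest.fixture(scope="session")
def fig2_params(fig2_config):
    return cli_io.params_from_config(fig2_config)


@pytest.fixture(scope="session")
def fig2_noise(fig2_config):
    return cli_io.noise_from_config(fig2_config)


@pytest.fixture(scope="session")
def fig2_coeffs(fig2_params, fig2_noise):
    r_grid = densities.build_r_grid(fig2_params, fig2_noise)
    return pl.averaged_coefficients(fig2_params, fig2_noise, r_grid)


@pytest.fixture(scope="session")
def fig2_p0(fig2_coeffs):
    return gfpk.solve_p0(fig2_coeffs)


@pytest.fixture(scope="session")
def fig2_density(fig2_coeffs, fig2_p0):
    p1 = gfpk.solve_p1(fig2_coeffs, fig2_p0)
    p2 = gfpk.solve_p2(fig2_coeffs, fig2_p0)
    return gfpk.assemble_density(fig2_p0, p1, p2, fig2_coeffs.eps)


@pytest.fixture(scope="session")
def fig2_pops(fig2_density, fig2_params, fig2_coeffs):
    return densities.population_densities(fig2_density, fig2_params, fig2_coeffs)


@pytest.fixture(scope="session")
def fig2_gaussian(fig2_params, fig2_noise):
    """Gaussian-reference pipeline at the Fig-2 noise intensities."""
    return densities.gaussian_reference(
        fig2_params, fig2_noise.intensities(fig2_params.eps))
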