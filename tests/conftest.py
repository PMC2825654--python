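import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from darkscatter import (
    CollimatorSpec,
    DetectorBank,
    DetectorChannel,
    DetectorGrid,
    ScatterPhysics,
    SimulationConfig,
    build_table1_phantom,
    simulate,
)
from darkscatter.single_scatter import build_acceptance_table, single_scatter_image

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_phantom():
    return build_table1_phantom()


@pytest.fixture(scope="session")
def physics50():
    """50 keV physics with the Rayleigh form factor calibrated to 4.3 deg."""
    return ScatterPhysics.calibrated(50.0)


@pytest.fixture(scope="session")
def reduced_grid():
    """Desk-scale detector: 60 x 60 pixels at 0.2 cm pitch."""
    return DetectorGrid(60, 60, 0.2)


@pytest.fixture(scope="session")
def reference_channels():
    return [
        DetectorChannel("IH", CollimatorSpec(50.0), 2.5),
        DetectorChannel("IL", CollimatorSpec(10.0), 2.5),
        DetectorChannel("IL_far", CollimatorSpec(10.0), 17.5),
        DetectorChannel("IL_septa", CollimatorSpec(10.0, septa=True), 2.5),
    ]


@pytest.fixture(scope="session")
def reference_run(table1_phantom, physics50, reduced_grid, reference_channels):
    """One large matched-stream acquisition shared by the imaging checks.

    5e7 photons so that the smallest region contrast (cube1 vs cube2, a
    0.0035 cm^-1 difference in the Rayleigh coefficient over a 1 cm cube)
    stands several standard errors above the counting noise.
    """
    bank = DetectorBank(reduced_grid, reference_channels, phantom_exit_z=2.5)
    config = SimulationConfig(n_photons=50_000_000, seed=2026)
    return simulate(config, table1_phantom, bank, physics50)


@pytest.fixture(scope="session")
def single_scatter_prediction(table1_phantom, physics50, reduced_grid):
    """Analytic single-scatter image for the explicit-septa aspect-10 channel
    at 2.5 cm, with the statistically simulated acceptance table."""
    from dataclasses import replace

    grid = replace(reduced_grid, plane_z=table1_phantom.z_max + 2.5)
    collimator = CollimatorSpec(10.0, septa=True)
    table = build_acceptance_table(table1_phantom, grid, collimator,
                                   physics50, method="mc",
                                   n_samples=20_000, seed=5)
    image = single_scatter_image(table1_phantom, grid, collimator,
                                 physics50, table)
    return table, image


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
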