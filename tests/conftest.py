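import numpy as np
import pytest

from epidermsim.cell_model import LifecycleParams
from epidermsim.geometry import MembraneSpec
from epidermsim.mechanics import ForceParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_spec():
    return MembraneSpec(kind="flat", domain_x_um=100.0, domain_y_um=100.0)


@pytest.fixture
def sin_spec():
    return MembraneSpec(kind="sinusoidal", amplitude_um=50.0,
                        wavelength_um=100.0, domain_x_um=100.0,
                        domain_y_um=100.0)


@pytest.fixture
def lifecycle():
    return LifecycleParams()


@pytest.fixture
def forces():
    return ForceParams()


# ---------------------------------------------------------------------------
# Session-scoped simulation batteries shared by the acceptance tests. These are
# the expensive pieces; everything that needs a long run reuses them. Problem
# sizes (documented in docs/methods.md): the flat-membrane battery runs the
# full 500 h on the desk-scale domain; the paired flat-vs-sinusoidal ordering
# uses 300 h (the ordering is established well before then); the sweep uses
# single replicates at 200 h with paired seeds across the grid.
# ---------------------------------------------------------------------------

ACCEPT_SEED = 20180101
ACCEPT_REPLICATES = 5


@pytest.fixture(scope="session")
def flat_steady_runs():
    """Five 500 h flat-membrane runs with independent seeds."""
    from epidermsim.experiments import replicate_seeds, run_condition

    spec = MembraneSpec(kind="flat", domain_x_um=100.0, domain_y_um=100.0)
    return [run_condition(spec, seed, "flat", rep, keep_snapshots=True)
            for rep, seed in enumerate(
                replicate_seeds(ACCEPT_SEED, ACCEPT_REPLICATES))]


@pytest.fixture(scope="session")
def flat_vs_sin_report():
    from epidermsim.experiments import experiment_flat_vs_sinusoidal

    return experiment_flat_vs_sinusoidal(
        replicates=ACCEPT_REPLICATES, base_seed=ACCEPT_SEED,
        sim_overrides={"run": {"t_total_h": 300.0, "snapshot_every_h": 50.0}})


@pytest.fixture(scope="session")
def sweep_report():
    from epidermsim.experiments import experiment_amplitude_wavelength_sweep

    return experiment_amplitude_wavelength_sweep(
        replicates=1, base_seed=ACCEPT_SEED,
        sim_overrides={"run": {"t_total_h": 200.0, "snapshot_every_h": 50.0}})
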