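import numpy as np
import pytest

from bivalentscan.pipeline import RunConfig, run_all
from bivalentscan.synthetic_data import SimulationConfig, simulate_study


def small_sim_config(seed: int = 17, **overrides) -> SimulationConfig:
    """A desk-scale study: 2 x 7 Mb genome, 50 genes, 35 peaks."""
    defaults = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=7_000_000,
        n_genes=50,
        n_activated_targets=10,
        n_repressed_targets=5,
        n_decoy_peaks=20,
        n_patients=200,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One small simulated study on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("small_study")
    manifest = simulate_study(small_sim_config(), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-scale pipeline run (the study conditions the
    planted-effect recovery checks are defined on), with wall time."""
    import time

    outdir = tmp_path_factory.mktemp("default_run")
    config = RunConfig.from_dict({"seed": 20260921})
    t0 = time.time()
    summary = run_all(config, outdir)
    elapsed = time.time() - t0
    return outdir, config, summary, elapsed


@pytest.fixture()
def rng():
    return np.random.default_rng(20_25)
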