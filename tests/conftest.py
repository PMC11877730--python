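import numpy as np
import pytest

from methylxci.synthetic_data import SimConfig, export_fixture, simulate_study


@pytest.fixture(scope="session")
def sim_small():
    """A small somatic-mode study used across test modules."""
    cfg = SimConfig(
        seed=7,
        n_genes=30,
        n_intergenic_cpgs=60,
        n_autosomal_cpgs=40,
        n_samples_per_sex=12,
        coupling_mode="somatic",
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """An exported on-disk study fixture."""
    cfg = SimConfig(
        seed=11,
        n_genes=25,
        n_intergenic_cpgs=50,
        n_autosomal_cpgs=30,
        n_samples_per_sex=10,
        coupling_mode="placenta",
    )
    outdir = tmp_path_factory.mktemp("fixture") / "study"
    export_fixture(cfg, outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
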