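import numpy as np
import pytest

from panelcov.synthetic_data import KitSpec, SimulationConfig, generate, write_outputs

SMALL_KITS = (
    KitSpec("kitA", 0.92, 30.5, 4),
    KitSpec("kitB", 0.97, 80.0, 6),
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A 12-gene, 2-kit study small enough for per-test reuse."""
    return SimulationConfig(
        seed=11,
        n_genes=12,
        n_chroms=2,
        chrom_length=20_000,
        exons_per_gene=3,
        exon_length=(60, 100),
        intron_length=(40, 80),
        gene_gap=150,
        kits=SMALL_KITS,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return generate(small_cfg)


@pytest.fixture(scope="session")
def small_dir(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("smallsim")
    write_outputs(small_sim, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2014)
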