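import pytest

from painnets import SynthConfig
from painnets import simulate


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Reduced study for fast end-to-end runs."""
    return SynthConfig(
        seed=7, n_genes=300, n_samples_per_tissue=60, n_tissues=2,
        module_sizes=(40, 40, 40, 40), signal_module_ids=(0, 1),
        network_size=150, n_pathways=8, pathway_size=30,
    )


@pytest.fixture(scope="session")
def expression_draw(default_config):
    return simulate.generate_expression(default_config)


@pytest.fixture(scope="session")
def gwas_draw(default_config):
    return simulate.generate_gwas(default_config, "NP")


@pytest.fixture(scope="session")
def annotation_draw(default_config):
    return simulate.generate_gene_annotation_and_eqtl(default_config)


@pytest.fixture(scope="session")
def network_draw(default_config):
    return simulate.generate_networks(default_config)
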