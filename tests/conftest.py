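import pytest

from xyscan import pipeline
from xyscan.simdata import SimConfig, build_truth


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale PAR/young/old chromosome plus two autosomes."""
    return SimConfig(seed=11, chrom_length=10_000_000,
                     sex_chrom_length=3_000_000, n_genes_per_chrom=240)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_truth(small_config)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_config):
    """One full pipeline run shared by the file-level tests."""
    d = tmp_path_factory.mktemp("simrun")
    pipeline.run_simulate(small_config, d)
    pipeline.run_scan(d, seed=11)
    pipeline.run_classify(d)
    pipeline.run_ase(d)
    pipeline.run_dosage(d)
    return d
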