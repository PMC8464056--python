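import numpy as np
import pytest

from rddmkit import SyntheticConfig, export_dataset
from rddmkit.pipeline import pipeline_config_for_dataset, run_pipeline


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic dataset (one 150 kb chromosome) for fast tests.

    Conversion error 0 so the methylation-absence categories are exact.
    """
    cfg = SyntheticConfig(
        seed=11,
        n_chromosomes=1,
        chromosome_length=150_000,
        n_feedback_loci=12,
        n_multi_pathway_loci=12,
        n_tes_per_chromosome=45,
        n_genes_per_chromosome=12,
        conversion_error=0.0,
    )
    return export_dataset(cfg, tmp_path_factory.mktemp("smallds"))


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("smallrun")
    cfg = pipeline_config_for_dataset(
        small_dataset, out, seed=11, params={"n_permutations": 200}
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture(scope="session")
def full_dataset(tmp_path_factory):
    """The default ~1 Mb study-condition dataset (two chromosomes,
    60 + 60 planted loci, two replicates per genotype, met1 single)."""
    cfg = SyntheticConfig(seed=11, conversion_error=0.0)
    return export_dataset(cfg, tmp_path_factory.mktemp("fullds"))


@pytest.fixture(scope="session")
def full_run(full_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("fullrun")
    cfg = pipeline_config_for_dataset(full_dataset, out, seed=11)
    manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(11)
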