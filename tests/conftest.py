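import pytest

from sscoloc import ScenarioConfig, simulate_summary_stats, write_fixture_files


@pytest.fixture(scope="session")
def bundle_c():
    """Colocalized locus (shared causal SNP), seed 1."""
    return simulate_summary_stats(ScenarioConfig(scenario="C", seed=1))


@pytest.fixture(scope="session")
def bundle_a():
    """Null locus (no GWAS or eQTL signal), seed 2."""
    return simulate_summary_stats(ScenarioConfig(scenario="A", seed=2))


@pytest.fixture(scope="session")
def multi_bundle_c():
    """Colocalized locus with 2 genes x 2 tissues (signal on the first pair)."""
    cfg = ScenarioConfig(scenario="C", seed=1, genes=("GENE1", "GENE2"),
                         tissues=("pancreas", "lung"))
    return simulate_summary_stats(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, multi_bundle_c):
    """On-disk file bundle (TSVs, .ld, VCF, GTF) for the colocalized locus."""
    out = tmp_path_factory.mktemp("locus_c")
    paths = write_fixture_files(multi_bundle_c, out)
    return paths
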