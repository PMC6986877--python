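import pytest

from glireg.pipeline import PipelineParams, run_all
from glireg.simulate import SimulationConfig, generate_dataset

#: Reduced geometry for tests that only need a valid bundle, not power.
SMALL_CONFIG = dict(
    chrom_sizes={"chr1": 400_000, "chr2": 300_000},
    n_genes=60,
    n_gbr={"stable": 40, "hh_sensitive": 10, "hh_dependent": 10, "non_acetylated": 5},
    background_reads=60_000,
    atac_background_reads=20_000,
)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default study conditions with a fixed seed (shared across tests)."""
    outdir = tmp_path_factory.mktemp("bundle_default")
    return generate_dataset(SimulationConfig(seed=7), outdir)


@pytest.fixture(scope="session")
def pipeline_result(default_bundle):
    """Full pipeline run on the default bundle."""
    return run_all(default_bundle.directory, PipelineParams(seed=7))


@pytest.fixture()
def small_bundle(tmp_path):
    return generate_dataset(SimulationConfig(seed=5, **SMALL_CONFIG), tmp_path / "bundle")
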