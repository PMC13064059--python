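import pytest
from hypothesis import HealthCheck, settings

from zwscan import SimParams, pipeline, simulate_dataset
from zwscan import io as zio

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: the study-condition run shared across tests: 2 Mb chrW, 10 F + 10 M, depth 30
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    return simulate_dataset(SimParams(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_run")
    manifest = pipeline.run_pipeline(default_sim, zio.load_config(), outdir, force=True)
    return default_sim, manifest


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb chromosome for file-heavy and base-resolution tests."""
    params = SimParams(
        seed=7,
        chrom_length=200_000,
        region_bounds=(40_000, 75_000, 135_000, 140_000),
        autosome_length=100_000,
    )
    return simulate_dataset(params)
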