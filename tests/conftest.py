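import pytest

from anther_smallrna.pipeline import PipelineConfig, run_pipeline
from anther_smallrna.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Session-wide synthetic configuration shared by the heavier tests."""
    return SimulationConfig(
        seed=11,
        library_depth=100_000,
        n_planted_mirnas=10,
        n_conserved=5,
        n_transcripts=30,
        degradome_depth=20_000,
        de_spec=[("ghr-miR901", "Mar-F-1", "Mar-S-1", 4.0)],
    )


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory, sim_config):
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(outdir=out, simulation=sim_config)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def dataset(pipeline_results):
    """(paths, ground_truth) of the session synthetic dataset."""
    return pipeline_results["input_paths"], pipeline_results["ground_truth"]
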