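import shutil
from pathlib import Path

import pytest

from paleoscape.pipeline import PipelineConfig, run_simulate


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """A simulated mini-estuary fixture shared across pipeline tests."""
    base = tmp_path_factory.mktemp("estuary")
    cfg = PipelineConfig(
        input_dir=str(base / "fixture"), output_dir=str(base / "out"), seed=3
    )
    run_simulate(cfg)
    return base / "fixture"


@pytest.fixture()
def pipeline_config(fixture_dir, tmp_path) -> PipelineConfig:
    return PipelineConfig(
        input_dir=str(fixture_dir),
        output_dir=str(tmp_path / "out"),
        seed=3,
        mcmc_iterations=800,
    )
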