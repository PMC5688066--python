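import numpy as np
import pytest

from marinibin.config import PipelineConfig
from marinibin.pipeline import run_pipeline
from marinibin.synthio import build_fixture


@pytest.fixture(scope="session")
def fixture1():
    """Default synthetic study at seed 1 (3 clades + background)."""
    return build_fixture(seed=1)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at seed 1, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=1)
    manifest = run_pipeline(cfg, out)
    return cfg, out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
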