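import numpy as np
import pytest

from eibalance.simulate import default_config, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The packaged default two-condition dataset (seed 7)."""
    return generate_dataset(default_config())


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A full default pipeline run with files written."""
    from eibalance.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(outdir=str(out), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
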