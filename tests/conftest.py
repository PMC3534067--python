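import numpy as np
import pytest

from srnakit.report import PipelineConfig, run_pipeline
from srnakit.simulate import SimConfig, write_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default synthetic study: 8 libraries x 1e5 reads, seed fixed."""
    outdir = tmp_path_factory.mktemp("dataset")
    cfg = SimConfig(seed=1)
    genome, features, result = write_dataset(cfg, str(outdir))
    return {
        "dir": str(outdir),
        "config": cfg,
        "genome": genome,
        "features": features,
        "result": result,
    }


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    return run_pipeline(default_dataset["dir"], PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
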