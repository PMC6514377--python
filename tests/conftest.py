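import numpy as np
import pytest

from phenolidar.pipeline import PipelineConfig, run_pipeline
from phenolidar.simulate import make_dataset


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """Standard synthetic campaign: 20-row parcel, 5 plates, 10 spots, seed 0."""
    d = tmp_path_factory.mktemp("campaign")
    make_dataset(str(d), n_spots=10, seed=0)
    return str(d)


@pytest.fixture(scope="session")
def pipeline_result(dataset_dir):
    return run_pipeline(PipelineConfig(), dataset_dir)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
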