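import numpy as np
import pytest

from ictalnet.bonn import TASKS
from ictalnet.preprocess import PreprocessConfig, preprocess_dataset
from ictalnet.synthetic import SynthParams, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Five synthetic subsets with 6 records each (30 records, seed 42)."""
    return generate_dataset(6, SynthParams(seed=42))


@pytest.fixture(scope="session")
def ternary_records(small_dataset):
    task = TASKS["ternary"]
    return [(rec, task.class_of(rec.subset)) for rec in small_dataset.records]


@pytest.fixture(scope="session")
def short_segments():
    """Short (512-sample) preprocessed ternary segments for fast model tests.

    The spike rate is raised so a ~3 s window still carries a few interictal
    spikes (the default 0.5 Hz is calibrated to 23.6 s records).
    """
    params = SynthParams(seed=7, n_samples=512, spike_rate_hz=2.0)
    ds = generate_dataset(16, params)
    task = TASKS["ternary"]
    records = [(rec, task.class_of(rec.subset)) for rec in ds.records]
    cfg = PreprocessConfig(segment_len_samples=512)
    return preprocess_dataset(records, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
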