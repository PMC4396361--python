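import logging

import numpy as np
import pytest

from tectomap.config import PipelineConfig
from tectomap.pipeline import analyze_imaging
from tectomap.synth import gen_ephys_dataset, gen_imaging_dataset

logging.getLogger("tectomap").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_imaging_dataset():
    """64x64 concentric-rule dataset, small design, for pipeline-level tests."""
    return gen_imaging_dataset(
        shape=(64, 64), n_patch_reps=3, n_dir_reps=5, seed=11
    )


@pytest.fixture(scope="session")
def small_imaging_result(small_imaging_dataset):
    ds = small_imaging_dataset
    cfg = PipelineConfig(reference_roi_px=[0, 10, 0, 10], n_map_permutations=0, seed=11)
    return analyze_imaging(ds.stack, ds.events, ds.geometry, cfg)


@pytest.fixture(scope="session")
def columnar_ephys_table():
    table, truth = gen_ephys_dataset(rule="columnar_random", within_kappa=8, seed=7)
    return table, truth
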