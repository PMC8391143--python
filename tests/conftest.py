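import logging

import numpy as np
import pytest

from ventralenc import PipelineConfig, SyntheticStudyConfig, make_layer_features
from ventralenc.synthetic import ROISpec

logging.getLogger("ventralenc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_study_config() -> SyntheticStudyConfig:
    """A minutes-free study: 2 subjects, 2 ROIs, 3 shallow layers."""
    return SyntheticStudyConfig(
        n_subjects=2,
        n_train=80,
        n_val=30,
        n_layers=3,
        layer_dims=[40, 40, 40],
        rois=[
            ROISpec("V1", 8, [0.8, 0.2, 0.0]),
            ROISpec("FFA", 8, [0.0, 0.2, 0.8]),
        ],
        k_true=4,
        snr=2.0,
        n_runs=5,
        run_noise_sd=1.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_pipeline_config(tiny_study_config) -> PipelineConfig:
    return PipelineConfig(
        study=tiny_study_config,
        sparsity=8,
        n_perm=200,
        n_sim=200,
        top_k=5,
        seed=5,
        log_level="ERROR",
    )


@pytest.fixture(scope="session")
def small_features():
    """A 2-layer hierarchical feature set shared by feature-space tests."""
    return make_layer_features(60, 20, [30, 25], seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
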