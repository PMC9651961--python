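import numpy as np
import pytest

import transfc as tf


@pytest.fixture(scope="session")
def desk_config() -> tf.PipelineConfig:
    """Desk-scale study conditions: 16 subjects, one 240-volume run."""
    return tf.PipelineConfig(
        phantom=tf.PhantomConfig(n_subjects=16, n_volumes_per_run=240,
                                 noise_sd=1.0, rng_seed=0))


@pytest.fixture(scope="session")
def desk_result(desk_config) -> tf.PipelineResult:
    """One full pipeline run shared by the integration-level tests."""
    return tf.run_pipeline(desk_config, write_artifacts=False)


@pytest.fixture(scope="session")
def anatomy_truth():
    return tf.build_phantom_anatomy(tf.PhantomConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
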