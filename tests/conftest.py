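import numpy as np
import pytest

from cnnforest import CnnSpec, CohortConfig, ForestParams, generate_cohort
from cnnforest.pipeline import PipelineConfig


# Desk-scale configuration used by the end-to-end tests: 40+40 patients,
# 8 images each, 32x32, n_cnns=4, 2 epochs, 15 trees.  Batch size and
# optimizer were fixed by a pilot run; the full 5-fold run takes ~40 s.
DESK_COHORT = CohortConfig(
    n_healthy_patients=40,
    n_cad_patients=40,
    images_per_patient=8,
    image_size=(32, 32),
    lesion_intensity=0.8,
    lesion_radius_px=5,
    noise_sd=0.05,
    seed=1,
)


def desk_cnn_spec() -> CnnSpec:
    return CnnSpec(input_shape=(32, 32), epochs=2, batch_size=32, optimizer="adam")


def desk_pipeline_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        n_cnns=4,
        folds=5,
        cnn_spec=desk_cnn_spec(),
        forest_params=ForestParams(n_trees=15),
        global_seed=seed,
    )


# Tiny configuration for unit tests of the training machinery (seconds, not minutes).
TINY_COHORT = CohortConfig(
    n_healthy_patients=10,
    n_cad_patients=10,
    images_per_patient=4,
    image_size=(16, 16),
    lesion_intensity=0.8,
    lesion_radius_px=3,
    noise_sd=0.05,
    seed=7,
)


def tiny_cnn_spec(**overrides) -> CnnSpec:
    defaults = dict(
        input_shape=(16, 16),
        filters=(4, 8),
        dense_units=16,
        epochs=2,
        batch_size=16,
        optimizer="adam",
    )
    defaults.update(overrides)
    return CnnSpec(**defaults)


@pytest.fixture(scope="session")
def desk_cohort():
    return generate_cohort(DESK_COHORT)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(TINY_COHORT)


@pytest.fixture(scope="session")
def flat_cohort():
    """Cohort with no lesion signal: classes are statistically identical."""
    cfg = CohortConfig(
        n_healthy_patients=15,
        n_cad_patients=15,
        images_per_patient=4,
        image_size=(16, 16),
        lesion_intensity=0.0,
        lesion_radius_px=3,
        noise_sd=0.05,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
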