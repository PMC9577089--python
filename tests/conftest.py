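import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cbparc import CohortConfig, LabelVolume, VolumeGrid, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def label_volume(labels, affine=None) -> LabelVolume:
    """Wrap an integer array as a LabelVolume on a unit grid."""
    labels = np.asarray(labels, dtype=np.int32)
    grid = VolumeGrid(
        shape=labels.shape, affine=np.eye(4) if affine is None else affine
    )
    return LabelVolume(grid=grid, labels=labels)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 12 subjects, 10x10x3 seed, 2 clusters."""
    return generate_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A cheaper cohort for pipeline plumbing tests."""
    return generate_cohort(
        CohortConfig(
            n_subjects=6,
            seed_shape=(6, 4, 2),
            k_true=2,
            n_targets=8,
            n_streamlines=500,
            rng_seed=7,
        )
    )
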