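import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voicersa as v

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def labels24():
    """Canonical 3 identities x 8 clips item list."""
    return v.make_item_labels()


@pytest.fixture
def small_design():
    """Reduced design for fast GLM round trips."""
    return v.StudyDesign(n_clips_per_identity=2, n_reps_per_clip=2, n_null=6,
                         n_runs=1)


@pytest.fixture
def small_mask():
    return v.VoxelMask(np.ones((6, 6, 6), dtype=bool))
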