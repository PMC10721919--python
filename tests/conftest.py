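import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import tonguetopo as tt
from tonguetopo.mapping import StudyConfig, cohort_feature_table
from tonguetopo.synthesis import zero_effects


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of the reduced synthetic cohort (6 participants x 60
    segments) under default effect sizes.  Shared by the study-level tests;
    computed once per session."""
    return cohort_feature_table(StudyConfig(), seed=1)


@pytest.fixture(scope="session")
def zero_effect_table():
    """Cohort feature table with all participant/gender/age effects zeroed."""
    return cohort_feature_table(StudyConfig(effects=zero_effects()), seed=5)


@pytest.fixture(scope="session")
def recovery_surface():
    """Noise-free 0.5 cm^2 patch with 40 well-separated planted papillae."""
    return tt.generate_surface(
        7071, 7071, papilla_counts={"fungiform": 12, "filiform": 28},
        noise_sd=0, texture_sd=0, micro_density=0,
        height_jitter_sd=0, size_jitter_sd=0, sharpness_jitter_sd=0,
        min_spacing=500.0, seed=9)


@pytest.fixture(scope="session")
def recovery_sweep(recovery_surface):
    return tt.sweep_surface(recovery_surface.mesh, seed=9)


@pytest.fixture(scope="session")
def small_surface():
    """A small default-condition surface with a handful of papillae."""
    return tt.generate_surface(3000, 3000,
                               papilla_counts={"fungiform": 2, "filiform": 6},
                               seed=3)


@pytest.fixture(scope="session")
def small_segments(small_surface):
    return tt.annotated_segments(small_surface, n_none=2, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
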