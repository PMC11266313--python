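import pytest
from hypothesis import settings

from semgshift.grid import make_grid
from semgshift.synth import SubjectProfile, simulate_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_profile():
    """Small, fast subject: 2 gestures x 3 repetitions on a 4x6 grid."""
    return SubjectProfile(grid=make_grid(4, 6), n_gestures=2, n_repetitions=3, seed=7)


@pytest.fixture(scope="session")
def tiny_recordings(tiny_profile):
    return [
        simulate_trial(tiny_profile, g, r)
        for g in range(tiny_profile.n_gestures)
        for r in range(tiny_profile.n_repetitions)
    ]


@pytest.fixture(scope="session")
def default_trial():
    """One trial at the full default scale (8x24 grid, 2,048 Hz)."""
    return simulate_trial(SubjectProfile(seed=3), 2, 5)
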