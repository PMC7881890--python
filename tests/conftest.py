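import numpy as np
import pytest

import gazedecode as gz


@pytest.fixture(scope="session")
def small_cohort():
    return gz.make_cohort(3, 3, seed=11)


@pytest.fixture(scope="session")
def layouts4():
    return gz.default_layouts(4, seed=2)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, layouts4):
    """6 participants x 4 images, 3 s at 60 Hz."""
    return gz.simulate_dataset(small_cohort, layouts4, duration_s=3.0, seed=7)


@pytest.fixture(scope="session")
def events_by_key(small_dataset):
    return {t.key: gz.detect_fixations_idt(t) for t in small_dataset}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_walk_trial(rng, n, step_sd=0.005, pid="P1", img="I1"):
    """Bounded random-walk gaze trace (test helper)."""
    steps = rng.normal(0.0, step_sd, size=(n, 2))
    pos = np.clip(
        np.cumsum(steps, axis=0) + [0.5, 0.37],
        [0, 0], [gz.SCREEN_WIDTH, gz.SCREEN_HEIGHT],
    )
    return gz.Trial(
        participant_id=pid, image_id=img, group="unknown",
        t_ms=np.arange(n) * (1000.0 / 60.0),
        x=pos[:, 0], y=pos[:, 1],
    )
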