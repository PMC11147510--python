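import numpy as np
import pytest

import fiberphot as fp


@pytest.fixture
def quiet_spec():
    """Noise-free, artifact-free recording spec: bleach only."""
    return fp.SyntheticSpec(
        duration_s=20.0,
        noise_sd=0.0,
        artifact_rate_hz=0.0,
        seed=0,
    )


@pytest.fixture
def swim_track():
    """Short swim-assay track: active early, passive late."""
    schedule = (
        ("climbing", 0.0, 30.0),
        ("swimming", 30.0, 60.0),
        ("immobile", 60.0, 110.0),
        ("hindpaw swimming", 110.0, 120.0),
        ("immobile", 120.0, 150.0),
    )
    return fp.generate_behavior_track(schedule, 30.0, fp.SWIM_CATEGORIES)


def random_behavior_track(rng, categories=("a", "b", "c"), n_frames=None, rate=None):
    """Random label churn for property/oracle tests."""
    n = n_frames or int(rng.integers(5, 400))
    r = rate or float(rng.choice([10.0, 25.0, 30.0]))
    labels = rng.choice(np.array(categories, dtype=object), size=n)
    return fp.BehaviorTrack(labels, r, tuple(categories))
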