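import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vibrafall as vf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def floor():
    return vf.FloorModel()


@pytest.fixture(scope="session")
def tiny_design():
    """A few events of each activity at reduced duration: fast to generate."""
    return vf.ScenarioDesign(
        inventory=[
            vf.ActivityEntry("fall", 6, {"mass_kg": [75.0, 48.0]}),
            vf.ActivityEntry("walk", 3, {"mass_kg": 69.0}),
            vf.ActivityEntry("free_jump", 4, {"mass_kg": 78.0}),
            vf.ActivityEntry("rhythmic_jump", 4, {"mass_kg": 69.0}),
            vf.ActivityEntry("bag_drop", 4, {"mass_kg": 5.0, "drop_height_m": 0.6}),
            vf.ActivityEntry("ball_drop", 4, {"mass_kg": 0.6, "drop_height_m": 1.45}),
        ],
        sensors=[(0.5, 0.5), (0.5, 4.5), (3.5, 4.5), (2.0, 2.5)],
        fs=800.0,
        duration=1.5,
        noise_sd=0.001,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design, floor):
    return vf.generate_scenario(tiny_design, floor)


def make_two_cluster_views(n_per_class=60, sep=3.0, seed=0):
    """Synthetic stacked view matrix for 2 sensors (widths 2, 2, 1) with two
    Gaussian classes separated by ``sep`` standard deviations."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(sep, 1.0, size=(n_per_class, 5))
    neg = rng.normal(0.0, 1.0, size=(n_per_class, 5))
    X = np.vstack([pos, neg])
    # peak/energy views must be nonnegative in spirit; shift is irrelevant
    # to the classifier but keeps the geometry comparable
    y = np.concatenate([np.ones(n_per_class, int), -np.ones(n_per_class, int)])
    perm = rng.permutation(y.size)
    return X[perm], y[perm]
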