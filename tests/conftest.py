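import numpy as np
import pytest

import audioloc as al


@pytest.fixture(scope="session")
def small_cfg() -> al.SimConfig:
    return al.SimConfig(seed=7, n_participants=6)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Six synthetic participants: 6 x 2 x 65 = 780 trials."""
    return al.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    records, trajectories, _ = small_dataset
    return al.flag_outliers(al.compute_metrics(records, trajectories))


@pytest.fixture(scope="session")
def default_dataset():
    """The full default-scale study: 37 participants, 4810 trials."""
    return al.generate_dataset(al.SimConfig(seed=20221206))


@pytest.fixture(scope="session")
def default_metrics(default_dataset):
    records, trajectories, _ = default_dataset
    return al.flag_outliers(al.compute_metrics(records, trajectories))


def make_metrics(unsigned_errors, target_az=0.0, condition="V", **overrides):
    """Minimal TrialMetrics list for filter/summary unit tests."""
    out = []
    for i, e in enumerate(unsigned_errors):
        fields = dict(
            trial_id=f"t{i}",
            participant_id=overrides.get("participant_id", "P01"),
            group="G_V",
            condition=condition,
            target_az=target_az,
            signed_error=float(e),
            unsigned_error=abs(float(e)),
            latency=1.0,
            head_divergence=0.0,
            head_distance=0.0,
        )
        fields.update(overrides)
        out.append(al.TrialMetrics(**fields))
    return out
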