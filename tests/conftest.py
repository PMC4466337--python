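import numpy as np
import pytest

from optorc import (
    GroundTruthLN,
    LinearFilter,
    StaticNonlinearity,
    default_ground_truth,
    generate_bernoulli,
    simulate_population,
)


def constant_hazard_model(rate_rt: float, rate_tr: float) -> GroundTruthLN:
    """Stimulus-independent ground truth: zero filters, constant rates."""
    zero = LinearFilter(taus=np.array([0.0]), h=np.array([0.0]), dt=0.25)
    return GroundTruthLN(
        filter_rt=zero,
        filter_tr=LinearFilter(taus=np.array([0.0]), h=np.array([0.0]), dt=0.25,
                               kind="TURN_TO_RUN"),
        nonlin_rt=StaticNonlinearity("constant", {"rate": rate_rt}),
        nonlin_tr=StaticNonlinearity("constant", {"rate": rate_tr}),
    )


@pytest.fixture(scope="session")
def bernoulli_stim():
    return generate_bernoulli(600.0, 0.25, 0.5, seed=7)


@pytest.fixture(scope="session")
def small_population(bernoulli_stim):
    gt = default_ground_truth("attractive-monophasic")
    return gt, simulate_population(gt, bernoulli_stim, n_animals=30, seed=7)
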