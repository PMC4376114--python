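import numpy as np
import pytest

from sepsispomdp.solver import PomdpModel
from sepsispomdp.states import Culture, StateLabel, VitalsSnapshot


def random_simplex(rng, n):
    x = rng.gamma(1.0, 1.0, size=n)
    return x / x.sum()


def random_pomdp(rng, n_states, n_actions, n_obs, gamma=0.9, reward_scale=10.0):
    """A fully random, valid POMDP."""
    T = np.stack(
        [
            np.stack([random_simplex(rng, n_states) for _ in range(n_actions)])
            for _ in range(n_states)
        ]
    )
    O = np.stack([random_simplex(rng, n_obs) for _ in range(n_states)])
    R = rng.uniform(-reward_scale, reward_scale, size=n_states)
    b0 = random_simplex(rng, n_states)
    return PomdpModel(T=T, O=O, R=R, b0=b0, gamma=gamma)


def identity_obs_pomdp(rng, n_states, n_actions, gamma=0.9, reward_scale=10.0):
    """Random MDP embedded as a POMDP with identity observations."""
    model = random_pomdp(rng, n_states, n_actions, n_states, gamma, reward_scale)
    model.O = np.eye(n_states)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: Canonical fully observed vitals per state (labels deterministically).
CANONICAL_VITALS = {
    StateLabel.NO_SIRS: dict(
        temperature=37.0, heart_rate=75.0, respiratory_rate=14.0, wbc=8000.0,
        map=90.0, sbp=120.0, blood_culture=Culture.NEGATIVE,
    ),
    StateLabel.SIRS: dict(
        temperature=39.0, heart_rate=110.0, respiratory_rate=26.0, wbc=15000.0,
        map=85.0, sbp=112.0, blood_culture=Culture.NEGATIVE,
    ),
    StateLabel.SEPSIS: dict(
        temperature=39.0, heart_rate=110.0, respiratory_rate=26.0, wbc=15000.0,
        map=85.0, sbp=112.0, blood_culture=Culture.POSITIVE,
    ),
    StateLabel.SEPTIC_SHOCK: dict(
        temperature=39.0, heart_rate=110.0, respiratory_rate=26.0, wbc=15000.0,
        map=55.0, sbp=75.0, blood_culture=Culture.POSITIVE,
    ),
    StateLabel.BACTEREMIA: dict(
        temperature=37.0, heart_rate=75.0, respiratory_rate=14.0, wbc=8000.0,
        map=90.0, sbp=120.0, blood_culture=Culture.POSITIVE,
    ),
    StateLabel.PS: dict(map=90.0, sbp=120.0, blood_culture=Culture.NEGATIVE),
    StateLabel.BPS: dict(map=90.0, sbp=120.0, blood_culture=Culture.POSITIVE),
    StateLabel.PSS: dict(map=55.0, sbp=75.0, blood_culture=Culture.POSITIVE),
}


def snapshot_for(state: StateLabel, timestamp: float = 0.0) -> VitalsSnapshot:
    return VitalsSnapshot(timestamp=timestamp, **CANONICAL_VITALS[state])
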