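import numpy as np
import pytest

from sepsispomdp.solver import (
    DEFAULT_STATE_REWARDS,
    AlphaVectorPolicy,
    InconsistentObservationError,
    PomdpModel,
    belief_update,
    default_reward_vector,
    exact_mdp_value_iteration,
    extract_action,
    perseus_solve,
    point_based_backup,
    sample_beliefs,
)
from sepsispomdp.states import StateLabel

from conftest import identity_obs_pomdp, random_pomdp


# -------------------------------------------------------------- reward table


def test_default_reward_table_values():
    assert DEFAULT_STATE_REWARDS[StateLabel.DISMISSAL] == 100_000
    assert DEFAULT_STATE_REWARDS[StateLabel.NO_SIRS] == 50_000
    assert DEFAULT_STATE_REWARDS[StateLabel.PS] == 5_000
    assert DEFAULT_STATE_REWARDS[StateLabel.SIRS] == -50
    assert DEFAULT_STATE_REWARDS[StateLabel.BACTEREMIA] == -10_000
    assert DEFAULT_STATE_REWARDS[StateLabel.BPS] == -12_500
    assert DEFAULT_STATE_REWARDS[StateLabel.PSS] == -15_000
    assert DEFAULT_STATE_REWARDS[StateLabel.SEPSIS] == -40_000
    assert DEFAULT_STATE_REWARDS[StateLabel.SEPTIC_SHOCK] == -60_000
    assert DEFAULT_STATE_REWARDS[StateLabel.DEATH] == -100_000


def test_reward_vector_ordering_matches_severity():
    from sepsispomdp.states import SEVERITY_ORDER

    rewards = [DEFAULT_STATE_REWARDS[s] for s in SEVERITY_ORDER]
    assert rewards == sorted(rewards, reverse=True)


def test_reward_overrides():
    r = default_reward_vector({"SIRS": -500.0})
    assert r[int(StateLabel.SIRS)] == -500.0
    assert r[int(StateLabel.DEATH)] == -100_000.0


# ------------------------------------------------------------- belief update


def test_update_identity_T_state_independent_O():
    n = 4
    T = np.stack([np.eye(n)] * 2, axis=1)  # (S, A, S) identity per action
    O = np.full((n, 3), 1 / 3)
    model = PomdpModel(T=T, O=O, R=np.zeros(n), b0=np.full(n, 0.25), gamma=0.9)
    b = np.array([0.1, 0.2, 0.3, 0.4])
    b2, norm = belief_update(b, 0, 1, model)
    assert np.allclose(b2, b)
    assert norm == pytest.approx(1 / 3)


def test_update_two_state_hand_computed():
    # b=(0.5,0.5), T uniform, O(s1,z)=0.8, O(s2,z)=0.2 -> b'=(0.8,0.2)
    T = np.full((2, 1, 2), 0.5)
    O = np.array([[0.8, 0.2], [0.2, 0.8]])
    model = PomdpModel(T=T, O=O, R=np.zeros(2), b0=np.array([0.5, 0.5]), gamma=0.9)
    b2, norm = belief_update(np.array([0.5, 0.5]), 0, 0, model)
    assert np.allclose(b2, [0.8, 0.2])
    assert norm == pytest.approx(0.5)


def test_update_deterministic_transition_point_mass():
    T = np.zeros((3, 1, 3))
    T[:, 0, 2] = 1.0  # everything funnels to s*=2
    O = np.full((3, 4), 0.25)
    model = PomdpModel(T=T, O=O, R=np.zeros(3), b0=np.full(3, 1 / 3), gamma=0.9)
    b2, _ = belief_update(np.array([0.3, 0.4, 0.3]), 0, 1, model)
    assert np.allclose(b2, [0, 0, 1])


def test_update_impossible_observation_raises():
    T = np.stack([np.eye(2)], axis=1)
    O = np.array([[1.0, 0.0], [1.0, 0.0]])  # z=1 never emitted
    model = PomdpModel(T=T, O=O, R=np.zeros(2), b0=np.array([0.5, 0.5]), gamma=0.9)
    with pytest.raises(InconsistentObservationError):
        belief_update(np.array([0.5, 0.5]), 0, 1, model)


def test_update_preserves_simplex_randomized(rng):
    for _ in range(200):
        S = int(rng.integers(2, 6))
        model = random_pomdp(rng, S, int(rng.integers(1, 4)), int(rng.integers(2, 5)))
        b = rng.dirichlet(np.ones(S))
        b2, norm = belief_update(
            b, int(rng.integers(model.n_actions)), int(rng.integers(model.n_observations)), model
        )
        assert b2.min() >= 0
        assert b2.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0 < norm <= 1 + 1e-12


# -------------------------------------------------- exact MDP value iteration


def test_absorbing_death_value_geometric_series():
    # V(absorbing) = R/(1-gamma)
    T = np.zeros((1, 2, 1))
    T[:, :, 0] = 1.0
    V, _ = exact_mdp_value_iteration(T, np.array([-100_000.0]), 0.95, tolerance=1e-6)
    assert V[0] == pytest.approx(-2_000_000.0, rel=1e-6)


def test_single_action_chain_matches_linear_solve(rng):
    # V = (I - gamma*T)^-1 R for a single action
    S = 5
    T1 = rng.dirichlet(np.ones(S), size=S)  # (S, S)
    R = rng.uniform(-10, 10, S)
    gamma = 0.9
    V, _ = exact_mdp_value_iteration(T1[:, None, :], R, gamma, tolerance=1e-12)
    oracle = np.linalg.solve(np.eye(S) - gamma * T1, R)
    assert np.allclose(V, oracle, atol=1e-8)


def test_gamma_zero_returns_rewards(rng):
    model = random_pomdp(rng, 4, 3, 2, gamma=0.0)
    V, _ = exact_mdp_value_iteration(model.T, model.R, 0.0)
    assert np.allclose(V, model.R)


# ------------------------------------------------------------------- backups


def test_single_state_geometric_series_backup():
    r, gamma = 3.0, 0.5
    T = np.ones((1, 1, 1))
    O = np.ones((1, 1))
    model = PomdpModel(T=T, O=O, R=np.array([r]), b0=np.array([1.0]), gamma=gamma)
    policy = AlphaVectorPolicy(np.zeros((1, 1)), np.zeros(1, dtype=int))
    b = np.array([1.0])
    for k in range(6):
        vec, action = point_based_backup(b, policy, model)
        expected = r * (1 - gamma ** (k + 1)) / (1 - gamma)
        assert vec[0] == pytest.approx(expected, rel=1e-12)
        policy = AlphaVectorPolicy(vec[None, :], np.array([action]))


def test_backup_at_corner_matches_mdp_bellman(rng):
    model = identity_obs_pomdp(rng, 2, 2)
    alpha = rng.uniform(-5, 5, size=(3, 2))
    policy = AlphaVectorPolicy(alpha, np.zeros(3, dtype=int))
    V_alpha = alpha.max(axis=0)  # value function at corners under the set
    for s in range(2):
        b = np.zeros(2)
        b[s] = 1.0
        vec, _ = point_based_backup(b, policy, model)
        # oracle: Bellman backup with V = max over vectors (identity O makes
        # the next belief a corner, so the best vector is the corner max)
        q = model.R[s] + model.gamma * np.array(
            [model.T[s, a] @ V_alpha for a in range(2)]
        )
        assert vec[s] == pytest.approx(q.max(), rel=1e-12)


def test_backup_never_decreases_value(rng):
    for _ in range(20):
        model = random_pomdp(rng, 4, 3, 5)
        vectors = rng.uniform(-20, 0, size=(4, 4))
        policy = AlphaVectorPolicy(vectors, rng.integers(0, 3, size=4))
        b = rng.dirichlet(np.ones(4))
        vec, _ = point_based_backup(b, policy, model)
        # guaranteed when the current set is a uniform lower bound; here we
        # only check the backup of a pessimistic set
        low = np.full((1, 4), model.R.min() / (1 - model.gamma))
        low_policy = AlphaVectorPolicy(low, np.zeros(1, dtype=int))
        vec2, _ = point_based_backup(b, low_policy, model)
        assert vec2 @ b >= low_policy.value(b) - 1e-9


# ------------------------------------------------------------ belief sampling


def test_sample_beliefs_n1_is_b0(rng):
    model = random_pomdp(rng, 3, 2, 4)
    beliefs = sample_beliefs(model, n=1, seed=0)
    assert beliefs.shape == (1, 3)
    assert np.allclose(beliefs[0], model.b0)


def test_sample_beliefs_simplex_and_determinism(rng):
    model = random_pomdp(rng, 4, 3, 5)
    b1 = sample_beliefs(model, n=25, seed=99)
    b2 = sample_beliefs(model, n=25, seed=99)
    assert (b1 == b2).all()  # bit-reproducible
    assert b1.shape[0] == 25
    assert np.allclose(b1.sum(axis=1), 1.0, atol=1e-9)
    assert (b1 >= -1e-15).all()
    # distinctness
    assert len({tuple(np.round(r, 12)) for r in b1}) == 25


def test_sample_beliefs_include_corners(rng):
    model = random_pomdp(rng, 3, 2, 4)
    beliefs = sample_beliefs(model, n=10, seed=1, include_corners=True)
    for s in range(3):
        corner = np.zeros(3)
        corner[s] = 1.0
        assert any(np.allclose(b, corner) for b in beliefs)


# ------------------------------------------------------------------- Perseus


def test_perseus_gamma_zero_is_myopic(rng):
    model = random_pomdp(rng, 3, 2, 4, gamma=0.0)
    beliefs = sample_beliefs(model, n=5, seed=0, include_corners=True)
    policy = perseus_solve(model, beliefs, seed=0)
    # with state-based rewards and no lookahead every action ties; value is <R, b>
    assert policy.value(model.b0) == pytest.approx(model.R @ model.b0, rel=1e-9)


def test_perseus_matches_exact_mdp_on_identity_obs(rng):
    for trial in range(5):
        S = int(rng.integers(3, 6))
        A = int(rng.integers(2, 4))
        model = identity_obs_pomdp(rng, S, A, gamma=0.9)
        V_mdp, greedy = exact_mdp_value_iteration(model.T, model.R, model.gamma, 1e-10)
        beliefs = np.eye(S)
        policy = perseus_solve(
            model, beliefs, tolerance=1e-7 * np.abs(model.R).max(), max_iterations=3000, seed=trial
        )
        scale = max(1.0, np.abs(V_mdp).max())
        for s in range(S):
            v = policy.value(np.eye(S)[s])
            assert abs(v - V_mdp[s]) / scale < 1e-4
            action, _, _ = extract_action(policy, np.eye(S)[s])
            # greedy action must be value-equivalent (ties possible)
            Q = model.R[s] + model.gamma * model.T[s] @ V_mdp
            assert Q[action] == pytest.approx(Q[greedy[s]], rel=1e-6)


def test_perseus_monotone_and_converged_flag(rng):
    model = random_pomdp(rng, 4, 3, 5, gamma=0.8)
    beliefs = sample_beliefs(model, n=15, seed=3, include_corners=True)
    policy = perseus_solve(model, beliefs, max_iterations=500, seed=3)
    assert policy.converged
    # monotonicity across stages: truncating the same seeded run after k
    # stages yields values that never decrease in k at any sampled belief
    import warnings

    prev = None
    for k in (1, 2, 4, 8, 16):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pk = perseus_solve(model, beliefs, max_iterations=k, seed=3)
        vals = pk.values(beliefs)
        if prev is not None:
            assert (vals >= prev - 1e-9).all()
        prev = vals


def test_perseus_nonconvergence_warns(rng):
    model = random_pomdp(rng, 4, 3, 5, gamma=0.95)
    beliefs = sample_beliefs(model, n=10, seed=4, include_corners=True)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        policy = perseus_solve(model, beliefs, tolerance=1e-15, max_iterations=2, seed=4)
    assert not policy.converged


def test_perseus_bit_reproducible(rng):
    model = random_pomdp(rng, 4, 2, 5)
    beliefs = sample_beliefs(model, n=10, seed=5, include_corners=True)
    p1 = perseus_solve(model, beliefs, seed=11)
    p2 = perseus_solve(model, beliefs, seed=11)
    assert (p1.vectors == p2.vectors).all()
    assert (p1.actions == p2.actions).all()


def test_value_function_convex_midpoint(rng):
    model = random_pomdp(rng, 4, 3, 5)
    beliefs = sample_beliefs(model, n=20, seed=6, include_corners=True)
    policy = perseus_solve(model, beliefs, seed=6)
    for _ in range(100):
        b1 = rng.dirichlet(np.ones(4))
        b2 = rng.dirichlet(np.ones(4))
        mid = 0.5 * (b1 + b2)
        assert policy.value(mid) <= 0.5 * policy.value(b1) + 0.5 * policy.value(b2) + 1e-9


def test_perseus_tiger_toy_matches_grid_pbvi():
    """2-state toy: noisy listening vs. terminal guesses.

    Oracle: exact alpha-vector value iteration where backups are enumerated
    over all (action, per-observation vector choice) combinations and pruned
    on a 0.001-step belief grid.  The Perseus policy's action must agree
    with the oracle's greedy action except within one grid step of a
    decision boundary.
    """
    # actions: 0=listen (stay, small cost), 1=commit-left, 2=commit-right
    # commit moves to an absorbing "done" third state... keep 2 states by
    # making commits reset the state uniformly (episodic approximation).
    S, A, Z = 2, 3, 2
    T = np.zeros((S, A, S))
    T[:, 0, :] = np.eye(S)  # listen: state persists
    T[:, 1, :] = 0.5  # commit: reset
    T[:, 2, :] = 0.5
    O = np.array([[0.85, 0.15], [0.15, 0.85]])  # informative after listen
    gamma = 0.75

    # rewards depend on action; encode R(s,a) by augmenting: our PomdpModel
    # uses per-state rewards, so build the toy directly in alpha space.
    R = np.array([[-1.0, 10.0, -100.0], [-1.0, -100.0, 10.0]])  # (S, A)

    def exhaustive_stage(alphas):
        # all g_{a,z} projections
        new = []
        for a in range(A):
            proj = []  # per observation: list of back-projected vectors
            for z in range(Z):
                vecs = []
                for alpha in alphas:
                    v = np.array(
                        [sum(T[s, a, s2] * O[s2, z] * alpha[s2] for s2 in range(S)) for s in range(S)]
                    )
                    vecs.append(v)
                proj.append(vecs)
            for i in range(len(alphas)):
                for j in range(len(alphas)):
                    new.append((R[:, a] + gamma * (proj[0][i] + proj[1][j]), a))
        # prune on grid
        grid = np.linspace(0, 1, 1001)
        B = np.stack([1 - grid, grid], axis=1)
        vals = B @ np.stack([v for v, _ in new]).T
        keep = sorted(set(vals.argmax(axis=1)))
        return [new[k] for k in keep]

    alphas = [(np.zeros(S), 0)]
    for _ in range(40):
        alphas = exhaustive_stage([v for v, _ in alphas])

    grid = np.linspace(0, 1, 1001)
    B = np.stack([1 - grid, grid], axis=1)
    mat = np.stack([v for v, _ in alphas])
    acts = np.array([a for _, a in alphas])
    oracle_vals = (B @ mat.T).max(axis=1)
    oracle_act = acts[(B @ mat.T).argmax(axis=1)]

    # Perseus on the same toy: emulate R(s, a) via 3 state copies is overkill;
    # instead run Perseus's backup loop with the action-dependent reward by
    # substituting model.R per action through a tiny local implementation.
    def backup(b, Alpha):
        best, bv, ba = None, -np.inf, 0
        for a in range(A):
            bp = b @ T[:, a, :]
            U = O * bp[:, None]
            k = (Alpha @ U).argmax(axis=0)
            W = (O * Alpha[k].T).sum(axis=1)
            g = R[:, a] + gamma * (T[:, a, :] @ W)
            if g @ b > bv:
                best, bv, ba = g, g @ b, a
        return best, ba

    rng = np.random.default_rng(0)
    beliefs = np.stack([1 - grid[::10], grid[::10]], axis=1)
    Alpha = np.full((1, S), R.min() / (1 - gamma))
    A_act = np.zeros(1, dtype=int)
    for _ in range(200):
        V = (beliefs @ Alpha.T).max(axis=1)
        newV, newA = [], []
        improved = np.zeros(len(beliefs), dtype=bool)
        while not improved.all():
            i = int(rng.choice(np.flatnonzero(~improved)))
            g, a = backup(beliefs[i], Alpha)
            if g @ beliefs[i] >= V[i] - 1e-12:
                newV.append(g)
                newA.append(a)
            else:
                k = int(np.argmax(Alpha @ beliefs[i]))
                newV.append(Alpha[k])
                newA.append(A_act[k])
            improved = (beliefs @ np.stack(newV).T).max(axis=1) >= V - 1e-12
        Alpha, A_act = np.stack(newV), np.array(newA)

    per_vals = (B @ Alpha.T).max(axis=1)
    per_act = A_act[(B @ Alpha.T).argmax(axis=1)]
    assert np.allclose(per_vals, oracle_vals, atol=1e-3 * np.abs(oracle_vals).max())
    # actions agree except within one step of a boundary
    disagree = np.flatnonzero(per_act != oracle_act)
    boundary = np.flatnonzero(np.diff(oracle_act) != 0)
    for d in disagree:
        assert any(abs(d - (bd + 0.5)) <= 1.5 for bd in boundary)


# ------------------------------------------------------------ extract_action


def test_extract_single_vector_no_runner_up():
    policy = AlphaVectorPolicy(np.array([[1.0, 2.0]]), np.array([7]))
    action, value, runner_up = extract_action(policy, np.array([0.5, 0.5]))
    assert action == 7
    assert value == pytest.approx(1.5)
    assert runner_up is None


def test_extract_crossing_at_half():
    # vectors (1,0) and (0,1) cross at b* = 0.5 exactly
    policy = AlphaVectorPolicy(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
    a_left, _, ru_left = extract_action(policy, np.array([0.6, 0.4]))
    a_right, _, ru_right = extract_action(policy, np.array([0.4, 0.6]))
    a_mid, _, _ = extract_action(policy, np.array([0.5, 0.5]))
    assert (a_left, ru_left) == (0, 1)
    assert (a_right, ru_right) == (1, 0)
    assert a_mid == 0  # tie broken by lowest action index


def test_extract_agrees_with_mdp_greedy_identity_obs(rng):
    model = identity_obs_pomdp(rng, 4, 3, gamma=0.85)
    V_mdp, greedy = exact_mdp_value_iteration(model.T, model.R, model.gamma, 1e-10)
    policy = perseus_solve(
        model, np.eye(4), tolerance=1e-7 * np.abs(model.R).max(), max_iterations=3000, seed=0
    )
    for s in range(4):
        action, _, _ = extract_action(policy, np.eye(4)[s])
        Q = model.R[s] + model.gamma * model.T[s] @ V_mdp
        assert Q[action] == pytest.approx(Q[greedy[s]], rel=1e-6)
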