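"""POMDP container, belief update, exact MDP value iteration (oracle), and a
Perseus-style randomized point-based value iteration solver.

The value function is represented as a set of alpha vectors, each tagged
with an action; V(b) = max_k <alpha_k, b> is piecewise linear and convex.
Each Perseus stage backs up randomly chosen beliefs until every sampled
belief's value has improved, which guarantees monotone non-decreasing values
across stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .states import StateLabel

__all__ = [
    "DEFAULT_STATE_REWARDS",
    "default_reward_vector",
    "PomdpModel",
    "AlphaVectorPolicy",
    "InconsistentObservationError",
    "belief_update",
    "exact_mdp_value_iteration",
    "point_based_backup",
    "sample_beliefs",
    "perseus_solve",
    "extract_action",
]

#: Per-state rewards, from best to worst (the "Healthy" top reward is
#: attached to dismissal).
DEFAULT_STATE_REWARDS: dict[StateLabel, float] = {
    StateLabel.DISMISSAL: 100_000.0,
    StateLabel.NO_SIRS: 50_000.0,
    StateLabel.PS: 5_000.0,
    StateLabel.SIRS: -50.0,
    StateLabel.BACTEREMIA: -10_000.0,
    StateLabel.BPS: -12_500.0,
    StateLabel.PSS: -15_000.0,
    StateLabel.SEPSIS: -40_000.0,
    StateLabel.SEPTIC_SHOCK: -60_000.0,
    StateLabel.DEATH: -100_000.0,
}


def default_reward_vector(overrides: Optional[dict] = None) -> np.ndarray:
    """Reward per state index, optionally overriding individual states."""
    r = np.empty(len(StateLabel))
    table = dict(DEFAULT_STATE_REWARDS)
    if overrides:
        for key, value in overrides.items():
            state = key if isinstance(key, StateLabel) else StateLabel[str(key)]
            table[state] = float(value)
    for s in StateLabel:
        r[int(s)] = table[s]
    return r


class InconsistentObservationError(ValueError):
    """The observation has probability zero under the propagated belief."""


@dataclass
class PomdpModel:
    """The 8-tuple (S, A, Z, T, O, R, b0, gamma) with dense arrays.

    ``T`` has shape (S, A, S), ``O`` shape (S, Z) (observation emission
    depends on the arrival state only), ``R`` shape (S,) and ``b0`` shape
    (S,).  The model is generic in S/A/Z so small toy problems and the full
    10-state clinical model share one code path.
    """

    T: np.ndarray
    O: np.ndarray
    R: np.ndarray
    b0: np.ndarray
    gamma: float
    state_names: Optional[tuple[str, ...]] = None
    action_names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.O = np.asarray(self.O, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.b0 = np.asarray(self.b0, dtype=float)
        if not (0 <= self.gamma < 1):
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def n_actions(self) -> int:
        return self.T.shape[1]

    @property
    def n_observations(self) -> int:
        return self.O.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        S, A = self.n_states, self.n_actions
        if self.T.shape != (S, A, S):
            raise ValueError(f"T has shape {self.T.shape}, expected {(S, A, S)}")
        if self.O.shape[0] != S:
            raise ValueError("O first axis must match states")
        if not np.allclose(self.T.sum(axis=2), 1.0, atol=atol):
            raise ValueError("T rows must sum to 1")
        if not np.allclose(self.O.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("O rows must sum to 1")
        if abs(self.b0.sum() - 1.0) > 1e-12 or (self.b0 < 0).any():
            raise ValueError("b0 must be a probability simplex")
        if self.R.shape != (S,):
            raise ValueError("R must be per-state")


def belief_update(
    b: np.ndarray, a: int, z: int, model: PomdpModel
) -> tuple[np.ndarray, float]:
    """Bayes update: b'(s') ∝ O(s', z) Σ_s T(s, a, s') b(s).

    Returns the normalized posterior and the normalizer P(z | b, a).
    Raises :class:`InconsistentObservationError` on a zero normalizer.
    """
    b = np.asarray(b, dtype=float)
    predicted = b @ model.T[:, a, :]
    unnorm = predicted * model.O[:, z]
    norm = float(unnorm.sum())
    if norm <= 0.0:
        raise InconsistentObservationError(
            f"observation {z} has zero probability after action {a}"
        )
    return unnorm / norm, norm


def exact_mdp_value_iteration(
    T: np.ndarray,
    R: np.ndarray,
    gamma: float,
    tolerance: float = 1e-10,
    max_iterations: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Value iteration on the fully observable MDP (the solver's oracle).

    V(s) = max_a [R(s) + gamma Σ_s' T(s,a,s') V(s')], iterated until the
    sup-norm change drops below ``tolerance``.  Returns (V, greedy policy).
    """
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    S = T.shape[0]
    V = np.zeros(S)
    for _ in range(max_iterations):
        Q = R[:, None] + gamma * np.einsum("sat,t->sa", T, V)
        V_new = Q.max(axis=1)
        if np.max(np.abs(V_new - V)) < tolerance:
            V = V_new
            break
        V = V_new
    Q = R[:, None] + gamma * np.einsum("sat,t->sa", T, V)
    return V, Q.argmax(axis=1)


@dataclass
class AlphaVectorPolicy:
    """A set of action-tagged alpha vectors; V(b) = max_k <vectors[k], b>."""

    vectors: np.ndarray  # (K, S)
    actions: np.ndarray  # (K,), int action indices
    stage: int = 0
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    def value(self, b: np.ndarray) -> float:
        return float((self.vectors @ np.asarray(b, dtype=float)).max())

    def values(self, beliefs: np.ndarray) -> np.ndarray:
        """Value at each row of an (N, S) belief matrix."""
        return (np.asarray(beliefs, dtype=float) @ self.vectors.T).max(axis=1)

    def to_json(self, path=None) -> dict:
        payload = {
            "vectors": self.vectors.tolist(),
            "actions": self.actions.tolist(),
            "stage": self.stage,
            "converged": self.converged,
            "metadata": self.metadata,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh)
        return payload

    @classmethod
    def from_json(cls, payload) -> "AlphaVectorPolicy":
        if not isinstance(payload, dict):
            with open(payload) as fh:
                payload = json.load(fh)
        return cls(
            vectors=np.asarray(payload["vectors"], dtype=float),
            actions=np.asarray(payload["actions"], dtype=int),
            stage=int(payload["stage"]),
            converged=bool(payload["converged"]),
            metadata=payload.get("metadata", {}),
        )


def _initial_policy(model: PomdpModel) -> AlphaVectorPolicy:
    # uniform lower bound: collecting min R forever
    low = model.R.min() / (1.0 - model.gamma) if model.gamma > 0 else model.R.min()
    return AlphaVectorPolicy(
        vectors=np.full((1, model.n_states), low), actions=np.zeros(1, dtype=int)
    )


def point_based_backup(
    b: np.ndarray, current: AlphaVectorPolicy, model: PomdpModel
) -> tuple[np.ndarray, int]:
    """One Bellman backup of the alpha-vector set at belief ``b``.

    For each action, the future term sums over observations the best current
    vector for the updated belief, back-projected through T and O; the
    returned vector is the action-tagged maximizer of <., b>.
    """
    b = np.asarray(b, dtype=float)
    Alpha = current.vectors  # (K, S)
    O = model.O  # (S, Z)
    best_val = -np.inf
    best_vec: Optional[np.ndarray] = None
    best_action = 0
    for a in range(model.n_actions):
        Ta = model.T[:, a, :]  # (S, S')
        b_pred = b @ Ta  # (S',)
        U = O * b_pred[:, None]  # (S', Z): P(s', z | b, a) up to normalization
        scores = Alpha @ U  # (K, Z): <alpha_k, u_z>
        kstar = scores.argmax(axis=0)  # (Z,)
        # W(s') = Σ_z O(s', z) alpha_{k*(z)}(s')
        W = (O * Alpha[kstar].T).sum(axis=1)  # (S',)
        g = model.R + model.gamma * (Ta @ W)  # (S,)
        val = float(g @ b)
        if val > best_val:
            best_val, best_vec, best_action = val, g, a
    assert best_vec is not None
    return best_vec, best_action


def sample_beliefs(
    model: PomdpModel,
    n: int,
    horizon: int = 30,
    seed: int = 42,
    include_corners: bool = False,
    max_attempts: int = 200,
) -> np.ndarray:
    """Collect reachable beliefs by forward simulation under random actions.

    Trajectories start at ``b0``; the latent state is simulated so that
    observations are drawn from the model.  Returns an (n, S) matrix whose
    first row is ``b0``; beliefs are distinct up to 1e-12 rounding.  If the
    model's reachable belief set is smaller than ``n`` (e.g. identity
    observations), fewer rows are returned.
    """
    rng = np.random.default_rng(seed)
    S = model.n_states
    beliefs: list[np.ndarray] = [model.b0.copy()]
    seen = {tuple(np.round(model.b0, 12))}
    if include_corners:
        for s in range(S):
            corner = np.zeros(S)
            corner[s] = 1.0
            key = tuple(np.round(corner, 12))
            if key not in seen:
                seen.add(key)
                beliefs.append(corner)
    attempts = 0
    while len(beliefs) < n and attempts < max_attempts:
        attempts += 1
        b = model.b0.copy()
        s = int(rng.choice(S, p=model.b0))
        for _ in range(horizon):
            a = int(rng.integers(model.n_actions))
            s = int(rng.choice(S, p=model.T[s, a]))
            z = int(rng.choice(model.n_observations, p=model.O[s]))
            try:
                b, _ = belief_update(b, a, z, model)
            except InconsistentObservationError:  # pragma: no cover
                break
            key = tuple(np.round(b, 12))
            if key not in seen:
                seen.add(key)
                beliefs.append(b.copy())
            if len(beliefs) >= n:
                break
    return np.asarray(beliefs[:max(n, 1)] if len(beliefs) >= n else beliefs)


def perseus_solve(
    model: PomdpModel,
    beliefs: np.ndarray,
    tolerance: Optional[float] = None,
    max_iterations: int = 1000,
    seed: int = 42,
) -> AlphaVectorPolicy:
    """Randomized point-based value iteration over a fixed belief set.

    Each stage repeatedly picks a random not-yet-improved belief, backs it
    up, and drops every belief whose value the new vector already improves;
    the stage ends when all beliefs improved.  Stops when the largest value
    change across beliefs falls below ``tolerance`` (default
    1e-3 * max|R|) or after ``max_iterations`` stages (warning + flag).
    """
    beliefs = np.atleast_2d(np.asarray(beliefs, dtype=float))
    if beliefs.shape[0] == 0:
        raise ValueError("belief set must be non-empty")
    if tolerance is None:
        tolerance = 1e-3 * float(np.abs(model.R).max())
    rng = np.random.default_rng(seed)

    policy = _initial_policy(model)
    V = policy.values(beliefs)
    eps = 1e-9 * max(1.0, float(np.abs(model.R).max()))
    converged = False
    stage = 0
    for stage in range(1, max_iterations + 1):
        new_vectors: list[np.ndarray] = []
        new_actions: list[int] = []
        improved = np.zeros(len(beliefs), dtype=bool)
        while not improved.all():
            candidates = np.flatnonzero(~improved)
            i = int(rng.choice(candidates))
            vec, action = point_based_backup(beliefs[i], policy, model)
            if vec @ beliefs[i] >= V[i] - eps:
                new_vectors.append(vec)
                new_actions.append(action)
            else:
                # keep the previous best vector for this belief (Perseus rule)
                k = int(np.argmax(policy.vectors @ beliefs[i]))
                new_vectors.append(policy.vectors[k].copy())
                new_actions.append(int(policy.actions[k]))
            vals = beliefs @ np.asarray(new_vectors).T
            improved = vals.max(axis=1) >= V - eps

        vectors = np.asarray(new_vectors)
        actions = np.asarray(new_actions, dtype=int)
        # deduplicate identical vectors
        _, unique_idx = np.unique(np.round(vectors, 10), axis=0, return_index=True)
        unique_idx.sort()
        policy = AlphaVectorPolicy(vectors[unique_idx], actions[unique_idx], stage=stage)
        V_new = policy.values(beliefs)
        if (V_new < V - eps).any():  # pragma: no cover - Perseus guarantee
            raise AssertionError("Perseus stage decreased a belief value")
        delta = float(np.max(V_new - V))
        V = V_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Perseus did not converge in {max_iterations} stages", RuntimeWarning
        )
    policy.converged = converged
    policy.stage = stage
    policy.metadata = {"tolerance": tolerance, "seed": seed, "gamma": model.gamma}
    return policy


def extract_action(
    policy: AlphaVectorPolicy, b: np.ndarray
) -> tuple[int, float, Optional[int]]:
    """Best action at belief ``b``, its value, and the runner-up action.

    Ties break toward the lowest action index.  The runner-up is the best
    action different from the first, or ``None`` if the policy's vectors all
    carry one action.
    """
    b = np.asarray(b, dtype=float)
    vals = policy.vectors @ b
    best_per_action: dict[int, float] = {}
    for action, value in zip(policy.actions, vals):
        a = int(action)
        if a not in best_per_action or value > best_per_action[a]:
            best_per_action[a] = float(value)
    best_action = min(
        best_per_action, key=lambda a: (-best_per_action[a], a)
    )
    others = {a: v for a, v in best_per_action.items() if a != best_action}
    runner_up = (
        min(others, key=lambda a: (-others[a], a)) if others else None
    )
    return best_action, best_per_action[best_action], runner_up
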