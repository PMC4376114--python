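"""Estimation of transition and observation models from labeled trajectories.

Transition probabilities are plain frequencies of (state, action, next state)
patterns within each (state, action) pair.  The observation model factorizes
per state: each of the five vitals gets a five-bin distribution obtained by
fitting a parametric family (normal / lognormal / gamma, AIC-selected) and
integrating its density over equal-width bins spanning the observed min-max
range; the blood culture is a per-state Bernoulli.  The joint probability of
an observation code is the product of its six factors.

Bin edges are pooled across states (state-unconditional min-max) so that a
raw snapshot maps to a single well-defined observation code regardless of
the latent state; per-state fits then assign each state its own bin masses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .states import (
    ABSORBING_STATES,
    N_ACTIONS,
    N_OBSERVATIONS,
    N_VITAL_BINS,
    OBSERVATION_VITALS,
    Culture,
    ObservationCode,
    StateLabel,
    VitalsSnapshot,
    observation_index,
)

__all__ = [
    "NoDataError",
    "DegenerateDataError",
    "SparseDataWarning",
    "TransitionModel",
    "VitalFit",
    "BinningScheme",
    "ObservationModel",
    "estimate_transitions",
    "fit_vital_distribution",
    "build_binning",
    "estimate_observation_model",
]

N_STATES = len(StateLabel)
MIN_FIT_SAMPLES = 10


class NoDataError(ValueError):
    """Raised when an estimator receives no data at all."""


class DegenerateDataError(ValueError):
    """Raised on zero-variance or zero-width inputs."""


class SparseDataWarning(UserWarning):
    """Emitted when a bin or state has too few samples for a reliable fit."""


# --------------------------------------------------------------------------
# Transition model
# --------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """P(next | state, action) with the supporting counts.

    ``backed_off[s, a]`` marks rows that had no data and were filled with the
    action-marginalized row for ``s`` (or uniform over non-absorbing states
    when ``s`` itself was never observed).  Absorbing states are exact unit
    self-loops for every action.
    """

    probabilities: np.ndarray  # (S, A, S)
    support_counts: np.ndarray  # (S, A, S), ints
    backed_off: np.ndarray  # (S, A), bool

    @property
    def n_states(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_actions(self) -> int:
        return self.probabilities.shape[1]

    def validate(self, atol: float = 1e-12) -> None:
        rows = self.probabilities.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("transition rows do not sum to 1")
        if (self.probabilities < -atol).any():
            raise ValueError("negative transition probability")

    def to_json(self, path=None) -> dict:
        payload = {
            "probabilities": self.probabilities.tolist(),
            "support_counts": self.support_counts.tolist(),
            "backed_off": self.backed_off.tolist(),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh)
        return payload

    @classmethod
    def from_json(cls, payload) -> "TransitionModel":
        if not isinstance(payload, dict):
            with open(payload) as fh:
                payload = json.load(fh)
        return cls(
            probabilities=np.asarray(payload["probabilities"], dtype=float),
            support_counts=np.asarray(payload["support_counts"], dtype=int),
            backed_off=np.asarray(payload["backed_off"], dtype=bool),
        )


def estimate_transitions(
    triples: Iterable[tuple[int, int, int]],
    n_states: int = N_STATES,
    n_actions: int = N_ACTIONS,
    absorbing: Sequence[int] = tuple(int(s) for s in ABSORBING_STATES),
    laplace: float = 0.0,
    shrinkage: float = 0.0,
) -> TransitionModel:
    """Frequency-estimate the transition tensor from (s, a, s') triples.

    ``laplace`` adds the given pseudo-count to every cell of observed rows
    (0 = pure frequencies).  ``shrinkage`` adds that many pseudo-counts
    distributed as the state's action-marginalized row, shrinking sparsely
    observed (state, action) rows toward the state's average dynamics
    instead of toward uniform (uniform pseudo-counts leak probability onto
    the high-reward absorbing state and make sparse rows look optimistic).
    Unobserved (state, action) rows back off to the action-marginalized row;
    fully unobserved states get a uniform row over non-absorbing states.
    Absorbing rows are forced to unit self-loops.
    """
    counts = np.zeros((n_states, n_actions, n_states), dtype=np.int64)
    n = 0
    for s, a, s2 in triples:
        counts[s, a, s2] += 1
        n += 1
    if n == 0:
        raise NoDataError("no transition triples supplied")

    probs = np.zeros((n_states, n_actions, n_states), dtype=float)
    backed_off = np.zeros((n_states, n_actions), dtype=bool)
    absorbing = set(int(s) for s in absorbing)
    non_absorbing = [s for s in range(n_states) if s not in absorbing]

    marginal = counts.sum(axis=1)  # (S, S): pooled over actions
    for s in range(n_states):
        pooled = marginal[s].astype(float)
        prior = pooled / pooled.sum() if pooled.sum() > 0 else None
        for a in range(n_actions):
            row = counts[s, a].astype(float)
            total = row.sum()
            if total > 0:
                if laplace > 0:
                    row = row + laplace
                if shrinkage > 0 and prior is not None:
                    row = row + shrinkage * prior
                probs[s, a] = row / row.sum()
            else:
                backed_off[s, a] = True
                if prior is not None:
                    probs[s, a] = prior
                else:
                    probs[s, a, non_absorbing] = 1.0 / len(non_absorbing)

    for s in absorbing:
        probs[s, :, :] = 0.0
        probs[s, :, s] = 1.0
        backed_off[s, :] = False

    return TransitionModel(probs, counts, backed_off)


# --------------------------------------------------------------------------
# Vital distribution fitting
# --------------------------------------------------------------------------

_FAMILIES = ("normal", "lognormal", "gamma")


@dataclass
class VitalFit:
    """A fitted per-(state, vital) distribution with selection diagnostics."""

    family: str  # normal | lognormal | gamma | empirical
    params: tuple  # scipy frozen-dist parameters (family-specific)
    loglik: float
    aic: float
    n: int
    candidates: dict = field(default_factory=dict)  # family -> aic

    def frozen(self):
        """The scipy frozen distribution (None for empirical fallback)."""
        if self.family == "normal":
            return stats.norm(*self.params)
        if self.family == "lognormal":
            s, scale = self.params
            return stats.lognorm(s, 0.0, scale)
        if self.family == "gamma":
            a, scale = self.params
            return stats.gamma(a, 0.0, scale)
        return None

    def cdf(self, x):
        dist = self.frozen()
        if dist is None:
            raise ValueError("empirical fit has no parametric CDF")
        return dist.cdf(x)


def fit_vital_distribution(
    samples: Sequence[float],
    families: Sequence[str] = _FAMILIES,
) -> VitalFit:
    """Maximum-likelihood fit among candidate families, selected by AIC.

    Fewer than 10 samples trigger a :class:`SparseDataWarning` and an
    ``empirical`` fallback fit; constant-valued samples raise
    :class:`DegenerateDataError`.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise NoDataError("no samples to fit")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant-valued samples (zero variance)")
    if x.size < MIN_FIT_SAMPLES:
        warnings.warn(
            f"only {x.size} samples (<{MIN_FIT_SAMPLES}); falling back to empirical fit",
            SparseDataWarning,
            stacklevel=2,
        )
        return VitalFit("empirical", (), float("nan"), float("inf"), int(x.size))
    if (x <= 0).any() and ("lognormal" in families or "gamma" in families):
        families = tuple(f for f in families if f == "normal")

    results: dict[str, tuple[tuple, float]] = {}
    for family in families:
        try:
            if family == "normal":
                loc, scale = stats.norm.fit(x)
                if scale <= 0:
                    continue
                ll = stats.norm.logpdf(x, loc, scale).sum()
                results[family] = ((loc, scale), float(ll))
            elif family == "lognormal":
                s, _, scale = stats.lognorm.fit(x, floc=0)
                ll = stats.lognorm.logpdf(x, s, 0.0, scale).sum()
                results[family] = ((s, scale), float(ll))
            elif family == "gamma":
                a, _, scale = stats.gamma.fit(x, floc=0)
                ll = stats.gamma.logpdf(x, a, 0.0, scale).sum()
                results[family] = ((a, scale), float(ll))
            else:
                raise ValueError(f"unknown family: {family}")
        except (stats.FitError, ValueError, RuntimeError):  # pragma: no cover
            continue
    if not results:
        raise DegenerateDataError("no candidate family could be fitted")

    aics = {fam: 2 * 2 - 2 * ll for fam, (_, ll) in results.items()}
    best = min(aics, key=lambda fam: aics[fam])
    params, ll = results[best]
    return VitalFit(best, params, ll, aics[best], int(x.size), candidates=aics)


# --------------------------------------------------------------------------
# Binning
# --------------------------------------------------------------------------


@dataclass
class BinFactor:
    """Five bin probabilities for one (state, vital) pair."""

    probs: np.ndarray  # (5,)
    family: str
    n: int
    sparse: bool = False  # some estimation bin held <= 10 samples


@dataclass
class BinningScheme:
    """Equal-width five-bin discretization of each vital.

    ``edges[vital]`` holds six strictly increasing, equally spaced edges over
    the pooled observed min-max range of that vital.  ``factors[(state,
    vital)]`` holds the state's bin-mass distribution (fitted CDF mass per
    bin, renormalized over the range).  ``fallback_bin[vital]`` is the
    state-unconditional modal bin, used when a vital is missing at encoding
    time.
    """

    edges: dict[str, np.ndarray]
    factors: dict[tuple[StateLabel, str], BinFactor]
    fallback_bin: dict[str, int]

    def bin_of(self, vital: str, value: float) -> int:
        """Half-open bins [e_k, e_{k+1}), last closed; clamp out-of-range."""
        e = self.edges[vital]
        idx = int(np.searchsorted(e, value, side="right") - 1)
        return min(max(idx, 0), N_VITAL_BINS - 1)

    def encode(self, v: VitalsSnapshot) -> ObservationCode:
        """Discretize a snapshot into its observation code.

        Missing vitals map to the modal bin and are reported in the code's
        ``imputed`` field.
        """
        bins = []
        imputed = []
        for vital in OBSERVATION_VITALS:
            value = getattr(v, vital)
            if value is None:
                bins.append(self.fallback_bin[vital])
                imputed.append(vital)
            else:
                bins.append(self.bin_of(vital, value))
        flag = 1 if v.blood_culture is Culture.POSITIVE else 0
        bins_t = tuple(bins)
        return ObservationCode(bins_t, flag, observation_index(bins_t, flag), frozenset(imputed))

    def to_json(self, path=None) -> dict:
        payload = {
            "edges": {vital: e.tolist() for vital, e in self.edges.items()},
            "fallback_bin": dict(self.fallback_bin),
            "factors": [
                {
                    "state": state.name,
                    "vital": vital,
                    "probs": f.probs.tolist(),
                    "family": f.family,
                    "n": f.n,
                    "sparse": f.sparse,
                }
                for (state, vital), f in self.factors.items()
            ],
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh)
        return payload

    @classmethod
    def from_json(cls, payload) -> "BinningScheme":
        if not isinstance(payload, dict):
            with open(payload) as fh:
                payload = json.load(fh)
        return cls(
            edges={v: np.asarray(e, dtype=float) for v, e in payload["edges"].items()},
            factors={
                (StateLabel[f["state"]], f["vital"]): BinFactor(
                    np.asarray(f["probs"], dtype=float), f["family"], f["n"], f["sparse"]
                )
                for f in payload["factors"]
            },
            fallback_bin={v: int(b) for v, b in payload["fallback_bin"].items()},
        )


def _bin_edges(lo: float, hi: float) -> np.ndarray:
    if not hi > lo:
        raise DegenerateDataError(f"degenerate range [{lo}, {hi}]")
    return np.linspace(lo, hi, N_VITAL_BINS + 1)


def _bin_masses(fit: VitalFit, edges: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Fitted CDF mass per bin, renormalized over [min, max]; empirical fallback."""
    if fit is not None and fit.family != "empirical":
        cdf = fit.cdf(edges)
        masses = np.diff(cdf)
        total = masses.sum()
        if total > 0:
            return masses / total
    # empirical histogram fallback
    hist, _ = np.histogram(samples, bins=edges)
    hist = np.clip(hist, 0, None).astype(float)
    if hist.sum() == 0:
        return np.full(N_VITAL_BINS, 1.0 / N_VITAL_BINS)
    return hist / hist.sum()


def build_binning(
    samples: Mapping[tuple[StateLabel, str], Sequence[float]],
    fits: Optional[Mapping[tuple[StateLabel, str], VitalFit]] = None,
    edges: Optional[Mapping[str, Sequence[float]]] = None,
) -> BinningScheme:
    """Build the five-bin discretization and per-state bin masses.

    ``samples`` maps (state, vital) to raw measurements.  When ``fits`` is
    omitted each group is fitted with :func:`fit_vital_distribution`
    (empirical fallback on sparse groups).  ``edges`` can pin the per-vital
    ranges; by default they span the pooled min-max of each vital.
    """
    if fits is None:
        fits = {}
        for key, vals in samples.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SparseDataWarning)
                try:
                    fits[key] = fit_vital_distribution(vals)
                except (NoDataError, DegenerateDataError):
                    fits[key] = None

    pooled: dict[str, list[float]] = {vital: [] for vital in OBSERVATION_VITALS}
    for (_, vital), vals in samples.items():
        if vital in pooled:
            pooled[vital].extend(float(x) for x in vals)

    edge_map: dict[str, np.ndarray] = {}
    fallback: dict[str, int] = {}
    for vital in OBSERVATION_VITALS:
        if edges is not None and vital in edges:
            e = np.asarray(edges[vital], dtype=float)
            if e.shape != (N_VITAL_BINS + 1,) or (np.diff(e) <= 0).any():
                raise ValueError(f"invalid edges for {vital}")
        else:
            vals = np.asarray(pooled[vital], dtype=float)
            if vals.size == 0:
                raise NoDataError(f"no samples at all for vital {vital!r}")
            e = _bin_edges(vals.min(), vals.max())
        edge_map[vital] = e
        vals = np.asarray(pooled[vital], dtype=float)
        if vals.size:
            hist, _ = np.histogram(vals, bins=e)
            fallback[vital] = int(np.argmax(hist))
        else:
            fallback[vital] = N_VITAL_BINS // 2

    factors: dict[tuple[StateLabel, str], BinFactor] = {}
    for (state, vital), vals in samples.items():
        vals_arr = np.asarray(vals, dtype=float)
        fit = fits.get((state, vital))
        masses = _bin_masses(fit, edge_map[vital], vals_arr)
        hist, _ = np.histogram(vals_arr, bins=edge_map[vital])
        sparse = bool((hist <= MIN_FIT_SAMPLES).any())
        if sparse:
            warnings.warn(
                f"bin with <= {MIN_FIT_SAMPLES} samples for {state.name}/{vital}",
                SparseDataWarning,
                stacklevel=2,
            )
        factors[(state, vital)] = BinFactor(
            masses,
            fit.family if fit is not None else "empirical",
            int(vals_arr.size),
            sparse,
        )
    return BinningScheme(edge_map, factors, fallback)


# --------------------------------------------------------------------------
# Observation model
# --------------------------------------------------------------------------


@dataclass
class ObservationModel:
    """Factorized per-state observation distributions over the 6250 codes.

    ``factors[s, k, b]`` is P(vital k falls in bin b | state s);
    ``culture_rate[s]`` is P(blood flag = 1 | state s).  The joint mass of a
    code is the product of its six factors (conditional independence given
    the state).
    """

    factors: np.ndarray  # (S, 5, 5)
    culture_rate: np.ndarray  # (S,)
    uniform_states: tuple[int, ...] = ()  # states that had no snapshots

    @property
    def n_states(self) -> int:
        return self.factors.shape[0]

    def prob(self, state: int, code: ObservationCode) -> float:
        p = 1.0
        for k, b in enumerate(code.vital_bins):
            p *= self.factors[state, k, b]
        rate = self.culture_rate[state]
        p *= rate if code.blood_flag else (1.0 - rate)
        return float(p)

    def dense(self) -> np.ndarray:
        """The full (S, 6250) matrix O[s, z]; rows sum to 1 exactly."""
        S = self.n_states
        # index = blood*5^5 + sum bins[k]*5^k  => vital 0 varies fastest,
        # so fold vitals in from the most significant digit downwards
        out = np.ones((S, 1), dtype=float)
        for k in range(len(OBSERVATION_VITALS)):
            # vital k becomes the most significant digit folded so far:
            # index_so_far = bin_k * 5**k + previous
            f = self.factors[:, k, :]  # (S, 5)
            out = (f[:, :, None] * out[:, None, :]).reshape(S, -1)
        rate = self.culture_rate[:, None]
        return np.concatenate([(1.0 - rate) * out, rate * out], axis=1)

    def validate(self) -> None:
        if not np.allclose(self.factors.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("per-vital factors do not sum to 1")
        if ((self.culture_rate < 0) | (self.culture_rate > 1)).any():
            raise ValueError("culture rate outside [0, 1]")
        if not np.allclose(self.dense().sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("joint observation mass does not sum to 1")

    def to_json(self, path=None) -> dict:
        payload = {
            "factors": self.factors.tolist(),
            "culture_rate": self.culture_rate.tolist(),
            "uniform_states": list(self.uniform_states),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh)
        return payload

    @classmethod
    def from_json(cls, payload) -> "ObservationModel":
        if not isinstance(payload, dict):
            with open(payload) as fh:
                payload = json.load(fh)
        return cls(
            factors=np.asarray(payload["factors"], dtype=float),
            culture_rate=np.asarray(payload["culture_rate"], dtype=float),
            uniform_states=tuple(payload["uniform_states"]),
        )


def estimate_observation_model(
    snapshots_by_state: Mapping[StateLabel, Sequence[VitalsSnapshot]],
    binning: BinningScheme,
    empirical: bool = False,
) -> ObservationModel:
    """Build the factorized observation model.

    Per-vital factors come from the binning scheme's fitted bin masses (or
    raw empirical bin frequencies when ``empirical=True``); the culture rate
    is the per-state frequency of a positive result.  States without
    snapshots get uniform factors and a 0.5 culture rate, with a warning.
    """
    S = N_STATES
    factors = np.full((S, len(OBSERVATION_VITALS), N_VITAL_BINS), 1.0 / N_VITAL_BINS)
    rate = np.full(S, 0.5)
    uniform_states = []
    for state in StateLabel:
        snaps = snapshots_by_state.get(state, ())
        if len(snaps) == 0:
            if state not in ABSORBING_STATES:
                warnings.warn(
                    f"state {state.name} has no snapshots; using uniform factors",
                    SparseDataWarning,
                    stacklevel=2,
                )
            uniform_states.append(int(state))
            continue
        rate[state] = float(
            np.mean([s.blood_culture is Culture.POSITIVE for s in snaps])
        )
        for k, vital in enumerate(OBSERVATION_VITALS):
            if empirical:
                vals = [getattr(s, vital) for s in snaps if getattr(s, vital) is not None]
                if vals:
                    bins = [binning.bin_of(vital, x) for x in vals]
                    hist = np.bincount(bins, minlength=N_VITAL_BINS).astype(float)
                    factors[state, k] = hist / hist.sum()
                continue
            factor = binning.factors.get((state, vital))
            if factor is not None:
                factors[state, k] = factor.probs
    model = ObservationModel(factors, rate, tuple(uniform_states))
    model.validate()
    return model
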