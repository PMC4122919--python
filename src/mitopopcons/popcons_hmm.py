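"""mitoPopCons: two-state HMM segmentation of per-site allele counts.

The observation at every genome position is the number of distinct alleles
seen there (1–4; monomorphic sites emit 1).  The two hidden states are
"functional" (constrained: polymorphism depleted by purifying selection) and
"nonfunctional".  The transition matrix is fixed a priori, phastCons-style;
Baum–Welch learns the emission probabilities only — the transition M-step is
swamped with pseudocounts proportional to the fixed matrix so transitions
cannot drift.  Training restarts from random emission matrices several times
and keeps the highest-likelihood fit; the state more likely to emit
monomorphic sites is labeled functional, and Viterbi runs of that state are
the called elements.

The forward/backward/Viterbi recursions are hand-unrolled for the two-state
chain: a genome-length pass is a tight scalar loop, which keeps full-genome
Baum–Welch (10 restarts) and the downsampling power analysis fast without
any compiled extension.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ElementSet

N_STATES = 2
N_OBS = 4  # allele counts 1..4
EMISSION_FLOOR = 1e-10

__all__ = [
    "HmmParams",
    "TrainResult",
    "default_transition",
    "phastcons_transition",
    "stationary_distribution",
    "forward_loglik",
    "viterbi_decode",
    "viterbi_logprob",
    "baum_welch_train",
    "call_elements",
    "posterior_marginals",
]


def default_transition(stay: float = 0.99) -> np.ndarray:
    """Symmetric two-state transition matrix with the given stay probability.

    stay = 0.99 gives geometric state runs of expected length 100 bp, the
    scale of the elements this method is meant to call.
    """
    if not 0 < stay < 1:
        raise ValueError("stay probability must lie in (0, 1)")
    return np.array([[stay, 1 - stay], [1 - stay, stay]])


def phastcons_transition(expected_element_length: float, expected_coverage: float) -> np.ndarray:
    """Transition matrix from the (omega, gamma) parametrization.

    ``expected_element_length`` (omega) is the mean length of a constrained
    element; ``expected_coverage`` (gamma) the stationary fraction of the
    genome in the constrained state.  State 0 is constrained.
    """
    if expected_element_length <= 1:
        raise ValueError("expected element length must exceed 1 bp")
    if not 0 < expected_coverage < 1:
        raise ValueError("expected coverage must lie in (0, 1)")
    mu = 1.0 / expected_element_length  # P(leave constrained)
    # stationary coverage gamma = nu / (mu + nu) => nu = mu * gamma / (1 - gamma)
    nu = mu * expected_coverage / (1.0 - expected_coverage)
    if nu >= 1:
        raise ValueError("parameters imply a leave-probability >= 1")
    return np.array([[1 - mu, mu], [nu, 1 - nu]])


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2-state row-stochastic matrix."""
    a, b = transition[0, 1], transition[1, 0]
    if a + b == 0:
        return np.array([0.5, 0.5])
    return np.array([b / (a + b), a / (a + b)])


@dataclass
class HmmParams:
    transition: np.ndarray  # (2, 2) row-stochastic
    emission: np.ndarray  # (2, 4) row-stochastic over allele counts 1..4
    initial: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        for name, mat, shape in (
            ("transition", self.transition, (N_STATES, N_STATES)),
            ("emission", self.emission, (N_STATES, N_OBS)),
            ("initial", self.initial[None, :], (1, N_STATES)),
        ):
            if mat.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if (mat < 0).any():
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1")

    def to_json(self, path) -> None:
        payload = {
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
            "initial": self.initial.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HmmParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.array(payload["transition"]),
            np.array(payload["emission"]),
            np.array(payload["initial"]),
        )


@dataclass
class TrainResult:
    params: HmmParams
    log_likelihood: float
    restart_log_likelihoods: list[float]
    restart_iterations: list[int]
    seed: int
    functional_state: int
    log_likelihood_traces: list[list[float]] = field(default_factory=list)


def _check_observations(observations) -> list[int]:
    obs = np.asarray(observations, dtype=np.int64)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observations must be a non-empty 1-D sequence")
    if obs.min() < 1 or obs.max() > N_OBS:
        raise ValueError("observations must be allele counts in 1..4")
    return (obs - 1).tolist()  # 0-based symbols, python ints for the scalar loops


def forward_loglik(params: HmmParams, observations) -> float:
    """log P(observations | params) via the scaled forward recursion."""
    obs = _check_observations(observations)
    e0 = params.emission[0].tolist()
    e1 = params.emission[1].tolist()
    (a00, a01), (a10, a11) = params.transition.tolist()
    pi0, pi1 = params.initial.tolist()
    log = math.log
    f0 = pi0 * e0[obs[0]]
    f1 = pi1 * e1[obs[0]]
    s = f0 + f1
    if s <= 0:
        return float("-inf")
    ll = log(s)
    f0 /= s
    f1 /= s
    for o in obs[1:]:
        g0 = (f0 * a00 + f1 * a10) * e0[o]
        g1 = (f0 * a01 + f1 * a11) * e1[o]
        s = g0 + g1
        if s <= 0:
            return float("-inf")
        ll += log(s)
        f0 = g0 / s
        f1 = g1 / s
    return float(ll)


def _forward_backward(transition, emission, initial, obs: list[int]):
    """Scaled forward-backward, two states unrolled.

    Returns (loglik, symbol_counts (2, 4), xi_sum (2, 2)) — the sufficient
    statistics for the Baum–Welch M-step.
    """
    T = len(obs)
    e0 = emission[0].tolist()
    e1 = emission[1].tolist()
    (a00, a01), (a10, a11) = transition.tolist()
    pi0, pi1 = initial.tolist()
    log = math.log

    alphas0 = [0.0] * T
    alphas1 = [0.0] * T
    scales = [0.0] * T
    f0 = pi0 * e0[obs[0]]
    f1 = pi1 * e1[obs[0]]
    s = f0 + f1
    ll = log(s)
    f0 /= s
    f1 /= s
    alphas0[0], alphas1[0], scales[0] = f0, f1, s
    for t in range(1, T):
        o = obs[t]
        g0 = (f0 * a00 + f1 * a10) * e0[o]
        g1 = (f0 * a01 + f1 * a11) * e1[o]
        s = g0 + g1
        ll += log(s)
        f0 = g0 / s
        f1 = g1 / s
        alphas0[t], alphas1[t], scales[t] = f0, f1, s

    counts0 = [0.0] * N_OBS
    counts1 = [0.0] * N_OBS
    xi00 = xi01 = xi10 = xi11 = 0.0
    b0 = b1 = 1.0
    o = obs[T - 1]
    counts0[o] += alphas0[T - 1]
    counts1[o] += alphas1[T - 1]
    for t in range(T - 2, -1, -1):
        o_next = obs[t + 1]
        sc = scales[t + 1]
        eb0 = e0[o_next] * b0 / sc
        eb1 = e1[o_next] * b1 / sc
        f0 = alphas0[t]
        f1 = alphas1[t]
        xi00 += f0 * a00 * eb0
        xi01 += f0 * a01 * eb1
        xi10 += f1 * a10 * eb0
        xi11 += f1 * a11 * eb1
        b0 = a00 * eb0 + a01 * eb1
        b1 = a10 * eb0 + a11 * eb1
        g0 = f0 * b0
        g1 = f1 * b1
        norm = g0 + g1
        o = obs[t]
        counts0[o] += g0 / norm
        counts1[o] += g1 / norm
    symbol_counts = np.array([counts0, counts1])
    xi_sum = np.array([[xi00, xi01], [xi10, xi11]])
    return float(ll), symbol_counts, xi_sum


def viterbi_decode(params: HmmParams, observations) -> np.ndarray:
    """Maximum-probability state path; ties break toward the lower state index."""
    obs = _check_observations(observations)
    T = len(obs)
    neginf = float("-inf")

    def safe_log(p: float) -> float:
        return math.log(p) if p > 0 else neginf

    le0 = [safe_log(p) for p in params.emission[0]]
    le1 = [safe_log(p) for p in params.emission[1]]
    (a00, a01), (a10, a11) = params.transition.tolist()
    la00, la01, la10, la11 = safe_log(a00), safe_log(a01), safe_log(a10), safe_log(a11)
    d0 = safe_log(params.initial[0]) + le0[obs[0]]
    d1 = safe_log(params.initial[1]) + le1[obs[0]]
    back = bytearray(T)
    for t in range(1, T):
        o = obs[t]
        from00 = d0 + la00
        from10 = d1 + la10
        from01 = d0 + la01
        from11 = d1 + la11
        # ties break toward the lower-index predecessor
        if from00 >= from10:
            b0, v0 = 0, from00
        else:
            b0, v0 = 1, from10
        if from01 >= from11:
            b1, v1 = 0, from01
        else:
            b1, v1 = 1, from11
        back[t] = b0 | (b1 << 1)
        d0 = v0 + le0[o]
        d1 = v1 + le1[o]
    path = np.empty(T, dtype=np.int8)
    state = 0 if d0 >= d1 else 1
    path[T - 1] = state
    for t in range(T - 1, 0, -1):
        state = (back[t] >> state) & 1
        path[t - 1] = state
    return path


def viterbi_logprob(params: HmmParams, observations) -> float:
    """Log joint probability of the Viterbi path and the observations."""
    obs = np.asarray(observations, dtype=np.int64) - 1
    path = viterbi_decode(params, observations)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        logE = np.log(params.emission)
        logpi = np.log(params.initial)
    lp = logpi[path[0]] + logE[path[0], obs[0]]
    lp += logA[path[:-1], path[1:]].sum() + logE[path[1:], obs[1:]].sum()
    return float(lp)


def posterior_marginals(params: HmmParams, observations) -> np.ndarray:
    """Per-site posterior state probabilities (for inspection, not calling)."""
    obs = _check_observations(observations)
    T = len(obs)
    e0 = params.emission[0].tolist()
    e1 = params.emission[1].tolist()
    (a00, a01), (a10, a11) = params.transition.tolist()
    alphas0 = [0.0] * T
    alphas1 = [0.0] * T
    scales = [0.0] * T
    f0 = params.initial[0] * e0[obs[0]]
    f1 = params.initial[1] * e1[obs[0]]
    s = f0 + f1
    f0, f1 = f0 / s, f1 / s
    alphas0[0], alphas1[0], scales[0] = f0, f1, s
    for t in range(1, T):
        o = obs[t]
        g0 = (f0 * a00 + f1 * a10) * e0[o]
        g1 = (f0 * a01 + f1 * a11) * e1[o]
        s = g0 + g1
        f0, f1 = g0 / s, g1 / s
        alphas0[t], alphas1[t], scales[t] = f0, f1, s
    gamma = np.empty((T, 2))
    b0 = b1 = 1.0
    gamma[T - 1] = alphas0[T - 1], alphas1[T - 1]
    for t in range(T - 2, -1, -1):
        o_next = obs[t + 1]
        sc = scales[t + 1]
        eb0 = e0[o_next] * b0 / sc
        eb1 = e1[o_next] * b1 / sc
        b0 = a00 * eb0 + a01 * eb1
        b1 = a10 * eb0 + a11 * eb1
        g0 = alphas0[t] * b0
        g1 = alphas1[t] * b1
        norm = g0 + g1
        gamma[t] = g0 / norm, g1 / norm
    return gamma


def baum_welch_train(
    observations,
    fixed_transition: np.ndarray | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    pseudocount_scale: float = 1e12,
) -> TrainResult:
    """Emission-only Baum–Welch with random restarts under fixed transitions.

    Each restart initializes both emission rows from a symmetric Dirichlet
    (seeded ``seed + restart``) and runs EM; the transition M-step adds
    ``pseudocount_scale x fixed_transition`` pseudocounts to the expected
    transition counts so the matrix stays within ~T/pseudocount_scale of its
    fixed value.  The initial distribution is held at the stationary
    distribution of the fixed matrix.  The restart with the highest final
    log-likelihood wins; the state with the higher probability of emitting
    monomorphic sites (observation 1) is the functional state.
    """
    obs = _check_observations(observations)
    if fixed_transition is None:
        fixed_transition = default_transition()
    A_fixed = np.asarray(fixed_transition, dtype=float)
    if A_fixed.shape != (N_STATES, N_STATES) or not np.allclose(A_fixed.sum(axis=1), 1.0):
        raise ValueError("fixed_transition must be a 2x2 row-stochastic matrix")
    initial = stationary_distribution(A_fixed)

    if len(set(obs)) == 1:
        warnings.warn(
            "all observations identical: states are not identifiable; "
            "emissions will converge to equal rows",
            stacklevel=2,
        )

    best: tuple[float, HmmParams] | None = None
    restart_lls: list[float] = []
    restart_iters: list[int] = []
    traces: list[list[float]] = []
    pseudo = pseudocount_scale * A_fixed

    for restart in range(n_restarts):
        rng = np.random.default_rng(seed + restart)
        emission = rng.dirichlet(np.ones(N_OBS), size=N_STATES)
        transition = A_fixed.copy()
        prev_ll = -np.inf
        trace: list[float] = []
        iterations = 0
        for iterations in range(1, max_iter + 1):
            ll, symbol_counts, xi_sum = _forward_backward(transition, emission, initial, obs)
            trace.append(ll)
            if iterations > 1 and ll - prev_ll < tol:
                break
            prev_ll = ll
            # M-step: emissions from expected symbol counts, floored
            emission = symbol_counts / symbol_counts.sum(axis=1, keepdims=True)
            emission = np.maximum(emission, EMISSION_FLOOR)
            emission /= emission.sum(axis=1, keepdims=True)
            # M-step: transitions frozen by pseudocounts
            trans_counts = pseudo + xi_sum
            transition = trans_counts / trans_counts.sum(axis=1, keepdims=True)
        params = HmmParams(transition, emission, initial.copy())
        final_ll = trace[-1]
        restart_lls.append(final_ll)
        restart_iters.append(iterations)
        traces.append(trace)
        if best is None or final_ll > best[0]:
            best = (final_ll, params)

    best_ll, best_params = best
    functional_state = int(np.argmax(best_params.emission[:, 0]))
    return TrainResult(
        params=best_params,
        log_likelihood=best_ll,
        restart_log_likelihoods=restart_lls,
        restart_iterations=restart_iters,
        seed=seed,
        functional_state=functional_state,
        log_likelihood_traces=traces,
    )


def call_elements(path: np.ndarray, functional_state: int, genome_length: int) -> ElementSet:
    """Maximal runs of the functional state, as half-open intervals."""
    path = np.asarray(path)
    if len(path) != genome_length:
        raise ValueError("state path length must equal genome length")
    hits = np.asarray(path == functional_state, dtype=np.int8)
    diff = np.diff(np.concatenate(([0], hits, [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ElementSet(
        genome_length,
        starts,
        ends,
        [f"mitoPopCons_{i + 1}" for i in range(len(starts))],
        source="polymorphism-HMM",
    )
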