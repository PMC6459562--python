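"""Monte Carlo death-birth dynamics on edge-typed graphs.

Implements the finite-population process the analytic machinery predicts:
in each elementary event a uniformly random individual reconsiders its
strategy and imitates one of its k neighbors with probability proportional
to fitness F = 1 - omega + omega * payoff, where the payoff is the single
multiplayer-game payoff of that neighbor's current neighborhood
configuration.  Provides fixation-probability estimation from single
mutants, per-generation drift estimation of the cooperator frequency, and
an exact absorbing-Markov-chain oracle for tiny graphs.

The chain kernels are compiled with numba; one generation is N elementary
events.  Replicates use per-run seeds derived from the master seed by
fixed offsets, so results are reproducible run by run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numba as nb
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .graphs import EdgeTypedGraph, neighborhood_config
from .payoffs import PayoffTensor

__all__ = [
    "SimConfig",
    "FixationEstimate",
    "DriftEstimate",
    "SimState",
    "evaluate_payoffs",
    "death_birth_step",
    "estimate_fixation",
    "estimate_delta_p",
    "exact_fixation",
]


@dataclass(frozen=True)
class SimConfig:
    omega: float = 0.01
    runs: int = 1000
    seed: int = 0
    max_generations: int = 10_000  # cap: max_generations * N elementary events

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if self.runs < 1:
            raise ValueError("need at least one run")


@dataclass(frozen=True)
class FixationEstimate:
    rho_A: float
    rho_B: float
    se_A: float
    se_B: float
    runs: int
    cap_hits_A: int = 0
    cap_hits_B: int = 0
    warning: str | None = None


@dataclass(frozen=True)
class DriftEstimate:
    p_target: float
    p_before: float  # realized mean frequency entering the measured generation
    delta_p: float
    se: float
    reps: int


def _tensor_arrays(tensor: PayoffTensor):
    g = tensor.profile.g
    strides = np.empty(len(g), dtype=np.int64)
    size = 1
    for t, gt in enumerate(g):
        strides[t] = size
        size *= gt + 1
    atab = np.empty(size, dtype=np.float64)
    btab = np.empty(size, dtype=np.float64)
    for c in tensor.profile.configurations():
        code = int(sum(ci * si for ci, si in zip(c, strides)))
        atab[code] = tensor.a[c]
        btab[code] = tensor.b[c]
    return strides, atab, btab


def _check_fitness(tensor: PayoffTensor, omega: float) -> None:
    worst = 1.0 - omega + omega * tensor.min_payoff()
    if omega > 0 and worst <= 0:
        raise ValueError(
            f"fitness positivity violated: 1 - omega + omega*min_payoff = {worst:g}"
        )


def _graph_tensor_arrays(graph: EdgeTypedGraph, tensor: PayoffTensor):
    if graph.profile.g != tensor.profile.g:
        raise ValueError("tensor profile does not match graph profile")
    nbr, typ = graph.as_arrays()
    strides, atab, btab = _tensor_arrays(tensor)
    return nbr, typ, strides, atab, btab


# ---------------------------------------------------------------------------
# python-level single-step machinery (unit-testable, mirrors the kernels)
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """Mutable population state: per-node strategy (1 = A) and A-count."""

    strategies: np.ndarray
    n_A: int = field(init=False)

    def __post_init__(self) -> None:
        self.strategies = np.asarray(self.strategies, dtype=np.int8)
        self.n_A = int(self.strategies.sum())


def evaluate_payoffs(
    graph: EdgeTypedGraph, strategies: Sequence[int], tensor: PayoffTensor
) -> np.ndarray:
    """Per-node payoff from the single game in the node's neighborhood."""
    if graph.profile.g != tensor.profile.g:
        raise ValueError("tensor profile does not match graph profile")
    out = np.empty(graph.N, dtype=float)
    for v in range(graph.N):
        c = neighborhood_config(graph, v, strategies)
        out[v] = tensor.a[c] if strategies[v] else tensor.b[c]
    return out


def death_birth_step(
    graph: EdgeTypedGraph,
    state: SimState,
    tensor: PayoffTensor,
    omega: float,
    rng: np.random.Generator,
) -> int:
    """One elementary event: a random node imitates a fitness-chosen neighbor.

    Returns the updated node's index.  Adoption probability of neighbor j
    is F_j / sum_{l in neighbors} F_l.
    """
    _check_fitness(tensor, omega)
    i = int(rng.integers(graph.N))
    payoffs = evaluate_payoffs(graph, state.strategies, tensor)
    nbrs = [v for v, _ in graph.neighbors(i)]
    fitness = 1.0 - omega + omega * payoffs[nbrs]
    if np.any(fitness <= 0):
        raise RuntimeError("non-positive fitness encountered")
    j = nbrs[int(rng.choice(len(nbrs), p=fitness / fitness.sum()))]
    new = state.strategies[j]
    if new != state.strategies[i]:
        state.n_A += 1 if new else -1
        state.strategies[i] = new
    return i


# ---------------------------------------------------------------------------
# numba chain kernels
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def _init_configs(nbr, typ, strides, strat, cfg):
    N, k = nbr.shape
    for i in range(N):
        code = 0
        for j in range(k):
            if strat[nbr[i, j]] == 1:
                code += strides[typ[i, j]]
        cfg[i] = code


@nb.njit(cache=True)
def _steps(nbr, typ, strides, atab, btab, omega, strat, cfg, n_A, n_steps):
    """Run n_steps elementary events; returns updated A-count."""
    N, k = nbr.shape
    for _ in range(n_steps):
        if n_A == 0 or n_A == N:
            break
        i = np.random.randint(0, N)
        tot = 0.0
        for j in range(k):
            u = nbr[i, j]
            pay = atab[cfg[u]] if strat[u] == 1 else btab[cfg[u]]
            tot += 1.0 - omega + omega * pay
        r = np.random.random() * tot
        acc = 0.0
        chosen = nbr[i, k - 1]
        for j in range(k):
            u = nbr[i, j]
            pay = atab[cfg[u]] if strat[u] == 1 else btab[cfg[u]]
            acc += 1.0 - omega + omega * pay
            if acc >= r:
                chosen = u
                break
        new = strat[chosen]
        if new != strat[i]:
            delta = 1 if new == 1 else -1
            strat[i] = new
            n_A += delta
            for j in range(k):
                cfg[nbr[i, j]] += delta * strides[typ[i, j]]
    return n_A


@nb.njit(cache=True)
def _fixation_batch(nbr, typ, strides, atab, btab, omega, runs, seed, cap, mutant_is_A):
    N, k = nbr.shape
    strat = np.empty(N, dtype=np.int8)
    cfg = np.empty(N, dtype=np.int64)
    fixed = 0
    cap_hits = 0
    resident = np.int8(0) if mutant_is_A else np.int8(1)
    mutant = np.int8(1) - resident
    for run in range(runs):
        np.random.seed(seed + run)
        for i in range(N):
            strat[i] = resident
        strat[np.random.randint(0, N)] = mutant
        _init_configs(nbr, typ, strides, strat, cfg)
        n_A = 1 if mutant_is_A else N - 1
        n_A = _steps(nbr, typ, strides, atab, btab, omega, strat, cfg, n_A, cap)
        if n_A != 0 and n_A != N:
            cap_hits += 1
        elif (mutant_is_A and n_A == N) or ((not mutant_is_A) and n_A == 0):
            fixed += 1
    return fixed, cap_hits


@nb.njit(cache=True)
def _drift_batch(nbr, typ, strides, atab, btab, omega, reps, seed, p, relax_steps):
    N, k = nbr.shape
    strat = np.empty(N, dtype=np.int8)
    cfg = np.empty(N, dtype=np.int64)
    s_dp = 0.0
    s_dp2 = 0.0
    s_p0 = 0.0
    for rep in range(reps):
        np.random.seed(seed + rep)
        n_A = 0
        for i in range(N):
            strat[i] = np.int8(1) if np.random.random() < p else np.int8(0)
            n_A += strat[i]
        _init_configs(nbr, typ, strides, strat, cfg)
        n_A = _steps(nbr, typ, strides, atab, btab, omega, strat, cfg, n_A, relax_steps)
        n0 = n_A
        n_A = _steps(nbr, typ, strides, atab, btab, omega, strat, cfg, n_A, N)
        dp = (n_A - n0) / N
        s_dp += dp
        s_dp2 += dp * dp
        s_p0 += n0 / N
    return s_dp, s_dp2, s_p0


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def estimate_fixation(
    graph: EdgeTypedGraph, tensor: PayoffTensor, config: SimConfig
) -> FixationEstimate:
    """Monte Carlo fixation probabilities of single A- and B-mutants.

    Each run places one mutant at a uniformly random node and iterates
    death-birth events to absorption (or the generation cap).  A- and
    B-mutant batches use paired per-run seeds.
    """
    _check_fitness(tensor, config.omega)
    nbr, typ, strides, atab, btab = _graph_tensor_arrays(graph, tensor)
    cap = config.max_generations * graph.N
    fix_A, caps_A = _fixation_batch(
        nbr, typ, strides, atab, btab, config.omega,
        config.runs, config.seed, cap, True,
    )
    fix_B, caps_B = _fixation_batch(
        nbr, typ, strides, atab, btab, config.omega,
        config.runs, config.seed, cap, False,
    )
    rho_A = fix_A / config.runs
    rho_B = fix_B / config.runs
    warning = None
    if max(caps_A, caps_B) > 0.01 * config.runs:
        warning = (
            f"{max(caps_A, caps_B)} of {config.runs} runs hit the generation "
            f"cap ({config.max_generations} generations)"
        )
    return FixationEstimate(
        rho_A=rho_A,
        rho_B=rho_B,
        se_A=math.sqrt(rho_A * (1 - rho_A) / config.runs),
        se_B=math.sqrt(rho_B * (1 - rho_B) / config.runs),
        runs=config.runs,
        cap_hits_A=caps_A,
        cap_hits_B=caps_B,
        warning=warning,
    )


def estimate_delta_p(
    graph: EdgeTypedGraph,
    tensor: PayoffTensor,
    config: SimConfig,
    p_grid: Sequence[float],
    reps: int,
    relax_generations: int = 10,
) -> list[DriftEstimate]:
    """Mean one-generation change of the A-frequency along a p grid.

    Each replicate draws an independent Bernoulli(p) strategy assignment,
    runs ``relax_generations`` generations so the local (pair)
    correlations the analytic drift presumes can build up, records the
    realized frequency, then measures the change over one further
    generation (N elementary events).  Reported per grid point: the mean
    realized starting frequency, the mean change and its standard error.
    """
    _check_fitness(tensor, config.omega)
    nbr, typ, strides, atab, btab = _graph_tensor_arrays(graph, tensor)
    out = []
    for idx, p in enumerate(p_grid):
        if not 0 < p < 1:
            raise ValueError("p grid must lie in (0, 1)")
        s_dp, s_dp2, s_p0 = _drift_batch(
            nbr, typ, strides, atab, btab, config.omega,
            reps, config.seed + idx * reps, float(p),
            relax_generations * graph.N,
        )
        mean = s_dp / reps
        var = max(s_dp2 / reps - mean * mean, 0.0)
        out.append(
            DriftEstimate(
                p_target=float(p),
                p_before=s_p0 / reps,
                delta_p=mean,
                se=math.sqrt(var / reps),
                reps=reps,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exact absorbing-chain oracle
# ---------------------------------------------------------------------------


def exact_fixation(
    graph: EdgeTypedGraph, tensor: PayoffTensor, omega: float
) -> tuple[float, float]:
    """Exact (rho_A, rho_B) by solving the full 2^N absorption system.

    Enumerates all strategy assignments, builds the one-event transition
    matrix of the death-birth chain and solves for the probability of
    reaching all-A from every state; fixation probabilities average over
    the N single-mutant starting states.  Limited to N <= 12.
    """
    N = graph.N
    if N > 12:
        raise ValueError("exact oracle limited to N <= 12 (state space 2^N)")
    _check_fitness(tensor, omega)
    nbr, typ = graph.as_arrays()
    strides, atab, btab = _tensor_arrays(tensor)
    k = graph.profile.k
    n_states = 1 << N
    full = n_states - 1

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_states)
    for s in range(n_states):
        if s == 0 or s == full:
            rows.append(s), cols.append(s), vals.append(1.0)
            rhs[s] = 1.0 if s == full else 0.0
            continue
        strat = [(s >> v) & 1 for v in range(N)]
        cfg = [
            sum(strides[typ[v, j]] for j in range(k) if strat[nbr[v, j]])
            for v in range(N)
        ]
        # h(s) = sum_t P(s->t) h(t)  ->  (I - P) h = 0 with absorbing rows
        probs: dict[int, float] = {}
        for i in range(N):
            fits = np.empty(k)
            for j in range(k):
                u = nbr[i, j]
                pay = atab[cfg[u]] if strat[u] else btab[cfg[u]]
                fits[j] = 1.0 - omega + omega * pay
            if np.any(fits <= 0):
                raise RuntimeError("non-positive fitness encountered")
            fits /= fits.sum()
            for j in range(k):
                u = nbr[i, j]
                t = (s | (1 << i)) if strat[u] else (s & ~(1 << i))
                probs[t] = probs.get(t, 0.0) + fits[j] / N
        rows.append(s), cols.append(s), vals.append(1.0)
        for t, pr in probs.items():
            rows.append(s), cols.append(t), vals.append(-pr)
    mat = csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    h = spsolve(mat, rhs)

    rho_A = float(np.mean([h[1 << v] for v in range(N)]))
    rho_B = float(np.mean([1.0 - h[full & ~(1 << v)] for v in range(N)]))
    return rho_A, rho_B
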