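"""Coupled triad-revision / opinion-formation engine and its baselines.

One *time step* revises one uniformly chosen triad.  Balanced triads are left
alone; an unbalanced triad is balanced by flipping one link, chosen by the
configured rule:

* ``preferential`` — the coupled model: a (---) triad befriends the pair with
  the *smallest* opinion distance; a (-++) triad flips its negative link to
  positive with probability p, otherwise breaks the positive link with the
  *largest* opinion distance.
* ``random`` — local triad dynamics (LTD): the flipped link is uniform among
  the legal candidates.
* ``constrained`` — constrained triad dynamics (CTD): the LTD candidate is
  applied only if the global unbalanced-triad count does not increase.

Every M = round((N-1)(N-2)/6) steps one uniformly chosen agent revises its
opinion to the average of itself and its friends within confidence epsilon
(enemies never influence an agent).  A *round* is N*M steps, so on average
every triad and every opinion is revised once per round.

Once the network is balanced it can never change again (every triad is
balanced, so no flip is ever triggered); the run then relaxes opinions alone
— rounds of N i.i.d. single-agent revisions — until the synchronous
fixed-point residual drops below ``tol_fixedpoint``.

Two engines implement identical semantics: ``"fast"`` (numba kernels, the
default) and ``"reference"`` (pure Python, used for small-N contract tests).
Each is bit-reproducible for a fixed seed; they consume randomness
differently, so their trajectories agree in law, not bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .core import (
    METRIC_CODES,
    OpinionMatrix,
    Params,
    SignedNetwork,
    SystemState,
    Triad,
    extract_cliques,
    flip_count_delta,
    init_random_state,
    opinion_distance,
)

BRANCH_NAMES = (
    "smallest-delta",
    "largest-delta",
    "negative-to-positive",
    "random",
    "rejected-by-constraint",
)

#: consecutive flip-free rounds with unbalanced triads after which a
#: constrained-dynamics run is declared jammed
JAM_ROUNDS = 50


@dataclass(frozen=True)
class Neighborhood:
    """The confidence set of an agent: itself plus every friend within
    opinion distance epsilon."""

    focal: int
    members: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FlipEvent:
    """Record of one triad revision that selected a link (CTD may reject it)."""

    t: int
    triad: Triad
    pair: tuple[int, int]
    old_sign: int
    new_sign: int
    branch: str

    @property
    def applied(self) -> bool:
        return self.branch != "rejected-by-constraint"


def build_neighborhood(
    state: SystemState, i: int, epsilon: float, metric: str = "chebyshev"
) -> Neighborhood:
    """Members = {i} ∪ {j : s_ij = +1 and Δ_ij <= epsilon}.  Enemies are
    excluded regardless of opinion distance."""
    x = state.opinions.values
    members = [i]
    for j in range(state.n):
        if j != i and state.network.signs[i, j] == 1:
            if opinion_distance(x, i, j, metric).value <= epsilon:
                members.append(j)
    return Neighborhood(i, np.array(sorted(members)))


def revise_opinion(state: SystemState, i: int, params: Params) -> OpinionMatrix:
    """Replace x_i, issue by issue, with the mean opinion of its confidence
    set (asynchronous: reads the current state).  Returns the opinion matrix."""
    nb = build_neighborhood(state, i, params.epsilon, params.metric)
    state.opinions.values[i] = state.opinions.values[nb.members].mean(axis=0)
    return state.opinions


def _apply_flip(state: SystemState, i: int, j: int) -> None:
    delta = flip_count_delta(state.network, i, j)
    state.network.flip(i, j)
    state.unbalanced_count += delta


def _tie_break(pairs: list[tuple[int, int]], values: list[float], best: float,
               rng: np.random.Generator) -> tuple[int, int]:
    cands = [pq for pq, v in zip(pairs, values) if v == best]
    return cands[0] if len(cands) == 1 else cands[rng.integers(len(cands))]


def revise_triad(
    state: SystemState, triad: Triad, params: Params, rng: np.random.Generator
) -> FlipEvent | None:
    """Preferential-flip revision; no-op on balanced triads."""
    net = state.network
    x = state.opinions.values
    signs = [net.sign(a, b) for a, b in triad.pairs]
    if signs[0] * signs[1] * signs[2] == 1:
        return None
    dists = [opinion_distance(x, a, b, params.metric).value for a, b in triad.pairs]
    if signs.count(-1) == 3:
        pair = _tie_break(list(triad.pairs), dists, min(dists), rng)
        branch = "smallest-delta"
    else:  # (-++)
        if rng.random() < params.p:
            pair = triad.pairs[signs.index(-1)]
            branch = "negative-to-positive"
        else:
            pos = [(pq, d) for pq, s, d in zip(triad.pairs, signs, dists) if s == 1]
            best = max(d for _, d in pos)
            pair = _tie_break([pq for pq, _ in pos], [d for _, d in pos], best, rng)
            branch = "largest-delta"
    old = net.sign(*pair)
    _apply_flip(state, *pair)
    return FlipEvent(state.t, triad, pair, old, -old, branch)


def _random_candidate(
    state: SystemState, triad: Triad, params: Params, rng: np.random.Generator
) -> tuple[tuple[int, int], str] | None:
    net = state.network
    signs = [net.sign(a, b) for a, b in triad.pairs]
    if signs[0] * signs[1] * signs[2] == 1:
        return None
    if signs.count(-1) == 3:
        return triad.pairs[rng.integers(3)], "random"
    if rng.random() < params.p:
        return triad.pairs[signs.index(-1)], "negative-to-positive"
    pos = [pq for pq, s in zip(triad.pairs, signs) if s == 1]
    return pos[rng.integers(2)], "random"


def revise_triad_ltd(
    state: SystemState, triad: Triad, params: Params, rng: np.random.Generator
) -> FlipEvent | None:
    """Local triad dynamics: the flipped link is uniform among candidates."""
    cand = _random_candidate(state, triad, params, rng)
    if cand is None:
        return None
    pair, branch = cand
    old = state.network.sign(*pair)
    _apply_flip(state, *pair)
    return FlipEvent(state.t, triad, pair, old, -old, branch)


def revise_triad_ctd(
    state: SystemState, triad: Triad, params: Params, rng: np.random.Generator
) -> FlipEvent | None:
    """Constrained triad dynamics: the LTD candidate flip is applied only if
    the global unbalanced-triad count would not increase."""
    cand = _random_candidate(state, triad, params, rng)
    if cand is None:
        return None
    pair, branch = cand
    old = state.network.sign(*pair)
    if flip_count_delta(state.network, *pair) > 0:
        return FlipEvent(state.t, triad, pair, old, old, "rejected-by-constraint")
    _apply_flip(state, *pair)
    return FlipEvent(state.t, triad, pair, old, -old, branch)


_REVISERS = {
    "preferential": revise_triad,
    "random": revise_triad_ltd,
    "constrained": revise_triad_ctd,
}


def _opinion_tick_prob(params: Params) -> float:
    n = params.n_agents
    return min(1.0, params.opinion_rate * 6.0 / ((n - 1) * (n - 2)))


def step(state: SystemState, params: Params, rng: np.random.Generator) -> FlipEvent | None:
    """Advance one time step: revise one uniform triad; additionally revise
    one uniform agent's opinion on schedule.  Returns the flip event, if any."""
    state.t += 1
    idx = rng.choice(state.n, size=3, replace=False)
    triad = Triad.make(*idx, n=state.n)
    event = _REVISERS[params.flip_rule](state, triad, params, rng)
    if params.stochastic_schedule:
        if rng.random() < _opinion_tick_prob(params):
            revise_opinion(state, int(rng.integers(state.n)), params)
    elif state.t % params.update_period == 0:
        revise_opinion(state, int(rng.integers(state.n)), params)
    return event


def opinion_round(
    state: SystemState, params: Params, rng: np.random.Generator, engine: str = "fast"
) -> None:
    """One round of opinion relaxation: N i.i.d. uniform single-agent
    revisions, the network untouched."""
    if engine == "fast":
        _kernels.opinion_round(
            state.network.signs,
            state.opinions.values,
            params.epsilon,
            METRIC_CODES[params.metric],
        )
    else:
        for _ in range(state.n):
            revise_opinion(state, int(rng.integers(state.n)), params)


def fixedpoint_residual(state: SystemState, params: Params) -> float:
    """Largest per-component change any single agent's revision would produce
    (synchronous residual).  Zero exactly at the fixed points of the
    asynchronous dynamics; leaves the state untouched."""
    from .core import distance_matrix

    x = state.opinions.values
    adj = (state.network.signs == 1) & (
        distance_matrix(x, params.metric) <= params.epsilon
    )
    np.fill_diagonal(adj, True)
    means = (adj @ x) / adj.sum(axis=1, keepdims=True)
    return float(np.max(np.abs(means - x)))


@dataclass
class RunResult:
    """Absorbing-state record of a single run."""

    params: Params
    seed: int
    engine: str
    termination: str  # "absorbed", "max_rounds" or "jammed"
    t_balance: int | None  # first step with zero unbalanced triads
    t_end: int | None  # step at which opinions reached a fixed point
    rounds: int
    final_state: SystemState
    cliques: tuple[np.ndarray, np.ndarray] | None
    n_op: int
    clustering: "OpinionClustering"
    d_plus: float
    d_minus: float
    flip_counts: dict[str, int]
    series: pd.DataFrame | None = None
    opinion_history: list[np.ndarray] | None = None

    @property
    def absorbed(self) -> bool:
        return self.termination == "absorbed"

    @property
    def balanced(self) -> bool:
        return self.t_balance is not None

    @property
    def rounds_to_balance(self) -> float | None:
        if self.t_balance is None:
            return None
        return self.t_balance / self.params.steps_per_round

    @property
    def clique_sizes(self) -> tuple[int, int] | None:
        if self.cliques is None:
            return None
        return len(self.cliques[0]), len(self.cliques[1])

    def to_record(self) -> dict:
        """JSON-safe summary (the run-record schema written by the CLI)."""

        def _num(v):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v

        return {
            "params": self.params.to_dict(),
            "seed": int(self.seed),
            "engine": self.engine,
            "termination": self.termination,
            "T_balance_steps": _num(self.t_balance),
            "T_balance_rounds": _num(self.rounds_to_balance),
            "T_end_steps": _num(self.t_end),
            "rounds": int(self.rounds),
            "clique_sizes": list(self.clique_sizes) if self.cliques is not None else None,
            "N_op": int(self.n_op),
            "D_plus": _num(self.d_plus),
            "D_minus": _num(self.d_minus),
            "flip_counts": {k: int(v) for k, v in self.flip_counts.items()},
        }


def _resolve_seed(params: Params) -> int:
    if params.seed is not None:
        return int(params.seed)
    return int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)


def _series_row(state: SystemState, params: Params, rnd: int) -> dict:
    from .observables import count_opinions, diversity_measures

    d_plus, d_minus = diversity_measures(state, params.metric)
    n_op, _ = count_opinions(state, params.tol_cluster, params.metric)
    return {
        "round": rnd,
        "t": state.t,
        "F_unbal": state.frac_unbalanced,
        "D_plus": d_plus,
        "D_minus": d_minus,
        "N_op": n_op,
    }


def _advance_python(
    state: SystemState, params: Params, rng: np.random.Generator, n_steps: int,
    counts: dict[str, int],
) -> tuple[int | None, int]:
    t_balance = None
    flips = 0
    for _ in range(n_steps):
        event = step(state, params, rng)
        if event is not None:
            counts[event.branch] += 1
            if event.applied:
                flips += 1
                if state.unbalanced_count == 0 and t_balance is None:
                    t_balance = state.t
    return t_balance, flips


def run(
    params: Params,
    initial_state: SystemState | None = None,
    engine: str = "fast",
    record_series: bool = True,
    record_opinions: bool = False,
) -> RunResult:
    """Run the coupled dynamics to its absorbing state (or a cap).

    The run ends "absorbed" when the network has zero unbalanced triads *and*
    a full opinion sweep moves no component by tol_fixedpoint or more; it
    ends "max_rounds" at the round cap and (constrained rule only) "jammed"
    after 50 consecutive rounds without an admissible flip while unbalanced
    triads remain.  After absorption, opinions within tol_cluster are snapped
    to their cluster mean for reporting.  Fully reproducible from the seed.
    """
    from .observables import count_opinions, diversity_measures

    if engine not in ("fast", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    seed = _resolve_seed(params)
    children = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(children[0])
    branch_counts = np.zeros(5, dtype=np.int64)
    python_counts = {name: 0 for name in BRANCH_NAMES}
    if engine == "fast":
        _kernels.seed_kernel(int(children[1].generate_state(1)[0] & 0x7FFFFFFF))

    state = initial_state.copy() if initial_state is not None else init_random_state(params, rng)
    spr = params.steps_per_round
    metric_code = METRIC_CODES[params.metric]
    rule_code = {"preferential": 0, "random": 1, "constrained": 2}[params.flip_rule]

    rows = [_series_row(state, params, 0)] if record_series else None
    history = [state.opinions.values.copy()] if record_opinions else None

    t_balance = state.t if state.unbalanced_count == 0 else None
    termination = "max_rounds"
    rnd = 0
    flip_free_rounds = 0

    # phase 1: triad revisions (with scheduled opinion updates) until balance
    while t_balance is None and rnd < params.max_rounds:
        if engine == "fast":
            t, unbal, tb, flips = _kernels.advance(
                state.network.signs,
                state.opinions.values,
                state.unbalanced_count,
                state.t,
                spr,
                params.p,
                params.epsilon,
                metric_code,
                rule_code,
                params.update_period,
                1 if params.stochastic_schedule else 0,
                _opinion_tick_prob(params),
                branch_counts,
            )
            state.t, state.unbalanced_count = int(t), int(unbal)
            if tb >= 0:
                t_balance = int(tb)
        else:
            tb, flips = _advance_python(state, params, rng, spr, python_counts)
            if tb is not None:
                t_balance = tb
        rnd += 1
        if record_series:
            rows.append(_series_row(state, params, rnd))
        if record_opinions:
            history.append(state.opinions.values.copy())
        if params.flip_rule == "constrained" and state.unbalanced_count > 0:
            flip_free_rounds = flip_free_rounds + 1 if flips == 0 else 0
            if flip_free_rounds >= JAM_ROUNDS:
                termination = "jammed"
                break

    # phase 2: balance is absorbing for the network; relax opinions to a
    # fixed point, detected by the (non-mutating) synchronous residual
    t_end = None
    if t_balance is not None and termination != "jammed":
        while True:
            if engine == "fast":
                resid = float(
                    _kernels.fp_residual(
                        state.network.signs,
                        state.opinions.values,
                        params.epsilon,
                        metric_code,
                    )
                )
            else:
                resid = fixedpoint_residual(state, params)
            if resid < params.tol_fixedpoint:
                t_end = state.t
                termination = "absorbed"
                break
            if rnd >= params.max_rounds:
                break
            opinion_round(state, params, rng, engine)
            rnd += 1
            state.t += spr
            if record_series:
                rows.append(_series_row(state, params, rnd))
            if record_opinions:
                history.append(state.opinions.values.copy())

    # snap converged opinions to their cluster mean for reporting
    if termination == "absorbed":
        _, clustering = count_opinions(state, params.tol_cluster, params.metric)
        for members, centroid in zip(clustering.clusters, clustering.centroids):
            state.opinions.values[members] = centroid
    n_op, clustering = count_opinions(state, params.tol_cluster, params.metric)
    d_plus, d_minus = diversity_measures(state, params.metric)

    cliques = None
    if state.unbalanced_count == 0:
        cliques = extract_cliques(state.network)

    if engine == "fast":
        flip_counts = dict(zip(BRANCH_NAMES, branch_counts.tolist()))
    else:
        flip_counts = python_counts

    return RunResult(
        params=params,
        seed=seed,
        engine=engine,
        termination=termination,
        t_balance=t_balance,
        t_end=t_end,
        rounds=rnd,
        final_state=state,
        cliques=cliques,
        n_op=n_op,
        clustering=clustering,
        d_plus=d_plus,
        d_minus=d_minus,
        flip_counts=flip_counts,
        series=pd.DataFrame(rows) if record_series else None,
        opinion_history=history,
    )


def run_bc_baseline(
    params: Params,
    engine: str = "fast",
    record_series: bool = True,
    record_opinions: bool = False,
) -> RunResult:
    """Pure bounded-confidence baseline: the network is all-positive and
    frozen; only asynchronous opinion updates run, to a fixed point."""
    seed = _resolve_seed(params)
    # third spawn key: keeps the initial draw disjoint from run()'s own stream
    init_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    network = SignedNetwork.all_friends(params.n_agents)
    opinions = OpinionMatrix.random(params.n_agents, params.n_issues, init_rng)
    state = SystemState.create(network, opinions)
    return run(
        params.replace(seed=seed),
        initial_state=state,
        engine=engine,
        record_series=record_series,
        record_opinions=record_opinions,
    )
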