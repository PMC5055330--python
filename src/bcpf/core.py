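"""Domain types and structural primitives for complete signed networks with opinions.

The system is a fully connected graph of ``N`` agents.  Every unordered pair
``(i, j)`` carries a sign ``s_ij ∈ {-1, +1}`` (enmity / friendship) and every
agent holds an opinion vector ``x_i ∈ [0, 1]^F`` over ``F`` issues.  A triad
``ijk`` is balanced iff ``s_ij * s_ik * s_jk = +1``; a complete signed graph is
balanced iff it is either all-friends or splits into two mutually hostile
cliques.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

METRICS = ("chebyshev", "euclidean")
FLIP_RULES = ("preferential", "random", "constrained")

#: integer codes shared with the compiled kernels
METRIC_CODES = {"chebyshev": 0, "euclidean": 1}
FLIP_RULE_CODES = {"preferential": 0, "random": 1, "constrained": 2}


class ConfigurationError(ValueError):
    """Invalid parameter value or combination."""


class InvalidTriadError(ValueError):
    """Triad indices out of range or not distinct."""


class NotBalancedError(ValueError):
    """Operation requires a balanced network."""


class NotApplicableError(ValueError):
    """Observable undefined for this state (e.g. non-bipolar partition)."""


def triad_count(n: int) -> int:
    """Number of triads in a complete graph on ``n`` nodes: n(n-1)(n-2)/6."""
    return n * (n - 1) * (n - 2) // 6


def default_update_period(n: int, opinion_rate: float = 1.0) -> int:
    """Opinion-update cadence M: one opinion revision every (N-1)(N-2)/6 triad
    revisions, rounded to the nearest integer with a floor of 1.

    ``opinion_rate`` > 1 updates opinions proportionally more often (rate 2
    halves the period), used for schedule-robustness experiments.
    """
    return max(1, round((n - 1) * (n - 2) / (6.0 * opinion_rate)))


@dataclass(frozen=True)
class Params:
    """All model, schedule and tolerance parameters of a run.

    Parameters
    ----------
    n_agents : int
        Number of agents N (>= 3).
    n_issues : int
        Number of opinion issues F (>= 1).
    p : float
        Probability in (0, 1) that an unbalanced (-++) triad resolves by
        flipping its negative link to positive (all-friends drift); with
        probability 1 - p a positive link flips to negative instead.
    epsilon : float
        Bounded-confidence level in [0, 1]: an agent only averages the
        opinions of friends within opinion distance epsilon.
    rho0 : float
        Independent per-link probability in [0, 1] that an initial link is
        positive.
    metric : {"chebyshev", "euclidean"}
        Opinion distance for F > 1 (both reduce to |x_i - x_j| at F = 1).
    flip_rule : {"preferential", "random", "constrained"}
        Triad resolution rule: opinion-distance preferential flip (BC-PF),
        uniform random flip (LTD), or random flip accepted only when the
        global unbalanced-triad count does not increase (CTD).
    opinion_update_period : int or None
        Cadence M in triad steps between opinion revisions; ``None`` means
        the default round((N-1)(N-2)/6), floor 1.
    opinion_rate : float
        Multiplier on the opinion-update speed (> 0); only used when the
        period is derived from the default.
    stochastic_schedule : bool
        If True, instead of a fixed cadence each triad step triggers an
        opinion update independently with probability opinion_rate * 1/M0,
        where M0 is the default period.
    max_rounds : int
        Hard cap on the run length, in rounds of N*M triad steps.
    seed : int or None
        RNG seed; ``None`` draws fresh entropy (run is then not reproducible).
    tol_fixedpoint : float
        Opinions are at a fixed point when the largest per-agent change over
        one full sweep falls below this.
    tol_cluster : float
        Two agents share an opinion (for N_op) when their distance is <= this.
    """

    n_agents: int
    n_issues: int = 1
    p: float = 0.1
    epsilon: float = 0.2
    rho0: float = 0.5
    metric: str = "chebyshev"
    flip_rule: str = "preferential"
    opinion_update_period: int | None = None
    opinion_rate: float = 1.0
    stochastic_schedule: bool = False
    max_rounds: int = 1_000_000
    seed: int | None = None
    tol_fixedpoint: float = 1e-10
    tol_cluster: float = 1e-6

    def __post_init__(self) -> None:
        if not isinstance(self.n_agents, (int, np.integer)) or self.n_agents < 3:
            raise ConfigurationError(f"n_agents must be an integer >= 3, got {self.n_agents}")
        if not isinstance(self.n_issues, (int, np.integer)) or self.n_issues < 1:
            raise ConfigurationError(f"n_issues must be an integer >= 1, got {self.n_issues}")
        if not 0.0 < self.p < 1.0:
            raise ConfigurationError(f"p must lie strictly inside (0, 1), got {self.p}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigurationError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if not 0.0 <= self.rho0 <= 1.0:
            raise ConfigurationError(f"rho0 must lie in [0, 1], got {self.rho0}")
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.flip_rule not in FLIP_RULES:
            raise ConfigurationError(
                f"unknown flip_rule {self.flip_rule!r}; expected one of {FLIP_RULES}"
            )
        if self.opinion_update_period is not None and self.opinion_update_period < 1:
            raise ConfigurationError("opinion_update_period must be >= 1")
        if self.opinion_rate <= 0:
            raise ConfigurationError("opinion_rate must be > 0")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")
        if self.tol_fixedpoint <= 0 or self.tol_cluster <= 0:
            raise ConfigurationError("tolerances must be > 0")

    @property
    def update_period(self) -> int:
        """Effective cadence M (triad steps per opinion revision)."""
        if self.opinion_update_period is not None:
            return self.opinion_update_period
        return default_update_period(self.n_agents, self.opinion_rate)

    @property
    def steps_per_round(self) -> int:
        """One round = N * M0 triad steps (M0 the rate-1 default period), so
        that on average every triad and every opinion is revised once."""
        return self.n_agents * default_update_period(self.n_agents)

    @property
    def n_triads(self) -> int:
        return triad_count(self.n_agents)

    def replace(self, **kwargs) -> "Params":
        import dataclasses

        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


class Triad(NamedTuple):
    """Three distinct agent indices stored canonically i < j < k."""

    i: int
    j: int
    k: int

    @classmethod
    def make(cls, a: int, b: int, c: int, n: int | None = None) -> "Triad":
        if len({a, b, c}) != 3:
            raise InvalidTriadError(f"triad indices must be distinct, got {(a, b, c)}")
        i, j, k = sorted((int(a), int(b), int(c)))
        if i < 0 or (n is not None and k >= n):
            raise InvalidTriadError(f"triad indices out of range [0, {n}): {(a, b, c)}")
        return cls(i, j, k)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return ((self.i, self.j), (self.i, self.k), (self.j, self.k))


@dataclass
class SignedNetwork:
    """Complete symmetric sign assignment over N agents.

    ``signs`` is an N x N int8 matrix with zero diagonal, ``signs[i, j] ∈
    {-1, +1}`` for i != j, and ``signs[i, j] == signs[j, i]``.
    """

    signs: np.ndarray

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        s = self.signs
        if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] < 3:
            raise ConfigurationError("signs must be a square matrix with N >= 3")
        if np.any(np.diagonal(s) != 0):
            raise ConfigurationError("self-links are not allowed (diagonal must be 0)")
        if not np.array_equal(s, s.T):
            raise ConfigurationError("signs must be symmetric")
        off = s[~np.eye(s.shape[0], dtype=bool)]
        if not np.all(np.abs(off) == 1):
            raise ConfigurationError("every off-diagonal sign must be -1 or +1")

    @property
    def n(self) -> int:
        return self.signs.shape[0]

    @classmethod
    def random(cls, n: int, rho0: float, rng: np.random.Generator) -> "SignedNetwork":
        """Each unordered pair positive with independent probability rho0."""
        iu = np.triu_indices(n, k=1)
        draws = np.where(rng.random(len(iu[0])) < rho0, 1, -1).astype(np.int8)
        s = np.zeros((n, n), dtype=np.int8)
        s[iu] = draws
        s += s.T
        return cls(s)

    @classmethod
    def all_friends(cls, n: int) -> "SignedNetwork":
        s = np.ones((n, n), dtype=np.int8)
        np.fill_diagonal(s, 0)
        return cls(s)

    @classmethod
    def two_cliques(cls, n: int, clique1: Sequence[int]) -> "SignedNetwork":
        """Bipolar network: ``clique1`` vs the rest, cross links negative."""
        member = np.zeros(n, dtype=bool)
        member[list(clique1)] = True
        same = member[:, None] == member[None, :]
        s = np.where(same, 1, -1).astype(np.int8)
        np.fill_diagonal(s, 0)
        return cls(s)

    def sign(self, i: int, j: int) -> int:
        if i == j:
            raise InvalidTriadError("no self-links in a complete signed network")
        return int(self.signs[i, j])

    def flip(self, i: int, j: int) -> None:
        """Toggle the sign of the unordered pair (i, j), preserving symmetry."""
        if i == j:
            raise InvalidTriadError("cannot flip a self-link")
        self.signs[i, j] = -self.signs[i, j]
        self.signs[j, i] = self.signs[i, j]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.signs > 0) // 2)

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.signs < 0) // 2)

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.signs.copy())


@dataclass
class OpinionMatrix:
    """N x F opinion values, each in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ConfigurationError("opinions must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_issues(self) -> int:
        return self.values.shape[1]

    @classmethod
    def random(cls, n: int, n_issues: int, rng: np.random.Generator) -> "OpinionMatrix":
        return cls(rng.random((n, n_issues)))

    def copy(self) -> "OpinionMatrix":
        return OpinionMatrix(self.values.copy())


class OpinionDistance(NamedTuple):
    """Scalar opinion distance plus the metric it was computed with."""

    value: float
    metric: str


def _pairwise_rows(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    d = np.abs(a - b)
    if metric == "chebyshev":
        return float(d.max())
    if metric == "euclidean":
        return float(np.sqrt(np.sum(d * d)))
    raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")


def opinion_distance(
    opinions: OpinionMatrix | np.ndarray, i: int, j: int, metric: str = "chebyshev"
) -> OpinionDistance:
    """Distance between the opinion vectors of agents i and j.

    ``chebyshev`` is the largest per-issue difference (two agents are within
    confidence only if they are close on *every* issue); ``euclidean`` is the
    geometric distance.  For F = 1 both equal |x_i - x_j|.
    """
    x = opinions.values if isinstance(opinions, OpinionMatrix) else np.atleast_2d(opinions)
    return OpinionDistance(_pairwise_rows(x[i], x[j], metric), metric)


def distance_matrix(opinions: OpinionMatrix | np.ndarray, metric: str = "chebyshev") -> np.ndarray:
    """Full N x N opinion-distance matrix under the given metric."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    x = opinions.values if isinstance(opinions, OpinionMatrix) else np.atleast_2d(opinions)
    from scipy.spatial.distance import cdist

    return cdist(x, x, metric=metric)


@dataclass
class SystemState:
    """Network + opinions + step counter + cached unbalanced-triad count."""

    network: SignedNetwork
    opinions: OpinionMatrix
    t: int = 0
    unbalanced_count: int = 0

    @classmethod
    def create(
        cls, network: SignedNetwork, opinions: OpinionMatrix, t: int = 0
    ) -> "SystemState":
        if network.n != opinions.n:
            raise ConfigurationError("network and opinions disagree on N")
        return cls(network, opinions, t, count_unbalanced(network))

    @property
    def n(self) -> int:
        return self.network.n

    @property
    def n_triads(self) -> int:
        return triad_count(self.n)

    @property
    def frac_unbalanced(self) -> float:
        return self.unbalanced_count / self.n_triads

    def copy(self) -> "SystemState":
        return SystemState(self.network.copy(), self.opinions.copy(), self.t, self.unbalanced_count)


def init_random_state(params: Params, rng: np.random.Generator | None = None) -> SystemState:
    """Random initial condition: i.i.d. link signs (positive w.p. rho0) and
    i.i.d. uniform opinions on [0, 1]^F; t = 0 and the unbalanced-triad count
    set by full enumeration."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    network = SignedNetwork.random(params.n_agents, params.rho0, rng)
    opinions = OpinionMatrix.random(params.n_agents, params.n_issues, rng)
    return SystemState.create(network, opinions)


# ---------------------------------------------------------------------------
# triad classification and balance


def triad_signs(network: SignedNetwork, triad: Triad) -> tuple[int, int, int]:
    i, j, k = triad
    return network.sign(i, j), network.sign(i, k), network.sign(j, k)


def triad_type(state_or_network, triad: Triad) -> str:
    """Classify a triad by its multiset of signs: '+++' or '+--' (balanced),
    '-++' or '---' (unbalanced)."""
    network = getattr(state_or_network, "network", state_or_network)
    n = network.n
    i, j, k = triad
    if len({i, j, k}) != 3 or min(i, j, k) < 0 or max(i, j, k) >= n:
        raise InvalidTriadError(f"invalid triad {tuple(triad)} for N={n}")
    n_neg = sum(1 for s in triad_signs(network, triad) if s < 0)
    return {0: "+++", 1: "-++", 2: "+--", 3: "---"}[n_neg]


def is_balanced_triad(network: SignedNetwork, triad: Triad) -> bool:
    s1, s2, s3 = triad_signs(network, triad)
    return s1 * s2 * s3 == 1


def count_unbalanced(network: SignedNetwork) -> int:
    """Unbalanced-triad count by full enumeration.

    Uses the closed form: the sum of s_ij*s_ik*s_jk over all triads equals
    trace(S^3)/6 for a symmetric ±1 matrix with zero diagonal, so the count is
    (n_triads - trace(S^3)/6) / 2.
    """
    s = network.signs.astype(np.int64)
    tr = int(np.trace(s @ s @ s))
    total = triad_count(network.n)
    return (total - tr // 6) // 2


def pair_unbalanced_count(network: SignedNetwork, i: int, j: int) -> int:
    """Number of unbalanced triads containing the pair (i, j); O(N)."""
    s = network.signs
    prod = int(s[i, j]) * s[i].astype(np.int32) * s[j].astype(np.int32)
    return int(np.sum(prod == -1))


def flip_count_delta(network: SignedNetwork, i: int, j: int) -> int:
    """Change in the global unbalanced-triad count if (i, j) were flipped.

    Flipping one pair toggles the balance of exactly the N-2 triads through
    it, so the delta is (N-2) - 2u with u the currently unbalanced ones.
    """
    u = pair_unbalanced_count(network, i, j)
    return (network.n - 2) - 2 * u


def _positive_components(network: SignedNetwork) -> tuple[int, np.ndarray]:
    adj = csr_matrix((network.signs > 0).astype(np.int8))
    return connected_components(adj, directed=False)


def is_balanced(network: SignedNetwork) -> bool:
    """True iff every triad is balanced.

    O(N^2) path: friendship must be transitive, so the positive subgraph must
    have at most two components and every cross-component link must be
    negative — equivalently, s_ij > 0 exactly for same-component pairs.
    """
    n_comp, labels = _positive_components(network)
    if n_comp > 2:
        return False
    same = labels[:, None] == labels[None, :]
    pos = network.signs > 0
    off = ~np.eye(network.n, dtype=bool)
    return bool(np.array_equal(pos[off], same[off]))


def extract_cliques(network: SignedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Partition of a balanced network into its (at most two) friendly cliques.

    Returns (C1, C2) as index arrays; C1 contains agent 0 and C2 may be
    empty (all-friends configuration).  Raises :class:`NotBalancedError` on
    an unbalanced network.
    """
    if not is_balanced(network):
        raise NotBalancedError("clique extraction requires a balanced network")
    _, labels = _positive_components(network)
    c1 = np.flatnonzero(labels == labels[0])
    c2 = np.flatnonzero(labels != labels[0])
    return c1, c2
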