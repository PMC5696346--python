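"""The full mobility model: memory-reinforced random walks over a populated
spatial domain.

A traveler at location *i* moves to location *j* with probability

    p_ij  ∝  (m_j / W_ji) * (1 + λ / r_j),

where ``m_j / W_ji`` is the population-competition weight (see
:mod:`mobisim.domain`), λ >= 0 is the single free memory-strength parameter,
and ``r_j`` is the order in which *j* was first visited by this traveler (the
home location has rank 1).  A never-visited location has memory factor 1.
Self-transitions are excluded: the walk models inter-city travel steps.

λ = 0 reduces to a population-only (gravity-like) walk; λ → ∞ traps the
traveler between the first two locations visited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .domain import SpatialDomain

logger = logging.getLogger("mobisim.simulate")


@dataclass(frozen=True)
class MemoryParams:
    """Memory strength λ >= 0 of the preferential-return effect."""

    lam: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError("lam must be finite and nonnegative")


@dataclass
class TravelerState:
    """Mutable per-traveler memory state.

    ``visit_order[r-1]`` is the r-th newly visited location; the home is
    always ``visit_order[0]`` (rank 1).
    """

    home: int
    visit_order: list[int] = field(default_factory=list)
    visit_counts: dict[int, int] = field(default_factory=dict)
    current: int = -1

    def __post_init__(self):
        if not self.visit_order:
            self.visit_order = [self.home]
        if self.visit_order[0] != self.home:
            raise ValueError("home must be the first visited location")
        if len(set(self.visit_order)) != len(self.visit_order):
            raise ValueError("visit_order entries must be unique")
        if not self.visit_counts:
            self.visit_counts = {self.home: 1}
        if self.current < 0:
            self.current = self.home

    def rank(self, j: int) -> int | None:
        """1-based first-visit rank of *j*, or None if unvisited."""
        try:
            return self.visit_order.index(j) + 1
        except ValueError:
            return None

    def record_move(self, j: int) -> None:
        if j not in self.visit_counts:
            self.visit_order.append(j)
            self.visit_counts[j] = 0
        self.visit_counts[j] += 1
        self.current = j


@dataclass
class Trajectory:
    """One traveler's ordered location sequence (initial location + L moves)."""

    traveler_id: int
    locations: np.ndarray

    def __post_init__(self):
        self.locations = np.asarray(self.locations, dtype=np.int64)

    @property
    def L(self) -> int:
        return len(self.locations) - 1

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)


@dataclass
class TrajectoryEnsemble:
    """A collection of trajectories plus the context that produced them.

    ``domain`` is None for the abstract (geometry-free) simplified walks.
    ``n_locations`` is the size of the location set the ids refer to.
    """

    trajectories: list[Trajectory]
    domain: SpatialDomain | None = None
    params: MemoryParams | None = None
    seed: int | None = None
    homes: np.ndarray | None = None
    n_locations: int | None = None

    def __post_init__(self):
        if self.n_locations is None and self.domain is not None:
            self.n_locations = self.domain.N
        if self.homes is None and self.trajectories:
            self.homes = np.array([t.locations[0] for t in self.trajectories])

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([t.L for t in self.trajectories])


# ----------------------------------------------------------------------
# attractiveness terms (reference, per-pair API)

def memory_attractiveness(state: TravelerState, j: int, params: MemoryParams) -> float:
    """Memory weight of destination *j*: 1 if unvisited, else 1 + λ/r_j."""
    r = state.rank(j)
    if r is None:
        return 1.0
    return 1.0 + params.lam / r


def competition_attractiveness(domain: SpatialDomain, i: int, j: int) -> float:
    """Population-competition weight m_j / W_ji for an i -> j move (i != j)."""
    if i == j:
        raise ValueError("competition weight is undefined for i == j")
    return float(domain.m[j] / domain.w_row(j)[i])


def transition_probabilities(
    domain: SpatialDomain, state: TravelerState, params: MemoryParams
) -> np.ndarray:
    """Normalized transition probability vector from ``state.current``.

    Entry j is p_ij ∝ (m_j/W_ji)(1 + λ/r_j); the current location has
    probability 0.
    """
    if domain.N < 2:
        raise ValueError("need at least 2 locations to move")
    B = domain.competition_matrix()
    w = B[state.current].copy()
    for r, loc in enumerate(state.visit_order, start=1):
        if loc != state.current:
            w[loc] *= 1.0 + params.lam / r
    total = w.sum()
    if total <= 0:
        raise RuntimeError("all transition weights vanished (invalid domain)")
    return w / total


# ----------------------------------------------------------------------
# simulation (fast incremental path)

def _sample_index(cumw: np.ndarray, rng: np.random.Generator) -> int:
    u = rng.random() * cumw[-1]
    return int(np.searchsorted(cumw, u, side="right"))


def _walk(
    B_row_of: np.ndarray,
    home: int,
    L: int,
    lam: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inner loop shared by trajectory simulation; returns the id sequence."""
    N = B_row_of.shape[0]
    mem = np.ones(N)
    mem[home] = 1.0 + lam  # home has rank 1
    path = np.empty(L + 1, dtype=np.int64)
    path[0] = home
    cur = home
    n_seen = 1
    for t in range(1, L + 1):
        w = B_row_of[cur] * mem  # B diagonal is 0 -> no self moves
        cumw = np.cumsum(w)
        nxt = _sample_index(cumw, rng)
        if mem[nxt] == 1.0:
            n_seen += 1
            mem[nxt] = 1.0 + lam / n_seen
        path[t] = nxt
        cur = nxt
    return path


def simulate_trajectory(
    domain: SpatialDomain,
    home: int,
    L: int,
    params: MemoryParams,
    seed: int | np.random.Generator | None = 0,
    traveler_id: int = 0,
) -> Trajectory:
    """Simulate one traveler: L moves from ``home`` under the full model."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 <= home < domain.N:
        raise ValueError(f"home {home} not a valid location id")
    if domain.N < 2:
        raise ValueError("need at least 2 locations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path = _walk(domain.competition_matrix(), home, L, params.lam, rng)
    return Trajectory(traveler_id, path)


# ----------------------------------------------------------------------
# trajectory-length laws

class LengthLaw:
    """Base class for trajectory-length distributions P(L)."""

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class FixedLength(LengthLaw):
    L: int

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")

    def sample(self, rng, size):
        return np.full(size, self.L, dtype=np.int64)


@dataclass(frozen=True)
class TruncatedPowerLawLength(LengthLaw):
    """Discrete truncated power law P(L) ∝ L^-exponent on [lmin, lmax].

    The default (exponent 1.5 on [10, 1000]) mimics the heavy-tailed
    activity spread of check-in records.
    """

    exponent: float = 1.5
    lmin: int = 10
    lmax: int = 1000

    def __post_init__(self):
        if not (1 <= self.lmin <= self.lmax):
            raise ValueError("need 1 <= lmin <= lmax")

    def sample(self, rng, size):
        support = np.arange(self.lmin, self.lmax + 1, dtype=float)
        p = support ** (-self.exponent)
        p /= p.sum()
        return rng.choice(support.astype(np.int64), size=size, p=p)


@dataclass(frozen=True)
class EmpiricalLength(LengthLaw):
    """Resample lengths from an observed set (with replacement)."""

    lengths: tuple

    def __post_init__(self):
        if len(self.lengths) == 0:
            raise ValueError("empty length support")
        if min(self.lengths) < 1:
            raise ValueError("lengths must be >= 1")

    def sample(self, rng, size):
        arr = np.asarray(self.lengths, dtype=np.int64)
        return rng.choice(arr, size=size)


DEFAULT_LENGTH_LAW = TruncatedPowerLawLength()


def sample_homes(
    domain: SpatialDomain, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample home locations proportionally to population."""
    p = domain.m / domain.m.sum()
    return rng.choice(domain.N, size=n, p=p)


def simulate_ensemble(
    domain: SpatialDomain,
    n_travelers: int,
    length_law: LengthLaw | Sequence[int] | None = None,
    params: MemoryParams = MemoryParams(0.0),
    seed: int = 0,
    homes: Sequence[int] | None = None,
) -> TrajectoryEnsemble:
    """Simulate an ensemble of independent travelers.

    Homes default to population-proportional sampling; lengths are drawn
    i.i.d. from ``length_law`` (default: truncated power law P(L) ∝ L^-1.5 on
    [10, 1000]).  One seed sequence is split per traveler, so individual
    trajectories are independent yet the whole ensemble is reproducible.
    """
    if n_travelers < 1:
        raise ValueError("n_travelers must be >= 1")
    if length_law is None:
        length_law = DEFAULT_LENGTH_LAW
    ss = np.random.SeedSequence(seed)
    master, *streams = [np.random.default_rng(s) for s in ss.spawn(n_travelers + 1)]
    if homes is None:
        homes = sample_homes(domain, n_travelers, master)
    homes = np.asarray(homes, dtype=np.int64)
    if len(homes) != n_travelers:
        raise ValueError("homes length must equal n_travelers")
    if isinstance(length_law, LengthLaw):
        lengths = length_law.sample(master, n_travelers)
    else:
        lengths = np.asarray(length_law, dtype=np.int64)
        if len(lengths) != n_travelers:
            raise ValueError("explicit lengths must match n_travelers")
    B = domain.competition_matrix()
    trajs = [
        Trajectory(k, _walk(B, int(homes[k]), int(lengths[k]), params.lam, streams[k]))
        for k in range(n_travelers)
    ]
    return TrajectoryEnsemble(
        trajs, domain=domain, params=params, seed=seed, homes=homes
    )
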