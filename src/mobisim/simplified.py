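"""Analytically tractable simplified variants of the mobility model.

Two simplifications are implemented:

* the *uniform-population memory walk*: N abstract locations of identical
  attractiveness; the r-th first-visited location has its weight updated to
  ``1 + λN/r`` (note the extra factor N relative to the full model's
  ``1 + λ/r`` — the two forms are intentionally kept distinct, see
  docs/methods.md), unvisited locations keep weight 1, and self-moves are
  excluded;

* the *one-step population flux*: m individuals sit at every location and
  each makes a single move under the pure competition kernel
  ``p_ij ∝ m_j / W_ji`` (no memory).  On a spatial domain of fractal
  dimension D this yields the gravity law T_ij ∝ m_i m_j / d_ij^D, hence
  P(d) ∝ d^-D and the universal flux distribution P(T) ∝ T^-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import TIE_RTOL, SpatialDomain
from .simulate import Trajectory, TrajectoryEnsemble, _sample_index

logger = logging.getLogger("mobisim.simplified")


@dataclass(frozen=True)
class UniformWalkParams:
    """Parameters of the uniform-population memory walk."""

    N: int
    lam: float
    L: int

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.lam < 0 or not np.isfinite(self.lam):
            raise ValueError("lam must be finite and nonnegative")
        if self.L < 1:
            raise ValueError("L must be >= 1")


def _uniform_walk(N: int, lam: float, L: int, rng: np.random.Generator) -> np.ndarray:
    w = np.ones(N)
    home = int(rng.integers(N))
    w[home] = 1.0 + lam * N  # rank 1
    path = np.empty(L + 1, dtype=np.int64)
    path[0] = home
    cur = home
    n_seen = 1
    for t in range(1, L + 1):
        wc = w[cur]
        w[cur] = 0.0  # no self-transition
        cumw = np.cumsum(w)
        nxt = _sample_index(cumw, rng)
        w[cur] = wc
        if w[nxt] == 1.0:
            n_seen += 1
            w[nxt] = 1.0 + lam * N / n_seen
        path[t] = nxt
        cur = nxt
    return path


def simulate_uniform_walk(
    params: UniformWalkParams, n_walkers: int = 1, seed: int = 0
) -> TrajectoryEnsemble:
    """Simulate the uniform-population memory walk (abstract locations).

    λ = 0 reduces to an unbiased random walk (S(t) grows linearly until
    saturation); very large λ traps each walker between its first two
    locations.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_walkers)]
    trajs = [
        Trajectory(k, _uniform_walk(params.N, params.lam, params.L, streams[k]))
        for k in range(n_walkers)
    ]
    return TrajectoryEnsemble(trajs, domain=None, seed=seed, n_locations=params.N)


# ----------------------------------------------------------------------
# one-step population flux

@dataclass(frozen=True)
class OneStepFluxParams:
    """m individuals per location, single move each, uniform populations."""

    m: int = 100

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class FluxMatrix:
    """Nonnegative origin-destination step counts T[i, j], zero diagonal."""

    T: np.ndarray
    domain: SpatialDomain | None = None

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 2 or self.T.shape[0] != self.T.shape[1]:
            raise ValueError("flux matrix must be square")
        if np.any(self.T < 0):
            raise ValueError("fluxes must be nonnegative")
        if np.any(np.diag(self.T) != 0):
            raise ValueError("flux diagonal must be zero")

    @property
    def N(self) -> int:
        return self.T.shape[0]

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.N, dtype=bool)
        return self.T[mask]

    def to_frame(self) -> pd.DataFrame:
        i, j = np.nonzero(self.T)
        return pd.DataFrame({"origin": i, "destination": j, "T": self.T[i, j]})


def one_step_gravity_flux(
    domain: SpatialDomain,
    params: OneStepFluxParams = OneStepFluxParams(),
    sampled: bool = False,
    seed: int = 0,
) -> FluxMatrix:
    """Expected one-step fluxes T_ij = m * p_ij with p_ij ∝ m_j / W_ji.

    Every location hosts ``params.m`` individuals who each move exactly once
    under the competition kernel, so each row of T sums to m.  With
    ``sampled=True`` the per-origin destination counts are drawn from the
    corresponding multinomial instead of being the expectation.
    """
    B = domain.competition_matrix()
    P = B / B.sum(axis=1, keepdims=True)
    if sampled:
        rng = np.random.default_rng(seed)
        T = np.vstack([rng.multinomial(params.m, P[i]) for i in range(domain.N)])
        T = T.astype(float)
    else:
        T = params.m * P
    return FluxMatrix(T, domain=domain)


def one_step_flux_histograms(
    domain: SpatialDomain,
    params: OneStepFluxParams = OneStepFluxParams(),
    bins_per_decade: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Streaming log-binned P(T) and flux-weighted P(d) for large domains.

    Equivalent to ``flux_distribution`` / ``travel_distance_distribution``
    applied to :func:`one_step_gravity_flux`, but runs in O(N) memory via two
    column passes over the W kernel, so it scales to the deep fractal point
    sets (N ~ 2e4) where the dense N x N matrices would not fit comfortably.

    Returns (flux_hist, dist_hist), each a DataFrame with geometric bin
    centres ``value``, bin probability ``mass`` (summing to 1) and ``density``
    (mass / bin width).
    """
    N = domain.N
    m = float(params.m)
    mm = domain.m.astype(float)
    if np.any(domain.m != domain.m[0]):
        logger.warning("one-step flux histograms assume uniform populations")

    def w_counts(j: int) -> tuple[np.ndarray, np.ndarray]:
        d = domain.distances_from(j)
        ds = np.sort(d)
        csum = np.cumsum(mm[np.argsort(d, kind="stable")])
        idx = np.searchsorted(ds, d * (1.0 + TIE_RTOL) + 1e-12, side="right") - 1
        return csum[idx], d

    # pass 1: row sums of B and the distance range; cache the B columns in
    # float32 when they fit comfortably (halves the runtime of pass 2)
    cache: np.ndarray | None = None
    if N * N * 4 <= 2_500_000_000:
        cache = np.empty((N, N), dtype=np.float32)
    rowsum = np.zeros(N)
    dmin, dmax = np.inf, 0.0
    for j in range(N):
        Wj, d = w_counts(j)
        col = mm[j] / Wj
        col[j] = 0.0
        rowsum += col
        if cache is not None:
            cache[j] = col
        pos = d[d > 0]
        if pos.size:
            dmin = min(dmin, pos.min())
            dmax = max(dmax, pos.max())

    # fixed log grids: T is bounded by m (row sums) and below by ~m/N^2
    t_lo, t_hi = m / (N * N) / 10.0, m * 1.001
    t_edges = np.logspace(np.log10(t_lo), np.log10(t_hi),
                          int(np.ceil(np.log10(t_hi / t_lo) * bins_per_decade)) + 1)
    d_edges = np.logspace(np.log10(dmin * 0.999), np.log10(dmax * 1.001),
                          int(np.ceil(np.log10(dmax / dmin) * bins_per_decade)) + 2)

    t_acc = np.zeros(len(t_edges) - 1)
    d_acc = np.zeros(len(d_edges) - 1)
    for j in range(N):
        if cache is not None:
            col = cache[j].astype(float)
            d = domain.distances_from(j)
        else:
            Wj, d = w_counts(j)
            col = mm[j] / Wj
            col[j] = 0.0
        Tcol = m * col / rowsum  # flux i -> j for every origin i
        Tcol[j] = 0.0
        t_acc += np.histogram(Tcol[Tcol > 0], bins=t_edges)[0]
        d_acc += np.histogram(d, bins=d_edges, weights=Tcol)[0]

    def _frame(acc, edges):
        mass = acc / acc.sum()
        widths = np.diff(edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        return pd.DataFrame({"value": centers, "mass": mass, "density": mass / widths})

    return _frame(t_acc, t_edges), _frame(d_acc, d_edges)
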