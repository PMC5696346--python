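"""Closed-form predictions for the simplified uniform-population walk and
the generalized-Zipf (EPR-equivalent) extension.

For the uniform walk with N locations and memory weights ``1 + λN/r``:

* the visit-frequency Zipf curve is ``f_r ∝ λS/r + 1 − λ`` (uniform for
  λ = 0, pure Zipf ``S/r`` at λ = 1, exponential-cutoff-like deviation for
  λ > 1);
* the probability of exploring a new location after S distinct visits is
  ``P_new = 1 / (1 + λ(ln S + C))``; the exact weight-sum form is
  ``P_new = (N − S) / (N + λ N H_S)``, which for S ≪ N reduces to the
  logarithmic form with C equal to the Euler–Mascheroni constant
  (H_S ≈ ln S + γ_E).  C is exposed as a parameter;
* S(t) follows from integrating dS/dt = P_new(S), giving the monotone
  implicit relation t(S) = (S−1)(1+λC) + λ(S ln S − S + 1), inverted
  numerically.

The one-step population flux on a fractal domain of dimension D obeys
T(d) ∝ d^−D while the number of pairs within distance d grows ∝ d^D, so the
flux distribution is P(T) ∝ T^−2 *independently of D*.

In the generalized-Zipf extension the walker draws a rank from the full
ladder r = 1..N with weights r^−ζ (ζ > 1); a rank beyond the S visited
locations is an exploration event, so P_new = P(rank > S) ∝ S^−(ζ−1) — the
defining relation of exploration-and-preferential-return (EPR) dynamics,
with γ = ζ − 1 — and S(t) grows sublinearly, S(t) ∝ t^(1/ζ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .simulate import Trajectory, TrajectoryEnsemble

logger = logging.getLogger("mobisim.theory")

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the analytic predictions."""

    N: int = 1000
    lam: float = 1.0
    C: float = EULER_GAMMA
    zeta: float | None = None

    def __post_init__(self):
        if self.zeta is not None and self.zeta <= 1:
            raise ValueError("zeta must exceed 1")


def analytic_visit_frequency(
    r, S: int, lam: float, normalized: bool = False
):
    """Zipf curve of the uniform walk: f_r ∝ λS/r + 1 − λ for r = 1..S.

    With ``normalized=True`` the curve is divided by its sum over r = 1..S.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 1) or np.any(r > S):
        raise ValueError("ranks must satisfy 1 <= r <= S")
    f = lam * S / r + 1.0 - lam
    if normalized:
        rr = np.arange(1, S + 1, dtype=float)
        f = f / (lam * S / rr + 1.0 - lam).sum()
    return f


def harmonic_number(S: int) -> float:
    return float(np.sum(1.0 / np.arange(1, S + 1)))


def analytic_p_new(S, lam: float, C: float = EULER_GAMMA):
    """Probability of exploring a new location: 1 / (1 + λ(ln S + C))."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 1):
        raise ValueError("S must be >= 1")
    return 1.0 / (1.0 + lam * (np.log(S) + C))


def exact_p_new(S: int, lam: float, N: int) -> float:
    """Exact weight-sum form (N − S) / (N + λ N H_S) of the exploration
    probability in the uniform walk; the logarithmic form is its S ≪ N
    approximation."""
    if not 1 <= S <= N:
        raise ValueError("need 1 <= S <= N")
    return (N - S) / (N + lam * N * harmonic_number(S))


def _t_of_S(S: float, lam: float, C: float) -> float:
    # integral of dt/dS = 1 + lam*(ln S + C) from 1 to S
    return (S - 1.0) * (1.0 + lam * C) + lam * (S * np.log(S) - S + 1.0)


def analytic_S_of_t(
    t, lam: float, C: float = EULER_GAMMA, N: int | None = None
):
    """S(t) of the uniform walk, from inverting t(S) = ∫ dS / P_new(S).

    Continuous, nondecreasing, with S(0) = 1; λ = 0 gives S = 1 + t.  If
    ``N`` is given the curve is capped at N.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    out = np.empty_like(tt)
    for k, tv in enumerate(tt):
        if tv == 0:
            out[k] = 1.0
            continue
        hi = 1.0 + tv  # t(S) >= S - 1, so the root is below 1 + t
        out[k] = brentq(lambda s: _t_of_S(s, lam, C) - tv, 1.0, hi,
                        xtol=1e-12, rtol=1e-12)
    if N is not None:
        out = np.minimum(out, float(N))
    return out if np.ndim(t) else float(out[0])


def analytic_flux_exponent() -> float:
    """The universal one-step flux exponent: P(T) ∝ T^−2.

    On a fractal domain, N(d) ∝ d^D location pairs lie within distance d
    while the pair flux scales as T(d) ∝ d^−D; changing variables,
    P(T) = P(d) |dd/dT| ∝ d^(D−1) · d^(D+1) / d^(2D) · T^−2 ∝ T^−2, so the
    exponent does not depend on D.
    """
    return -2.0


# ----------------------------------------------------------------------
# generalized-Zipf (EPR-equivalent) walker

def extended_p_new(S, rho: float, gamma: float):
    """EPR exploration law P_new = ρ S^−γ (γ = ζ − 1)."""
    S = np.asarray(S, dtype=float)
    return rho * S ** (-gamma)


def _zipf_walk(N: int, zeta: float, L: int, rng: np.random.Generator) -> np.ndarray:
    ranks = np.arange(1, N + 1, dtype=float)
    cumw = np.cumsum(ranks ** (-zeta))
    visit_order = np.empty(N, dtype=np.int64)
    unvisited = np.arange(N, dtype=np.int64)
    # start at a uniformly random location (rank 1)
    i0 = int(rng.integers(N))
    visit_order[0] = unvisited[i0]
    unvisited[i0] = unvisited[N - 1]
    n_unvisited = N - 1
    S = 1
    cur = visit_order[0]
    path = np.empty(L + 1, dtype=np.int64)
    path[0] = cur
    for t in range(1, L + 1):
        while True:
            u = rng.random() * cumw[-1]
            r = int(np.searchsorted(cumw, u, side="right"))  # 0-based rank
            if r < S:
                nxt = visit_order[r]
                if nxt != cur:
                    break
            elif n_unvisited > 0:
                k = int(rng.integers(n_unvisited))
                nxt = unvisited[k]
                unvisited[k] = unvisited[n_unvisited - 1]
                n_unvisited -= 1
                visit_order[S] = nxt
                S += 1
                break
            # rank beyond S with nothing left to explore: redraw
        path[t] = nxt
        cur = nxt
    return path


def generalized_zipf_walk(
    N: int, zeta: float, L: int, n_walkers: int = 1, seed: int = 0
) -> TrajectoryEnsemble:
    """Simulate the generalized-Zipf walker (abstract locations).

    At each step a rank is drawn from weights r^−ζ over r = 1..N; a rank
    within the S already-visited locations returns to that location (the
    current one is excluded), a larger rank explores a uniformly random new
    location, which becomes rank S+1.
    """
    if zeta <= 1:
        raise ValueError("zeta must exceed 1")
    if N < 2 or L < 1 or n_walkers < 1:
        raise ValueError("need N >= 2, L >= 1, n_walkers >= 1")
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_walkers)]
    trajs = [Trajectory(k, _zipf_walk(N, zeta, L, streams[k]))
             for k in range(n_walkers)]
    return TrajectoryEnsemble(trajs, domain=None, seed=seed, n_locations=N)


def exploration_rate_by_S(ensemble: TrajectoryEnsemble) -> "pd.DataFrame":
    """Measured P_new as a function of S: over all steps taken while the
    walker had S distinct locations, the fraction that explored a new one."""
    import pandas as pd

    events: dict[int, list[int]] = {}
    for traj in ensemble:
        path = traj.locations
        seen = set([int(path[0])])
        for b in path[1:]:
            S = len(seen)
            new = int(b) not in seen
            tot, n_new = events.get(S, [0, 0])
            events[S] = [tot + 1, n_new + int(new)]
            if new:
                seen.add(int(b))
    rows = [(S, n_new / tot, tot) for S, (tot, n_new) in sorted(events.items())]
    return pd.DataFrame(rows, columns=["S", "p_new", "n_steps"])
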