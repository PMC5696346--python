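"""Estimating the memory strength λ from observed trajectories.

The estimator minimizes the relative-L1 objective

    E(λ) = Σ_{t=1}^{L_max} |S_real(t) − S(t, λ)| / S_real(t)

over a grid of candidate λ, where S_real is the observed mean
distinct-locations curve and S(t, λ) the model curve, averaged over
replicate simulations run with the observed homes and trajectory lengths.
Common random numbers (the same replicate seeds for every λ) keep the
Monte-Carlo noise from masking the location of the minimum.  By default
L_max is the 90th percentile of the observed lengths: the S(t) tail is
carried by few long trajectories and is noisy.

The same relative-L1 form with the return-time pmf P(τ) or the Zipf curve
f_r in place of S(t) is available as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import SpatialDomain
from .simulate import MemoryParams, TrajectoryEnsemble, simulate_ensemble
from .stats import return_time_distribution, visit_frequency_rank, visited_count_curve

logger = logging.getLogger("mobisim.estimation")

OBSERVABLES = ("S_t", "P_tau", "f_r")


@dataclass
class SimContext:
    """Everything needed to rerun the model at a candidate λ.

    ``homes`` and ``lengths`` are matched to the observed ensemble so that
    the comparison isolates λ; ``n_replicates`` model runs are averaged per
    candidate, each replicate reusing the same seed across candidates.
    """

    domain: SpatialDomain
    homes: np.ndarray
    lengths: np.ndarray
    n_replicates: int = 20
    seed: int = 0
    L_max: int | None = None

    def __post_init__(self):
        self.homes = np.asarray(self.homes, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.homes) != len(self.lengths):
            raise ValueError("homes and lengths must have equal length")
        if self.L_max is None:
            self.L_max = max(1, int(np.percentile(self.lengths, 90)))

    def replicate_seeds(self) -> np.ndarray:
        root = np.random.SeedSequence(self.seed)
        return np.array(
            [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(self.n_replicates)]
        )


@dataclass
class FitResult:
    lambda_hat: float
    objective_value: float
    grid: list[tuple[float, float]]
    observable_used: str = "S_t"


def _model_replicates(lam: float, ctx: SimContext) -> list[TrajectoryEnsemble]:
    return [
        simulate_ensemble(
            ctx.domain, len(ctx.homes), length_law=ctx.lengths,
            params=MemoryParams(lam), seed=int(s), homes=ctx.homes,
        )
        for s in ctx.replicate_seeds()
    ]


def _mean_S_curve(ensembles: list[TrajectoryEnsemble], L_max: int) -> np.ndarray:
    total = np.zeros(L_max + 1)
    count = np.zeros(L_max + 1)
    for ens in ensembles:
        c = visited_count_curve(ens)
        n = min(len(c), L_max + 1)
        total[:n] += c["S"].to_numpy()[:n]
        count[:n] += 1
    count[count == 0] = np.nan
    return total / count


def _relative_l1(real: np.ndarray, model: np.ndarray) -> float:
    n = min(len(real), len(model))
    r, m = real[:n], model[:n]
    ok = np.isfinite(m)
    return float(np.sum(np.abs(r[ok] - m[ok]) / r[ok]))


def objective_E(S_real, lam: float, ctx: SimContext) -> float:
    """E(λ): summed relative absolute deviation of the model S(t) curve from
    the observed one over t = 1..L_max."""
    S_real = np.asarray(
        S_real["S"] if isinstance(S_real, pd.DataFrame) else S_real, dtype=float
    )
    if np.any(S_real == 0):
        raise ValueError("S_real must be positive everywhere (S(t) >= 1)")
    model = _mean_S_curve(_model_replicates(lam, ctx), ctx.L_max)
    n = min(len(S_real), ctx.L_max + 1)
    return _relative_l1(S_real[1:n], model[1:n])


def _pooled_pmf_objective(real: pd.Series, ensembles, kind: str) -> float:
    if kind == "P_tau":
        parts = [return_time_distribution(e) for e in ensembles]
    else:
        parts = [visit_frequency_rank(e) for e in ensembles]
    model = pd.concat(parts, axis=1).mean(axis=1)
    model = model.reindex(real.index).fillna(0.0)
    return float(np.sum(np.abs(real - model) / real))


def _objective_for(observable: str, data, ctx: SimContext):
    """Returns (reference, fn(lam) -> E) for the chosen observable."""
    if observable == "S_t":
        if isinstance(data, TrajectoryEnsemble):
            ref = visited_count_curve(data)["S"].to_numpy()
        elif isinstance(data, pd.DataFrame):
            ref = data["S"].to_numpy()
        else:
            ref = np.asarray(data, dtype=float)
        return lambda lam: objective_E(ref, lam, ctx)
    if observable not in OBSERVABLES:
        raise ValueError(f"observable must be one of {OBSERVABLES}")
    if not isinstance(data, TrajectoryEnsemble):
        raise ValueError(f"{observable} objective requires a TrajectoryEnsemble")
    real = (return_time_distribution(data) if observable == "P_tau"
            else visit_frequency_rank(data))
    real = real[real > 0]

    def fn(lam: float) -> float:
        return _pooled_pmf_objective(real, _model_replicates(lam, ctx), observable)

    return fn


def fit_lambda(
    data,
    ctx: SimContext,
    grid=None,
    refine: bool = True,
    observable: str = "S_t",
) -> FitResult:
    """Grid-search estimate of λ, with optional local refinement.

    ``data`` is an observed TrajectoryEnsemble, an S(t) DataFrame/array (for
    ``observable="S_t"``).  The default grid is λ = 0, 1, ..., 100;
    refinement evaluates two rounds of finer grids bracketing the coarse
    minimizer.  Deterministic given ``ctx.seed``.
    """
    if grid is None:
        grid = np.arange(0.0, 101.0, 1.0)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    fn = _objective_for(observable, data, ctx)
    evals = [(float(lam), fn(float(lam))) for lam in grid]
    Es = np.array([e for _, e in evals])
    if np.allclose(Es, Es[0]):
        logger.warning("objective is flat over the grid; returning midpoint")
        mid = float(grid[len(grid) // 2])
        return FitResult(mid, float(Es[0]), evals, observable)
    k = int(np.argmin(Es))
    best_lam, best_E = evals[k]
    if refine and grid.size > 1:
        lo = grid[max(0, k - 1)]
        hi = grid[min(len(grid) - 1, k + 1)]
        for _ in range(2):
            fine = np.linspace(lo, hi, 7)[1:-1]
            fine_evals = [(float(lam), fn(float(lam))) for lam in fine]
            evals.extend(fine_evals)
            cand = min(fine_evals + [(best_lam, best_E)], key=lambda kv: kv[1])
            best_lam, best_E = cand
            width = (hi - lo) / 3.0
            lo, hi = max(lo, best_lam - width), min(hi, best_lam + width)
    return FitResult(best_lam, best_E, sorted(evals), observable)


def context_from_ensemble(
    observed: TrajectoryEnsemble,
    domain: SpatialDomain | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    L_max: int | None = None,
) -> SimContext:
    """Build a SimContext matching an observed ensemble's homes and lengths."""
    domain = domain or observed.domain
    if domain is None:
        raise ValueError("a spatial domain is required")
    homes = observed.homes
    if homes is None:
        homes = np.array([t.locations[0] for t in observed])
    return SimContext(domain, homes, observed.lengths, n_replicates, seed, L_max)
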