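"""Mobility observables and power-law exponent fitting.

Individual-level observables
    S(t)   mean number of distinct locations visited within t steps
    P(τ)   distribution of return times (inter-visit gaps, pooled over
           locations and travelers)
    f_r    mean normalized visit frequency of each traveler's rank-r most
           visited location (Zipf plot)

Population-level observables
    P(d)   distribution of travel distance per step (or per flux unit)
    P(T)   distribution of pairwise origin-destination flux

Exponents are fitted either by least squares on log-binned densities
(``logbin_lsq``) or by maximum likelihood with a fixed lower cutoff
(``mle``, Hill estimator).  Fit ranges are always explicit: exponent
estimates are range-sensitive and hidden heuristics would make results
irreproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .domain import SpatialDomain
from .simplified import FluxMatrix
from .simulate import TrajectoryEnsemble

logger = logging.getLogger("mobisim.stats")


@dataclass
class MobilityStatistics:
    """Bundle of the model's observables as tidy tables."""

    S_curve: pd.DataFrame
    return_hist: pd.Series
    rank_freq: pd.Series
    dist_hist: pd.DataFrame | None = None
    flux_hist: pd.DataFrame | None = None


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted exponent of density ∝ value**exponent over ``fit_range``."""

    exponent: float
    fit_range: tuple[float, float]
    method: str
    stderr: float


# ----------------------------------------------------------------------
# individual-level observables

def _distinct_curve(path: np.ndarray) -> np.ndarray:
    """S(t) = distinct ids among the first t+1 entries, for t = 0..L."""
    first = ~pd.Series(path).duplicated().to_numpy()
    return np.cumsum(first)


def visited_count_curve(ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    """Mean S(t) over travelers, survivor-averaged.

    At step t only travelers with trajectory length L >= t contribute, since
    lengths vary across the ensemble.  Returns a DataFrame with columns
    ``t`` (0..max L) and ``S``; S(0) = 1 and the curve is nondecreasing.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    Lmax = int(ensemble.lengths.max())
    total = np.zeros(Lmax + 1)
    count = np.zeros(Lmax + 1, dtype=np.int64)
    for traj in ensemble:
        s = _distinct_curve(traj.locations)
        total[: len(s)] += s
        count[: len(s)] += 1
    return pd.DataFrame({"t": np.arange(Lmax + 1), "S": total / count})


def return_time_samples(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Pooled inter-visit gaps τ (steps between successive visits to the
    same location), over all locations and travelers."""
    gaps = []
    n_no_revisit = 0
    for traj in ensemble:
        path = traj.locations
        order = np.argsort(path, kind="stable")
        loc_sorted = path[order]
        pos = order.astype(np.int64)
        same = loc_sorted[1:] == loc_sorted[:-1]
        g = (pos[1:] - pos[:-1])[same]
        if g.size == 0:
            n_no_revisit += 1
        else:
            gaps.append(g)
    if n_no_revisit:
        logger.info("%d trajectories had no revisit and contribute no gaps",
                    n_no_revisit)
    if not gaps:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(gaps)


def return_time_distribution(ensemble: TrajectoryEnsemble) -> pd.Series:
    """Normalized pmf of return times τ; index τ, values P(τ)."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    gaps = return_time_samples(ensemble)
    if gaps.size == 0:
        return pd.Series(dtype=float, name="p")
    vals, counts = np.unique(gaps, return_counts=True)
    return pd.Series(counts / counts.sum(), index=pd.Index(vals, name="tau"),
                     name="p")


def visit_frequency_rank(ensemble: TrajectoryEnsemble) -> pd.Series:
    """Zipf plot f_r: mean normalized visit frequency by within-traveler rank.

    For each traveler, locations are ranked by visit count (descending, over
    all L+1 trajectory entries) and frequencies normalized by L+1; f_r
    averages the rank-r frequency over the travelers that have at least r
    distinct locations.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    max_rank = 0
    sums: np.ndarray = np.zeros(0)
    counts: np.ndarray = np.zeros(0, dtype=np.int64)
    for traj in ensemble:
        _, c = np.unique(traj.locations, return_counts=True)
        f = np.sort(c)[::-1] / len(traj.locations)
        if len(f) > max_rank:
            sums = np.pad(sums, (0, len(f) - max_rank))
            counts = np.pad(counts, (0, len(f) - max_rank))
            max_rank = len(f)
        sums[: len(f)] += f
        counts[: len(f)] += 1
    return pd.Series(sums / counts, index=pd.RangeIndex(1, max_rank + 1, name="r"),
                     name="f")


# ----------------------------------------------------------------------
# population-level observables

def log_binned_density(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    bins_per_decade: int = 10,
) -> pd.DataFrame:
    """Histogram positive values into base-10 log bins.

    Returns a DataFrame with geometric bin centres ``value``, bin
    probability ``mass`` (sums to 1) and ``density`` = mass / bin width.
    """
    values = np.asarray(values, dtype=float)
    keep = values > 0
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[keep]
    values = values[keep]
    if values.size == 0:
        raise ValueError("no positive values to bin")
    lo, hi = values.min() * 0.999, values.max() * 1.001
    n_bins = max(1, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    acc, _ = np.histogram(values, bins=edges, weights=weights)
    mass = acc / acc.sum()
    centers = np.sqrt(edges[:-1] * edges[1:])
    return pd.DataFrame({"value": centers, "mass": mass,
                         "density": mass / np.diff(edges)})


def linear_binned_density(
    values: np.ndarray, weights: np.ndarray | None = None, n_bins: int = 50
) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    edges = np.linspace(values.min(), values.max() * 1.001, n_bins + 1)
    acc, _ = np.histogram(values, bins=edges, weights=weights)
    mass = acc / acc.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"value": centers, "mass": mass,
                         "density": mass / np.diff(edges)})


def step_distances(ensemble: TrajectoryEnsemble, domain: SpatialDomain) -> np.ndarray:
    """Origin-destination distance of every travel step in the ensemble."""
    out = []
    for traj in ensemble:
        a, b = traj.locations[:-1], traj.locations[1:]
        out.append(np.hypot(domain.x[b] - domain.x[a], domain.y[b] - domain.y[a]))
    return np.concatenate(out)


def travel_distance_distribution(
    data: TrajectoryEnsemble | FluxMatrix,
    domain: SpatialDomain | None = None,
    bins: str = "log",
    bins_per_decade: int = 10,
    n_bins: int = 50,
) -> pd.DataFrame:
    """P(d): density of travel distances, per step or per unit of flux."""
    if isinstance(data, FluxMatrix):
        dom = domain or data.domain
        if dom is None:
            raise ValueError("a domain with geometry is required")
        D = dom.pairwise_distances()
        mask = ~np.eye(dom.N, dtype=bool) & (data.T > 0)
        values, weights = D[mask], data.T[mask]
    else:
        if domain is None:
            domain = data.domain
        if domain is None:
            raise ValueError("a domain with geometry is required")
        values, weights = step_distances(data, domain), None
    if bins == "log":
        return log_binned_density(values, weights, bins_per_decade)
    return linear_binned_density(values, weights, n_bins)


def flux_distance_decay(
    flux: FluxMatrix,
    domain: SpatialDomain | None = None,
    bins_per_decade: int = 10,
) -> pd.DataFrame:
    """Gravity distance-decay curve: mean pairwise flux vs distance.

    Bins the origin-destination pairs by distance (log bins) and averages
    the flux per pair within each bin.  On a fractal domain of dimension D
    this curve decays as d^-D (the distance-deterrence law T(d) ∝ d^-D of
    the one-step model), unlike the trip-length density of
    :func:`travel_distance_distribution`, whose pair-multiplicity factor
    d^(D-1) cancels the decay to ~d^-1.

    Returns a DataFrame with columns ``value`` (bin centre distance),
    ``density`` (mean flux per pair, for fitting) and ``n_pairs``.
    """
    dom = domain or flux.domain
    if dom is None:
        raise ValueError("a domain with geometry is required")
    D = dom.pairwise_distances()
    mask = ~np.eye(dom.N, dtype=bool)
    dist, T = D[mask], flux.T[mask]
    lo, hi = dist.min() * 0.999, dist.max() * 1.001
    n_bins = max(1, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    n_pairs, _ = np.histogram(dist, bins=edges)
    t_sum, _ = np.histogram(dist, bins=edges, weights=T)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = n_pairs > 0
    return pd.DataFrame({
        "value": centers[keep],
        "density": t_sum[keep] / n_pairs[keep],
        "n_pairs": n_pairs[keep],
    })


def distance_decay_fit_range(domain: SpatialDomain) -> tuple[float, float]:
    """Scaling window for the distance-decay exponent on a fractal domain:
    [4 * cell spacing, extent / 4].

    Below a few lattice cells the point set is discrete; above a fraction
    of the domain size the cumulative population W saturates at the total,
    flattening the kernel.  Requires fractal metadata on the domain.
    """
    meta = domain.meta
    if "ifs_scale" not in meta:
        raise ValueError("domain has no fractal metadata")
    cell = meta["extent"] * meta["ifs_scale"] ** meta["depth"]
    return (4.0 * cell, meta["extent"] / 4.0)


def ensemble_flux(ensemble: TrajectoryEnsemble) -> FluxMatrix:
    """Aggregate an ensemble's steps into an origin-destination FluxMatrix."""
    N = ensemble.n_locations
    if N is None:
        raise ValueError("ensemble has no location-set size")
    T = np.zeros((N, N))
    for traj in ensemble:
        a, b = traj.locations[:-1], traj.locations[1:]
        np.add.at(T, (a, b), 1.0)
    return FluxMatrix(T, domain=ensemble.domain)


def flux_distribution(
    flux: FluxMatrix, bins_per_decade: int = 10
) -> pd.DataFrame:
    """P(T): log-binned density of positive off-diagonal flux values."""
    vals = flux.off_diagonal()
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("flux matrix has no positive off-diagonal entries")
    return log_binned_density(vals, bins_per_decade=bins_per_decade)


# ----------------------------------------------------------------------
# power-law fitting

def fit_power_law(
    data,
    fit_range: tuple[float, float] | None = None,
    method: str = "logbin_lsq",
    bins_per_decade: int = 10,
    discrete: bool = False,
) -> PowerLawFit:
    """Fit density ∝ value**exponent.

    ``data`` is either a 1-D array of samples, or a binned density — a
    ``(value, density)`` pair of arrays or a DataFrame with those columns.
    The returned ``exponent`` is the signed log-log slope (negative for a
    decaying law); ``mle`` (samples only) reports ``-alpha`` of the Hill
    estimator with ``xmin = fit_range[0]``.
    """
    binned = None
    samples = None
    if isinstance(data, pd.DataFrame):
        binned = (data["value"].to_numpy(), data["density"].to_numpy())
    elif isinstance(data, tuple):
        binned = (np.asarray(data[0], float), np.asarray(data[1], float))
    else:
        samples = np.asarray(data, dtype=float)

    if method == "mle":
        if samples is None:
            raise ValueError("mle fitting requires raw samples")
        if fit_range is None:
            fit_range = (samples.min(), samples.max())
        x = samples[(samples >= fit_range[0]) & (samples <= fit_range[1])]
        if x.size < 10:
            raise ValueError("need at least 10 in-range points")
        xmin = fit_range[0] - 0.5 if discrete else fit_range[0]
        alpha = 1.0 + x.size / np.sum(np.log(x / xmin))
        stderr = (alpha - 1.0) / np.sqrt(x.size)
        return PowerLawFit(-alpha, tuple(fit_range), "mle", float(stderr))

    if method != "logbin_lsq":
        raise ValueError(f"unknown method {method!r}")

    if binned is None:
        if fit_range is not None:
            in_range = samples[(samples >= fit_range[0]) & (samples <= fit_range[1])]
            if in_range.size < 10:
                raise ValueError("need at least 10 in-range points")
        df = log_binned_density(samples, bins_per_decade=bins_per_decade)
        binned = (df["value"].to_numpy(), df["density"].to_numpy())
    xb, yb = binned
    if fit_range is None:
        fit_range = (xb.min(), xb.max())
    keep = (xb >= fit_range[0]) & (xb <= fit_range[1]) & (yb > 0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 nonempty bins in the fit range")
    res = _sps.linregress(np.log(xb[keep]), np.log(yb[keep]))
    return PowerLawFit(float(res.slope), tuple(fit_range), "logbin_lsq",
                       float(res.stderr))


def central_decades(df: pd.DataFrame, decades: float = 2.0) -> tuple[float, float]:
    """Range spanning ``decades`` around the geometric centre of the support
    of a binned density (bins with positive mass)."""
    support = df.loc[df["mass"] > 0, "value"]
    c = np.sqrt(support.min() * support.max())
    half = 10 ** (decades / 2.0)
    return (c / half, c * half)


def compute_statistics(
    ensemble: TrajectoryEnsemble, domain: SpatialDomain | None = None
) -> MobilityStatistics:
    """All individual-level observables (plus P(d)/P(T) when geometry exists)."""
    domain = domain or ensemble.domain
    dist_hist = flux_hist = None
    if domain is not None:
        dist_hist = travel_distance_distribution(ensemble, domain)
        flux = ensemble_flux(ensemble)
        if (flux.off_diagonal() > 0).any():
            flux_hist = flux_distribution(flux)
    return MobilityStatistics(
        S_curve=visited_count_curve(ensemble),
        return_hist=return_time_distribution(ensemble),
        rank_freq=visit_frequency_rank(ensemble),
        dist_hist=dist_hist,
        flux_hist=flux_hist,
    )
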