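"""Readers/writers for the package's delimited text formats, run
configuration, and the synthetic check-in fixture generator.

Formats (CSV with header, UTF-8, deterministic row order):

* ``locations.csv``  — id,x,y,m (see :func:`mobisim.domain.load_locations`)
* ``checkins.csv``   — user_id,timestamp,location_id
* ``traj.csv``       — traveler_id,step,location_id
* ``flux.csv``       — origin,destination,T
* per-observable statistics files (t,S / tau,p / r,f / d,p / T,p)
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .domain import SpatialDomain, load_locations
from .simplified import FluxMatrix
from .simulate import (
    DEFAULT_LENGTH_LAW,
    LengthLaw,
    MemoryParams,
    Trajectory,
    TrajectoryEnsemble,
    TruncatedPowerLawLength,
    simulate_ensemble,
)
from .stats import MobilityStatistics

logger = logging.getLogger("mobisim.io")


# ----------------------------------------------------------------------
# locations

def write_locations(domain: SpatialDomain, path) -> None:
    domain.to_frame().to_csv(path, index=False)


read_locations = load_locations


# ----------------------------------------------------------------------
# trajectories

def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    frames = []
    for traj in ensemble:
        frames.append(pd.DataFrame({
            "traveler_id": traj.traveler_id,
            "step": np.arange(len(traj.locations)),
            "location_id": traj.locations,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path, domain: SpatialDomain | None = None) -> TrajectoryEnsemble:
    df = pd.read_csv(path)
    trajs = []
    for tid, grp in df.sort_values(["traveler_id", "step"]).groupby("traveler_id"):
        locs = grp["location_id"].to_numpy()
        if domain is not None and (locs.min() < 0 or locs.max() >= domain.N):
            raise ValueError(f"traveler {tid}: location id outside the domain")
        trajs.append(Trajectory(int(tid), locs))
    return TrajectoryEnsemble(trajs, domain=domain)


# ----------------------------------------------------------------------
# check-ins

@dataclass(frozen=True)
class CheckinRecord:
    user_id: int
    timestamp: str
    location_id: int


def read_checkins(path, domain: SpatialDomain) -> TrajectoryEnsemble:
    """Load check-in records into per-user trajectories.

    Records are sorted per user by timestamp (or by file order when the
    timestamp column is absent); consecutive check-ins at the same location
    collapse into a single entry (a repeated check-in in one city is not a
    travel step); users left with fewer than 2 entries are dropped.  Each
    user's home is their most frequently visited location, ties broken by
    earliest first visit; homes are reported on the returned ensemble.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"user_id", "location_id"}
    if not required <= set(df.columns):
        raise ValueError(f"check-in file must have columns {sorted(required)}")
    bad = ~df["location_id"].isin(range(domain.N))
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(
            f"unresolvable location id {df.loc[bad, 'location_id'].iloc[0]} "
            f"at line {lineno}"
        )
    sort_cols = ["user_id"] + (["timestamp"] if "timestamp" in df.columns else [])
    df = df.sort_values(sort_cols, kind="stable")
    trajs, homes = [], []
    n_dropped = 0
    for uid, grp in df.groupby("user_id", sort=True):
        locs = grp["location_id"].to_numpy()
        keep = np.ones(len(locs), dtype=bool)
        keep[1:] = locs[1:] != locs[:-1]
        locs = locs[keep]
        if len(locs) < 2:
            n_dropped += 1
            continue
        vals, first_idx, counts = np.unique(locs, return_index=True, return_counts=True)
        best = np.lexsort((first_idx, -counts))[0]  # max count, earliest first visit
        homes.append(int(vals[best]))
        trajs.append(Trajectory(int(uid), locs))
    if n_dropped:
        logger.info("dropped %d users with fewer than 2 distinct consecutive "
                    "check-ins", n_dropped)
    return TrajectoryEnsemble(trajs, domain=domain, homes=np.array(homes, dtype=np.int64))


def write_checkins(ensemble: TrajectoryEnsemble, path, start="2020-01-01",
                   step_days: int = 1) -> None:
    """Write an ensemble as timestamped check-in records (one step = one day)."""
    t0 = pd.Timestamp(start)
    frames = []
    for traj in ensemble:
        ts = t0 + pd.to_timedelta(np.arange(len(traj.locations)) * step_days, unit="D")
        frames.append(pd.DataFrame({
            "user_id": traj.traveler_id,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "location_id": traj.locations,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def generate_synthetic_checkins(
    domain: SpatialDomain,
    params: MemoryParams,
    n_users: int,
    seed: int = 0,
    path=None,
    length_law: LengthLaw | None = None,
) -> TrajectoryEnsemble:
    """Simulate the full model and (optionally) emit a check-in fixture file."""
    ens = simulate_ensemble(domain, n_users, length_law=length_law or DEFAULT_LENGTH_LAW,
                            params=params, seed=seed)
    if path is not None:
        write_checkins(ens, path)
    return ens


# ----------------------------------------------------------------------
# fluxes and statistics

def write_flux(flux: FluxMatrix, path) -> None:
    df = flux.to_frame().sort_values(["origin", "destination"])
    df.to_csv(path, index=False)


def read_flux(path, N: int | None = None, domain: SpatialDomain | None = None) -> FluxMatrix:
    df = pd.read_csv(path)
    if domain is not None:
        N = domain.N
    if N is None:
        N = int(max(df["origin"].max(), df["destination"].max())) + 1
    T = np.zeros((N, N))
    T[df["origin"].to_numpy(), df["destination"].to_numpy()] = df["T"].to_numpy()
    return FluxMatrix(T, domain=domain)


def write_statistics(statistics: MobilityStatistics, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    statistics.S_curve.to_csv(outdir / "s_curve.csv", index=False)
    statistics.return_hist.rename_axis("tau").to_frame("p").to_csv(
        outdir / "return_times.csv")
    statistics.rank_freq.rename_axis("r").to_frame("f").to_csv(
        outdir / "rank_freq.csv")
    if statistics.dist_hist is not None:
        statistics.dist_hist.rename(columns={"value": "d", "density": "p"}).to_csv(
            outdir / "distance_hist.csv", index=False)
    if statistics.flux_hist is not None:
        statistics.flux_hist.rename(columns={"value": "T", "density": "p"}).to_csv(
            outdir / "flux_hist.csv", index=False)


# ----------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Serializable run configuration (YAML round-trip safe)."""

    lam: float = 0.0
    seed: int = 0
    n_travelers: int = 1000
    length_law: dict = field(default_factory=lambda: {
        "kind": "truncated_power_law", "exponent": 1.5, "lmin": 10, "lmax": 1000})
    domain_source: str | None = None
    output: str | None = None
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def make_length_law(self) -> LengthLaw:
        spec = dict(self.length_law)
        kind = spec.pop("kind", "truncated_power_law")
        if kind == "truncated_power_law":
            return TruncatedPowerLawLength(**spec)
        if kind == "fixed":
            from .simulate import FixedLength
            return FixedLength(**spec)
        raise ValueError(f"unknown length law {kind!r}")
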