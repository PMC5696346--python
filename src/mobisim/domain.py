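"""Populated spatial domains: location tables, the cumulative-population
kernel W, and synthetic / fractal domain generators.

The central object is :class:`SpatialDomain`, a set of locations with planar
coordinates (km) and positive integer populations.  The model's competition
kernel needs, for every ordered pair (origin *i*, destination *j*), the total
population ``W[j, i]`` inside the circle centred at *j* whose radius is the
*j*–*i* distance.  The circle is boundary-inclusive: every location at
distance exactly ``d(j, i)`` from *j* (including *i* itself and *j*) counts,
so ``W[j, i] >= m_i + m_j`` and the destination weight ``m_j / W[j, i]`` is
bounded by 1.  Distance ties are compared with a small relative tolerance so
that symmetric configurations (equilateral triangles, lattice points of
fractal domains) resolve deterministically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger("mobisim.domain")

#: relative tolerance used when deciding whether two inter-location
#: distances are tied (boundary-inclusive circle membership).
TIE_RTOL = 1e-9

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Location:
    """A single populated location."""

    id: int
    x: float
    y: float
    m: int


@dataclass(frozen=True)
class FractalDomainSpec:
    """Recipe for an iterated-function-system (IFS) point set.

    family : one of ``cantor_dust_2d``, ``vicsek``, ``sierpinski_triangle``,
        ``hexaflake``.
    depth : number of IFS iterations (>= 1); the point count is
        ``copies ** depth``.
    extent : nominal linear size of the domain in km.
    """

    family: str
    depth: int
    extent: float = 100.0


# family -> (copy count, contraction ratio, exact dimension)
FRACTAL_FAMILIES: dict[str, tuple[int, float, float]] = {
    "cantor_dust_2d": (4, 1 / 3, math.log(4) / math.log(3)),
    "vicsek": (5, 1 / 3, math.log(5) / math.log(3)),
    "sierpinski_triangle": (3, 1 / 2, math.log(3) / math.log(2)),
    "hexaflake": (7, 1 / 3, math.log(7) / math.log(3)),
}


class SpatialDomain:
    """A set of populated locations with a lazy cumulative-population kernel.

    Parameters
    ----------
    x, y : array-like of float
        Planar coordinates in km.
    m : array-like of int
        Population of each location (>= 1).
    meta : optional dict of provenance attributes (fractal family, extent...).
    """

    def __init__(self, x, y, m, meta: dict | None = None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.m = np.asarray(m)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.shape != self.m.shape:
            raise ValueError("x, y, m must be 1-D arrays of equal length")
        if self.x.size == 0:
            raise ValueError("domain must contain at least one location")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if np.any(self.m < 1) or not np.issubdtype(self.m.dtype, np.number):
            raise ValueError("populations must be positive (>= 1)")
        self.m = self.m.astype(np.int64)
        self.meta = dict(meta or {})
        self._W: np.ndarray | None = None
        self._B: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def N(self) -> int:
        return self.x.size

    @property
    def total_population(self) -> int:
        return int(self.m.sum())

    def __len__(self) -> int:
        return self.N

    def location(self, i: int) -> Location:
        return Location(i, float(self.x[i]), float(self.y[i]), int(self.m[i]))

    def distances_from(self, j: int) -> np.ndarray:
        """Euclidean distances (km) from location *j* to every location."""
        return np.hypot(self.x - self.x[j], self.y - self.y[j])

    def pairwise_distances(self) -> np.ndarray:
        dx = self.x[:, None] - self.x[None, :]
        dy = self.y[:, None] - self.y[None, :]
        return np.hypot(dx, dy)

    # ------------------------------------------------------------------
    def w_row(self, j: int) -> np.ndarray:
        """Cumulative population ``W[j, i]`` for a single centre *j*.

        ``W[j, i]`` sums ``m_k`` over every *k* with ``d(j, k) <= d(j, i)``
        (boundary-inclusive, ties within :data:`TIE_RTOL`).
        """
        d = self.distances_from(j)
        order = np.argsort(d, kind="stable")
        ds = d[order]
        csum = np.cumsum(self.m[order])
        # inclusive tie handling: nudge the query distance up by a hair
        idx = np.searchsorted(ds, d * (1.0 + TIE_RTOL) + 1e-12, side="right") - 1
        return csum[idx]

    @property
    def W(self) -> np.ndarray:
        """Full cumulative-population matrix, ``W[j, i]`` (centre j, ref i).

        Computed once by per-centre neighbour sort + prefix sums
        (O(N^2 log N)) and cached.
        """
        if self._W is None:
            W = np.empty((self.N, self.N), dtype=np.int64)
            for j in range(self.N):
                W[j] = self.w_row(j)
            self._W = W
        return self._W

    def competition_matrix(self) -> np.ndarray:
        """Destination-weight matrix ``B[i, j] = m_j / W[j, i]``, zero diagonal."""
        if self._B is None:
            B = (self.m[:, None] / self.W).T
            np.fill_diagonal(B, 0.0)
            self._B = B
        return self._B

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": np.arange(self.N), "x": self.x, "y": self.y, "m": self.m}
        )


# ----------------------------------------------------------------------
# loading

REQUIRED_COLUMNS = ("id", "x", "y", "m")


def load_locations(source) -> SpatialDomain:
    """Build a :class:`SpatialDomain` from a delimited table or DataFrame.

    The table must carry columns ``id,x,y,m`` (comma- or tab-delimited with a
    header when read from disk).  If ``lon,lat`` columns are present instead
    of ``x,y``, coordinates are converted to km with a local equirectangular
    projection about the mean latitude.  Ids must be unique and contiguous
    from 0; populations must be positive integers.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    cols = set(df.columns)
    if {"lon", "lat"} <= cols and not {"x", "y"} <= cols:
        lat0 = math.radians(df["lat"].mean())
        df["x"] = np.radians(df["lon"]) * math.cos(lat0) * EARTH_RADIUS_KM
        df["y"] = np.radians(df["lat"]) * EARTH_RADIUS_KM
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"location table missing column(s): {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate location id(s): {dupes}")
    if (df["m"] < 1).any() or not np.allclose(df["m"], np.round(df["m"])):
        raise ValueError("populations must be positive integers (m >= 1)")
    df = df.sort_values("id").reset_index(drop=True)
    ids = df["id"].to_numpy()
    if not np.array_equal(ids, np.arange(len(df))):
        raise ValueError("location ids must be contiguous integers from 0")
    return SpatialDomain(df["x"].to_numpy(), df["y"].to_numpy(), df["m"].to_numpy())


# ----------------------------------------------------------------------
# fractal generators

def _square_ifs_offsets(family: str) -> np.ndarray:
    if family == "cantor_dust_2d":
        return np.array([(0, 0), (2 / 3, 0), (0, 2 / 3), (2 / 3, 2 / 3)])
    if family == "vicsek":
        return np.array([(0, 0), (2 / 3, 0), (0, 2 / 3), (2 / 3, 2 / 3), (1 / 3, 1 / 3)])
    if family == "sierpinski_triangle":
        return np.array([(0, 0), (1 / 2, 0), (0, 1 / 2)])
    raise KeyError(family)


def fractal_points(spec: FractalDomainSpec) -> np.ndarray:
    """Deterministic IFS point set for *spec*, in a box of side ``extent``.

    Each point is the centre of a depth-``depth`` cell, so box grids aligned
    with the contraction ratio count occupied cells exactly.
    """
    if spec.family not in FRACTAL_FAMILIES:
        raise ValueError(
            f"unknown fractal family {spec.family!r}; "
            f"choose from {sorted(FRACTAL_FAMILIES)}"
        )
    if spec.depth < 1:
        raise ValueError("depth must be >= 1")
    copies, scale, _ = FRACTAL_FAMILIES[spec.family]

    if spec.family == "hexaflake":
        # centre copy + six copies at the hexagon vertices, contraction 1/3
        angles = np.arange(6) * (math.pi / 3)
        offs = np.vstack([[0.0, 0.0], (2 / 3) * np.column_stack([np.cos(angles), np.sin(angles)])])
        pts = np.array([[0.0, 0.0]])
        for _ in range(spec.depth):
            pts = (pts[None, :, :] * scale + offs[:, None, :]).reshape(-1, 2)
        # raw set spans [-1, 1]; rescale so the width equals `extent`
        pts = (pts + 1.0) * (spec.extent / 2.0)
        return pts

    offs = _square_ifs_offsets(spec.family)
    pts = np.array([[0.5, 0.5]])  # cell centre seed keeps points off box edges
    for _ in range(spec.depth):
        pts = (pts[None, :, :] * scale + offs[:, None, :]).reshape(-1, 2)
    return pts * spec.extent


def generate_fractal_domain(spec: FractalDomainSpec, m_uniform: int = 1) -> SpatialDomain:
    """Generate the fractal point set of *spec* with uniform populations."""
    if m_uniform < 1:
        raise ValueError("m_uniform must be >= 1")
    pts = fractal_points(spec)
    m = np.full(len(pts), int(m_uniform), dtype=np.int64)
    meta = {
        "family": spec.family,
        "depth": spec.depth,
        "extent": spec.extent,
        "ifs_scale": FRACTAL_FAMILIES[spec.family][1],
    }
    return SpatialDomain(pts[:, 0], pts[:, 1], m, meta=meta)


def fractal_box_sizes(spec: FractalDomainSpec) -> np.ndarray:
    """Box sizes aligned with the IFS contraction: ``extent * scale**k``."""
    _, scale, _ = FRACTAL_FAMILIES[spec.family]
    return spec.extent * scale ** np.arange(1, spec.depth + 1)


def _box_counts(x: np.ndarray, y: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Occupied-box counts for grids anchored at the per-axis minimum."""
    x0, y0 = x.min(), y.min()
    counts = np.empty(len(sizes), dtype=np.int64)
    for k, s in enumerate(sizes):
        ix = np.floor((x - x0) / s + 1e-9).astype(np.int64)
        iy = np.floor((y - y0) / s + 1e-9).astype(np.int64)
        counts[k] = len(np.unique(ix + (iy << 32)))
    return counts


def _check_box_sizes(sizes: np.ndarray) -> None:
    if sizes.size < 3:
        raise ValueError("need at least 3 box sizes")
    span = math.log10(sizes.max() / sizes.min())
    if span < 1.5:
        raise ValueError(f"box sizes must span >= 1.5 decades (got {span:.2f})")


def box_counting_dimension(
    domain: SpatialDomain, box_sizes: Sequence[float]
) -> float:
    """Box-counting dimension: LSQ slope of log(occupied boxes) vs log(1/size).

    Requires at least three box sizes spanning >= 1.5 decades.  Box grids are
    anchored at the per-axis minimum of the point set.  A degenerate point
    set (all points identical) returns 0 with a warning.

    The estimate is only meaningful for box sizes above the resolution of
    the point set; for IFS approximants counted down to their own cell scale
    use :func:`estimate_fractal_dimension`, which refines the approximant
    first.
    """
    sizes = np.asarray(box_sizes, dtype=float)
    _check_box_sizes(sizes)
    if np.ptp(domain.x) == 0 and np.ptp(domain.y) == 0:
        logger.warning("degenerate point set: box-counting dimension is 0")
        return 0.0
    counts = _box_counts(domain.x, domain.y, sizes)
    res = _sps.linregress(np.log(1.0 / sizes), np.log(counts))
    return float(res.slope)


def estimate_fractal_dimension(spec: FractalDomainSpec, refine: int = 2) -> float:
    """Box-counting dimension of the fractal of *spec* at sizes
    ``extent * scale**k`` for k = 1..depth.

    The occupied-box counts are taken on the approximant refined ``refine``
    IFS levels below the finest box, so every box size lies above the
    sampling resolution of the point set.  For the grid-aligned families
    (Cantor dust, Vicsek, right-triangle Sierpinski) refinement leaves the
    counts exactly ``copies**k``; for the hexaflake it removes the
    finest-scale undercount of square boxes the size of the hexagonal cells.
    """
    sizes = fractal_box_sizes(spec)
    _check_box_sizes(sizes)
    pts = fractal_points(
        FractalDomainSpec(spec.family, spec.depth + refine, spec.extent)
    )
    counts = _box_counts(pts[:, 0], pts[:, 1], sizes)
    res = _sps.linregress(np.log(1.0 / sizes), np.log(counts))
    return float(res.slope)


# ----------------------------------------------------------------------
# synthetic heterogeneous domains

def generate_synthetic_population(
    n_locations: int,
    zipf_exponent: float = 1.0,
    extent: float = 100.0,
    seed: int | None = 0,
    m_max: int = 10_000,
) -> SpatialDomain:
    """Random square domain with Zipf (rank-size) distributed populations.

    Coordinates are uniform in a square of side ``extent``; the rank-*r*
    population is ``max(1, round(m_max * r**-zipf_exponent))``, shuffled over
    the locations so city size is spatially unordered.  Reproducible under a
    fixed seed.
    """
    if n_locations < 2:
        raise ValueError("need at least 2 locations")
    if zipf_exponent <= 0:
        raise ValueError("zipf_exponent must be positive")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, extent, size=(n_locations, 2))
    ranks = np.arange(1, n_locations + 1, dtype=float)
    sizes = np.maximum(1, np.round(m_max * ranks ** (-zipf_exponent))).astype(np.int64)
    rng.shuffle(sizes)
    return SpatialDomain(
        xy[:, 0], xy[:, 1], sizes,
        meta={"kind": "synthetic_zipf", "zipf_exponent": zipf_exponent, "extent": extent},
    )
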