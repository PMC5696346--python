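"""Home-return loop extraction and motif census.

A trajectory that starts at the traveler's home is split at every return to
home; each segment (home ... home) is a *home loop*.  The loop's motif is
the simple directed graph on its distinct locations, one edge per observed
transition with multiplicities collapsed, identified up to relabeling of the
nodes (the home node is not distinguished).  Canonical ids are computed by
brute-force minimization over node permutations — loops with more than
``MAX_MOTIF_NODES`` distinct nodes are lumped into a single ``other`` bucket,
since high-order topologies are combinatorially explosive and empirically
rare.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .simulate import Trajectory, TrajectoryEnsemble

logger = logging.getLogger("mobisim.motifs")

MAX_MOTIF_NODES = 6
OTHER_MOTIF_ID = "other"

HomeLoop = np.ndarray  # ordered ids, first == last == home, length >= 3


def segment_home_loops(
    trajectory: Trajectory | np.ndarray, home: int | None = None
) -> list[HomeLoop]:
    """Split a trajectory into home-return loops.

    The trajectory must start at ``home`` (default: its first entry).  A
    trailing segment that never returns home is discarded (logged).
    """
    path = trajectory.locations if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    if home is None:
        home = int(path[0])
    if path[0] != home:
        raise ValueError("trajectory must start at the home location")
    if not np.any(path == home):
        raise ValueError("home absent from trajectory")
    returns = np.flatnonzero(path == home)
    loops: list[HomeLoop] = []
    for a, b in zip(returns[:-1], returns[1:]):
        loops.append(path[a: b + 1])
    tail = len(path) - 1 - returns[-1]
    if tail > 0:
        logger.debug("discarded a %d-step tail that does not return home", tail)
    return loops


@lru_cache(maxsize=None)
def _canonical_edges(n: int, edges: frozenset[tuple[int, int]]) -> str:
    """Lexicographically minimal edge list over all node relabelings."""
    best = None
    for perm in itertools.permutations(range(n)):
        relabeled = sorted((perm[a], perm[b]) for a, b in edges)
        if best is None or relabeled < best:
            best = relabeled
    return f"{n}:" + ",".join(f"{a}>{b}" for a, b in best)


def canonical_motif_id(loop: HomeLoop) -> str:
    """Relabeling-invariant id of a loop's simple directed-graph topology.

    Nodes are the loop's distinct locations, edges the observed transitions
    (collapsed); the id is the sorted edge list under the canonical (minimal)
    labeling, serialized as ``"<n>:a>b,c>d,..."``.  Loops with more than
    :data:`MAX_MOTIF_NODES` nodes map to ``"other"``.
    """
    loop = np.asarray(loop)
    if len(loop) < 3 or loop[0] != loop[-1]:
        raise ValueError("a home loop must start and end at home (>= 2 steps)")
    label: dict[int, int] = {}
    for loc in loop:
        if int(loc) not in label:
            label[int(loc)] = len(label)
    n = len(label)
    if n > MAX_MOTIF_NODES:
        return OTHER_MOTIF_ID
    edges = frozenset(
        (label[int(a)], label[int(b)]) for a, b in zip(loop[:-1], loop[1:])
    )
    return _canonical_edges(n, edges)


@dataclass
class MotifCensus:
    """Motif frequencies pooled over an ensemble's home loops."""

    counts: dict[str, int]
    total: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    def top(self, k: int = 9, include_other: bool = False) -> list[tuple[str, float]]:
        """The k most frequent motifs as (id, frequency), descending.

        The ``other`` bucket (loops beyond :data:`MAX_MOTIF_NODES` nodes) is
        an aggregation artifact, not a topology, and is excluded unless
        ``include_other`` is set.
        """
        items = self.frequencies.items()
        if not include_other:
            items = [kv for kv in items if kv[0] != OTHER_MOTIF_ID]
        return sorted(items, key=lambda kv: -kv[1])[:k]

    def top_mass(self, k: int = 9, include_other: bool = False) -> float:
        """Summed frequency of the k most frequent motifs."""
        return sum(f for _, f in self.top(k, include_other))

    def tail_mass(self, k: int = 9) -> float:
        """Frequency mass outside the k most frequent motifs."""
        return 1.0 - self.top_mass(k)


def motif_census(ensemble: TrajectoryEnsemble) -> MotifCensus:
    """Census motif topologies over all home loops of all travelers.

    Homes default to each trajectory's first entry (the model starts every
    traveler at home).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    counts: dict[str, int] = {}
    total = 0
    for traj in ensemble:
        for loop in segment_home_loops(traj):
            mid = canonical_motif_id(loop)
            counts[mid] = counts.get(mid, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no home-return loops in the ensemble")
    return MotifCensus(counts, total)
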