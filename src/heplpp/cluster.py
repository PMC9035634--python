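"""Sensor-level non-parametric cluster-based permutation tests.

Per-electrode two-sample t values are thresholded at a cluster-forming
alpha, supra-threshold electrodes of common sign are grouped into clusters
connected in the electrode adjacency graph, and each cluster's mass (sum of
member t values) is referred to the permutation distribution of the maximum
absolute cluster mass under random relabeling of subjects.  When the number
of distinct relabelings does not exceed the requested permutation count the
null distribution is enumerated exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as spstats
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from heplpp.io import Montage

__all__ = ["Adjacency", "Cluster", "ClusterResult", "build_adjacency", "cluster_permutation_test"]

logger = logging.getLogger(__name__)


@dataclass
class Adjacency:
    """Symmetric electrode neighbor structure."""

    labels: list[str]
    neighbors: list[list[int]]  # index-based adjacency lists, no self-edges

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.neighbors) != n:
            raise ValueError("one neighbor list per label required")
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"self-edge at electrode {self.labels[i]}")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def is_connected(self) -> bool:
        import networkx as nx

        return nx.is_connected(self.to_graph()) if len(self) else False

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        for i, nb in enumerate(self.neighbors):
            g.add_edges_from((i, j) for j in nb if j > i)
        return g


def _edges_from_delaunay(pts: np.ndarray) -> set[tuple[int, int]]:
    tri = Delaunay(pts)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def build_adjacency(
    montage: Montage, method: str = "delaunay", distance_quantile: float = 0.15
) -> Adjacency:
    """Electrode adjacency from the montage's 2-D projection.

    ``delaunay`` (default) takes the triangulation edges; ``distance``
    connects pairs closer than the given quantile of all pairwise
    distances.  A degenerate (collinear) montage falls back to the
    distance method with a warning.
    """
    pts = montage.projected_2d()
    if len(montage) < 3:
        raise ValueError("need at least 3 electrodes for an adjacency graph")
    if method == "delaunay":
        try:
            edges = _edges_from_delaunay(pts)
        except (QhullError, ValueError):
            warnings.warn(
                "degenerate montage geometry; falling back to distance adjacency",
                stacklevel=2,
            )
            method = "distance"
    if method == "distance":
        d = squareform(pdist(pts))
        thresh = np.quantile(d[np.triu_indices(len(montage), k=1)], distance_quantile)
        edges = {
            (i, j)
            for i in range(len(montage))
            for j in range(i + 1, len(montage))
            if d[i, j] <= thresh
        }
    elif method != "delaunay":
        raise ValueError(f"unknown adjacency method {method!r}")
    neighbors: list[list[int]] = [[] for _ in montage.labels]
    for i, j in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    return Adjacency(list(montage.labels), [sorted(nb) for nb in neighbors])


@dataclass
class Cluster:
    electrodes: list[str]
    mass: float
    sign: int
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    labels: list[str]
    forming_threshold: float
    n_perm: int
    exact: bool

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def _pooled_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Two-sample pooled-variance t per electrode from sufficient statistics."""
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = sumsq_b - n_b * mean_b**2
    sp2 = (ss_a + ss_b) / (n_a + n_b - 2)
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1.0), 0.0)
    return t


def _find_clusters(t: np.ndarray, thresh: float, neighbors: list[list[int]]):
    """Signed connected components among supra-threshold electrodes (BFS)."""
    supra = np.abs(t) > thresh
    seen = np.zeros(t.size, dtype=bool)
    out = []
    for start in np.flatnonzero(supra):
        if seen[start]:
            continue
        sign = 1 if t[start] > 0 else -1
        stack, members = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            members.append(i)
            for j in neighbors[i]:
                if supra[j] and not seen[j] and (t[j] > 0) == (sign > 0):
                    seen[j] = True
                    stack.append(j)
        out.append((members, float(t[members].sum()), sign))
    return out


def _max_mass(t: np.ndarray, thresh: float, neighbors) -> float:
    cl = _find_clusters(t, thresh, neighbors)
    return max((abs(m) for _, m, _ in cl), default=0.0)


def cluster_permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    adjacency: Adjacency,
    forming_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> ClusterResult:
    """Two-sample cluster-based permutation test over electrodes.

    ``values_a`` and ``values_b`` are subjects x electrodes matrices on the
    same electrode set as ``adjacency``.  The observed t map uses the
    pooled-variance two-sample t (group A minus group B); the null is built
    by permuting subject group labels.  Monte-Carlo p values use the
    add-one rule ``(1 + #{perm >= obs}) / (1 + n_perm)``; with exhaustive
    enumeration p is the exact proportion over all distinct relabelings.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1] or a.shape[1] != len(adjacency):
        raise ValueError("electrode sets of the two groups and adjacency must match")

    n = n_a + n_b
    df = n - 2
    thresh = float(spstats.t.ppf(1.0 - forming_alpha / 2.0, df))
    x = np.vstack([a, b])
    xsq = x**2
    all_idx = np.arange(n)

    def t_for(idx_a: np.ndarray) -> np.ndarray:
        # sum both groups explicitly (not total minus group A): keeps the
        # complementary relabeling exactly antisymmetric in floating point
        in_a = np.zeros(n, dtype=bool)
        in_a[idx_a] = True
        idx_b = all_idx[~in_a]
        sa, sqa = x[np.sort(idx_a)].sum(axis=0), xsq[np.sort(idx_a)].sum(axis=0)
        sb, sqb = x[idx_b].sum(axis=0), xsq[idx_b].sum(axis=0)
        return _pooled_t(sa, sqa, n_a, sb, sqb, n_b)

    t_obs = t_for(np.arange(n_a))
    found = _find_clusters(t_obs, thresh, adjacency.neighbors)

    n_distinct = comb(n, n_a)
    exact = n_distinct <= n_perm
    null_max = []
    if exact:
        logger.info("only %d distinct relabelings; using exact enumeration", n_distinct)
        for idx in combinations(range(n), n_a):
            null_max.append(_max_mass(t_for(np.array(idx)), thresh, adjacency.neighbors))
        null_max = np.array(null_max)
        denom = float(n_distinct)
        count_offset = 0
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            idx = rng.permutation(n)[:n_a]
            null_max.append(_max_mass(t_for(idx), thresh, adjacency.neighbors))
        null_max = np.array(null_max)
        denom = float(n_perm + 1)
        count_offset = 1

    clusters = []
    for members, mass, sign in found:
        count = int(np.sum(null_max >= abs(mass)))
        p = (count_offset + count) / denom
        clusters.append(
            Cluster([adjacency.labels[i] for i in members], mass, sign, float(p))
        )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(clusters, t_obs, list(adjacency.labels), thresh, n_perm, exact)
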