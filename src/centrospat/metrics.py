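"""Six clustering metrics for nuclear spot patterns.

* Ripley's K function and the derived *clustering percentage* (fraction of
  evaluation radii at which K(r) exceeds the homogeneous-Poisson expectation
  pi r^2, times 100),
* assortativity and Louvain modularity on a k-nearest-neighbour graph with
  inverse-squared-distance edge weights,
* Moran's I spatial autocorrelation with 1/d^2 weights,
* mean nearest-neighbour distance (MNND), and
* the dispersion index (variance over mean of the pairwise distances).

K(r) follows the plain unscaled estimator ``(A/N^2) * sum_{i != j} I(d_ij <= r)``
with no edge correction; the clustering percentage therefore saturates at
100 for a tightly clustered pattern and sits at 0 for hard-core patterns,
whose K stays below pi r^2 at every radius.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import InsufficientPointsError, InvalidParameterError, SpotPattern

#: Coincident spots closer than this (px) have their k-NN edge weight capped
#: at 1/eps^2 to keep the graph finite.
COINCIDENT_EPS = 0.5

#: Errors treated as "metric unavailable for this pattern" by the batch path.
_METRIC_ERRORS = (InsufficientPointsError, InvalidParameterError)


@dataclass(frozen=True)
class RadiiGrid:
    """Evaluation radii for Ripley's K: ``n_steps`` equal steps from 0.

    The grid holds ``n_steps + 1`` radii including 0; the clustering
    percentage divides by ``n_steps`` so that a pattern exceeding the Poisson
    expectation at every positive radius scores exactly 100.
    """

    r_max: float = 46.0
    n_steps: int = 50

    def __post_init__(self):
        if self.r_max <= 0 or self.n_steps < 1:
            raise InvalidParameterError("r_max must be > 0 and n_steps >= 1")

    @property
    def radii(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_steps + 1)


@dataclass(frozen=True)
class MetricSettings:
    """Shared metric parameters: graph k, Ripley grid, Louvain seed."""

    k: int = 10
    radii: RadiiGrid | None = None
    louvain_seed: int = 0

    def grid_for(self, pattern: SpotPattern) -> RadiiGrid:
        if self.radii is not None:
            return self.radii
        return RadiiGrid(r_max=pattern.region.radius)


@dataclass
class MetricVector:
    """The six metric values for one pattern; missing entries are None."""

    ripley_clustering_pct: float | None = None
    assortativity: float | None = None
    modularity: float | None = None
    morans_i: float | None = None
    mnnd: float | None = None
    dispersion_index: float | None = None

    _FIELDS = (
        "ripley_clustering_pct",
        "assortativity",
        "modularity",
        "morans_i",
        "mnnd",
        "dispersion_index",
    )

    def as_dict(self) -> dict[str, float | None]:
        return {f: getattr(self, f) for f in self._FIELDS}


# ---------------------------------------------------------------------------
# Ripley's K
# ---------------------------------------------------------------------------

def ripley_k(pattern: SpotPattern, radii=None) -> np.ndarray:
    """K(r) = (A/N^2) * #{ordered pairs i != j with d_ij <= r}."""
    if pattern.n_spots < 2:
        raise InsufficientPointsError("Ripley's K needs at least 2 spots")
    grid = radii.radii if isinstance(radii, RadiiGrid) else np.asarray(
        RadiiGrid(r_max=pattern.region.radius).radii if radii is None else radii,
        dtype=float,
    )
    d = np.sort(pdist(pattern.spots))
    return _ripley_k_sorted(d, pattern.n_spots, pattern.region.area, grid)


def _ripley_k_sorted(sorted_d, n, area, radii) -> np.ndarray:
    # each unordered pair within r contributes twice (both ordered pairs)
    counts = 2.0 * np.searchsorted(sorted_d, radii, side="right")
    return area / (n * n) * counts


def ripley_clustering_percentage(pattern: SpotPattern, radii: RadiiGrid | None = None) -> float:
    """Percentage of radii at which K(r) exceeds the CSR expectation pi r^2."""
    grid = radii if radii is not None else RadiiGrid(r_max=pattern.region.radius)
    k = ripley_k(pattern, grid)
    exceed = int(np.sum(k - np.pi * grid.radii**2 > 0))
    return 100.0 * exceed / grid.n_steps


def _clustering_pct_sorted(sorted_d, n, area, grid: RadiiGrid) -> float:
    r = grid.radii
    k = _ripley_k_sorted(sorted_d, n, area, r)
    return 100.0 * int(np.sum(k - np.pi * r**2 > 0)) / grid.n_steps


# ---------------------------------------------------------------------------
# k-NN graph, assortativity, modularity
# ---------------------------------------------------------------------------

@dataclass
class SpatialGraph:
    """Undirected k-NN graph over spots with 1/d^2 edge weights."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int, i < j
    weights: np.ndarray  # (E,) float

    def strengths(self) -> np.ndarray:
        """Weighted degree (strength) per node."""
        s = np.zeros(self.n_nodes)
        np.add.at(s, self.edges[:, 0], self.weights)
        np.add.at(s, self.edges[:, 1], self.weights)
        return s

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            (int(i), int(j), float(w)) for (i, j), w in zip(self.edges, self.weights)
        )
        return g

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


def _knn_edges(dmat: np.ndarray, k: int):
    n = dmat.shape[0]
    # the k+1 smallest per row include the point itself at distance 0
    nbr = np.argpartition(dmat, kth=k, axis=1)[:, : k + 1]
    rows = np.repeat(np.arange(n), k + 1)
    cols = nbr.ravel()
    keep = rows != cols
    rows, cols = rows[keep], cols[keep]
    i = np.minimum(rows, cols)
    j = np.maximum(rows, cols)
    pairs = np.unique(np.column_stack([i, j]), axis=0)
    d = np.maximum(dmat[pairs[:, 0], pairs[:, 1]], COINCIDENT_EPS)
    return pairs, 1.0 / d**2


def build_knn_graph(pattern: SpotPattern, k: int = 10) -> SpatialGraph:
    """Symmetrized k-nearest-neighbour graph with 1/d^2 weights.

    Coincident or near-coincident spots (d < 0.5 px) get their weight capped
    at 1/0.5^2 so that weights stay finite.
    """
    n = pattern.n_spots
    if n <= k:
        raise InsufficientPointsError(f"k-NN graph with k={k} needs > {k} spots")
    dmat = squareform(pdist(pattern.spots))
    edges, weights = _knn_edges(dmat, k)
    return SpatialGraph(n, edges, weights)


def assortativity(graph: SpatialGraph, return_flag: bool = False):
    """Pearson correlation of endpoint strengths over the (directed) edge list.

    Degenerate graphs in which every endpoint has the same strength have an
    undefined correlation; they return 0, flagged when ``return_flag``.
    """
    if len(graph.edges) < 2:
        raise InsufficientPointsError("assortativity needs at least 2 edges")
    s = graph.strengths()
    a = np.concatenate([s[graph.edges[:, 0]], s[graph.edges[:, 1]]])
    b = np.concatenate([s[graph.edges[:, 1]], s[graph.edges[:, 0]]])
    va = a.var()
    if va < 1e-30:
        return (0.0, True) if return_flag else 0.0
    r = float(((a - a.mean()) * (b - b.mean())).mean() / va)
    return (r, False) if return_flag else r


def _louvain_partition(g: ig.Graph, seed: int):
    state = _pyrandom.getstate()
    _pyrandom.seed(seed)
    try:
        return g.community_multilevel(weights="weight")
    finally:
        _pyrandom.setstate(state)


def modularity_louvain(graph: SpatialGraph, seed: int = 0, return_partition: bool = False):
    """Weighted modularity Q of the Louvain partition of the k-NN graph."""
    if graph.n_nodes == 0 or len(graph.edges) == 0:
        raise InsufficientPointsError("modularity needs a non-empty graph")
    g = graph.to_igraph()
    part = _louvain_partition(g, seed)
    q = float(g.modularity(part.membership, weights="weight"))
    if return_partition:
        return q, np.asarray(part.membership)
    return q


# ---------------------------------------------------------------------------
# Moran's I, MNND, dispersion index
# ---------------------------------------------------------------------------

def morans_i(pattern: SpotPattern) -> float:
    """Moran's I with w_ij = 1/d_ij^2 (0 for coincident pairs).

    The statistic is evaluated per coordinate axis on centered values and
    averaged over the axes with non-zero variance; see the methods note for
    why the vector-valued form is resolved this way.
    """
    xy = pattern.spots
    if xy.shape[0] < 2:
        raise InsufficientPointsError("Moran's I needs at least 2 spots")
    d2 = squareform(pdist(xy, "sqeuclidean"))
    return _morans_i_xy(xy, d2)


def _morans_i_xy(xy: np.ndarray, d2: np.ndarray) -> float:
    n = xy.shape[0]
    with np.errstate(divide="ignore"):
        w = np.where(d2 > 0, 1.0 / d2, 0.0)
    np.fill_diagonal(w, 0.0)
    w_sum = w.sum()
    if w_sum == 0:
        raise InvalidParameterError("all spots coincident: Moran's I undefined")
    z = xy - xy.mean(axis=0)
    vals = []
    for ax in range(2):
        denom = (z[:, ax] ** 2).sum()
        if denom > 1e-30:
            vals.append(n * (z[:, ax] @ w @ z[:, ax]) / (w_sum * denom))
    if not vals:
        raise InvalidParameterError("zero coordinate variance on both axes")
    return float(np.mean(vals))


def mnnd(pattern: SpotPattern) -> float:
    """Mean nearest-neighbour distance in px."""
    if pattern.n_spots < 2:
        raise InsufficientPointsError("MNND needs at least 2 spots")
    dmat = squareform(pdist(pattern.spots))
    np.fill_diagonal(dmat, np.inf)
    return float(dmat.min(axis=1).mean())


def dispersion_index(pattern: SpotPattern) -> float:
    """Population variance of the pairwise distances over their mean (px)."""
    if pattern.n_spots < 3:
        raise InsufficientPointsError("dispersion index needs at least 3 spots")
    d = pdist(pattern.spots)
    mu = d.mean()
    if mu == 0:
        raise InvalidParameterError("all spots coincident: dispersion undefined")
    return float(d.var(ddof=0) / mu)


# ---------------------------------------------------------------------------
# Batch entry point
# ---------------------------------------------------------------------------

def compute_all_metrics(
    pattern: SpotPattern, settings: MetricSettings = MetricSettings()
) -> MetricVector:
    """All six metrics on one pattern; per-metric failures become None."""
    out = MetricVector()
    grid = settings.grid_for(pattern)
    try:
        out.ripley_clustering_pct = ripley_clustering_percentage(pattern, grid)
    except _METRIC_ERRORS:
        pass
    try:
        graph = build_knn_graph(pattern, settings.k)
    except _METRIC_ERRORS:
        graph = None
    if graph is not None:
        try:
            out.assortativity = assortativity(graph)
        except _METRIC_ERRORS:
            pass
        try:
            out.modularity = modularity_louvain(graph, settings.louvain_seed)
        except _METRIC_ERRORS:
            pass
    try:
        out.morans_i = morans_i(pattern)
    except _METRIC_ERRORS:
        pass
    try:
        out.mnnd = mnnd(pattern)
    except _METRIC_ERRORS:
        pass
    try:
        out.dispersion_index = dispersion_index(pattern)
    except _METRIC_ERRORS:
        pass
    return out

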