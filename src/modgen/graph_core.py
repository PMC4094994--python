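"""Core domain types and closed-form metrics for modular random graphs.

The central quantity is Newman modularity of a partition {C_k}:

    Q = sum_k ( e_kk - a_k^2 )

where ``e_kk = |E(C_k)| / |E(G)|`` is the fraction of edges with both
endpoints inside module ``C_k`` and ``a_k = sum_{v in C_k} d(v) / (2|E(G)|)``
is the fraction of edge endpoints attached to ``C_k``.  ``Q = 0`` means the
within-module edge density equals the expectation of a random graph with the
same degree sequence; ``Q_max = 1 - 1/K`` is approached when all edges fall
within modules.

A target modularity translates into a mean within-module degree through

    E[Q] = sum_k [ dw_bar * s_k / M - (d_bar * s_k / M)^2 ],   M = n * d_bar

(with M the *total degree sum*, i.e. 2|E|), which for equal module sizes
reduces to ``E[Q] = dw_bar / d_bar - 1/K``.  :func:`expected_modularity` and
:func:`solve_mean_within_degree` evaluate and invert this relation.

Standard structural metrics (degree assortativity r, clustering coefficient
C, average path length L) and partition-comparison measures (pair-counting
Jaccard similarity J, variation of information VI) round out the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import FeasibilityError, InputError

__all__ = [
    "SimpleGraph",
    "Partition",
    "DegreeTriples",
    "GraphSpec",
    "BlockDensities",
    "MetricsReport",
    "modularity",
    "expected_modularity",
    "solve_mean_within_degree",
    "q_max",
    "block_densities",
    "degree_assortativity",
    "clustering_coefficient",
    "average_path_length",
    "partition_jaccard",
    "variation_of_information",
    "metrics_report",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _canonical_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class SimpleGraph:
    """An undirected simple graph on nodes ``{0, ..., n_nodes - 1}``.

    Edges are stored as a frozenset of canonical ``(min, max)`` pairs; self
    loops and multi-edges are rejected at construction.
    """

    n_nodes: int
    edges: frozenset

    def __post_init__(self):
        if self.n_nodes < 0:
            raise InputError("n_nodes must be non-negative")
        for (i, j) in self.edges:
            if i == j:
                raise InputError(f"self loop ({i}, {j}) is not allowed")
            if not (0 <= i < j < self.n_nodes):
                raise InputError(
                    f"edge ({i}, {j}) is not a canonical pair of node indices "
                    f"in [0, {self.n_nodes})"
                )

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "SimpleGraph":
        """Build a graph, canonicalizing edge orientation (duplicates collapse)."""
        return cls(n_nodes, frozenset(_canonical_edge(int(i), int(j)) for i, j in edges))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "SimpleGraph":
        """Convert from networkx; nodes must already be labelled 0..n-1."""
        n = g.number_of_nodes()
        if set(g.nodes) != set(range(n)):
            raise InputError("networkx graph nodes must be integers 0..n-1")
        return cls.from_edges(n, g.edges())

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        return nx.is_connected(self.to_networkx())


@dataclass(eq=False)
class Partition:
    """A node -> module assignment with 1-based contiguous module labels."""

    assignment: np.ndarray  # shape (n,), values in 1..K

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=np.int64)
        object.__setattr__(self, "assignment", a)
        if a.ndim != 1:
            raise InputError("assignment must be one label per node")
        if a.size and (a.min() < 1 or len(np.setdiff1d(np.arange(1, a.max() + 1), a))):
            raise InputError("module labels must be contiguous integers 1..K")

    @classmethod
    def from_sizes(cls, sizes: Sequence[int]) -> "Partition":
        """Nodes assigned to modules in contiguous index blocks of the given sizes."""
        sizes = [int(s) for s in sizes]
        if any(s <= 0 for s in sizes):
            raise InputError("module sizes must be positive")
        return cls(np.repeat(np.arange(1, len(sizes) + 1), sizes))

    @classmethod
    def single(cls, n: int) -> "Partition":
        return cls(np.ones(n, dtype=np.int64))

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) if self.assignment.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_modules + 1)[1:]

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def __eq__(self, other):
        return isinstance(other, Partition) and np.array_equal(
            self.assignment, other.assignment
        )


@dataclass(eq=False)
class DegreeTriples:
    """Per-node total, within- and between-degree with d = d_w + d_b."""

    d: np.ndarray
    d_w: np.ndarray
    d_b: np.ndarray

    def __post_init__(self):
        for name in ("d", "d_w", "d_b"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if not (self.d.shape == self.d_w.shape == self.d_b.shape):
            raise InputError("degree triple arrays must have identical length")
        if (self.d < 0).any() or (self.d_w < 0).any() or (self.d_b < 0).any():
            raise InputError("degrees must be non-negative")
        if not np.array_equal(self.d, self.d_w + self.d_b):
            raise InputError("d = d_w + d_b must hold for every node")

    @classmethod
    def from_within(cls, d, d_w) -> "DegreeTriples":
        d = np.asarray(d, dtype=np.int64)
        d_w = np.asarray(d_w, dtype=np.int64)
        return cls(d, d_w, d - d_w)

    @property
    def n_nodes(self) -> int:
        return self.d.size

    def validate_parity(self, partition: Partition) -> None:
        """Assert the handshake parities: global d, per-module d_w, global d_b."""
        if self.d.sum() % 2:
            raise InputError("total degree sum must be even")
        for k in range(1, partition.n_modules + 1):
            if self.d_w[partition.members(k)].sum() % 2:
                raise InputError(f"within-degree sum of module {k} must be even")
        if self.d_b.sum() % 2:
            raise InputError("between-degree sum must be even")


@dataclass(frozen=True)
class BlockDensities:
    """Within- and cross-module link probabilities of the equivalent planted
    two-density (Girvan–Newman style) model."""

    p_in: float
    p_out: float


@dataclass
class GraphSpec:
    """The full recipe for one modular random graph.

    Parameters
    ----------
    n:
        Number of nodes.
    degree_spec:
        A :class:`~modgen.degree_sampling.DegreeDistribution` or an explicit
        integer degree sequence of length ``n``.
    target_q:
        Desired modularity of the planted partition, in
        ``(-sum_k (s_k/n)^2, 1 - sum_k (s_k/n)^2)``.
    n_modules:
        Number of modules K.
    module_size_spec:
        ``"equal"``, an explicit list of K sizes summing to n, or a
        distribution object to sample sizes from.
    within_degree_spec:
        Optional override for the within-degree distribution; defaults to the
        same family as ``degree_spec`` with mean solved from the target Q.
        May be an explicit within-degree sequence.
    epsilon:
        Tolerance on |achieved Q - target Q|; default 0.01.
    epsilon_dw:
        Tolerance on the realized mean within-degree; default
        ``epsilon * mean_degree``.
    degree_mean_tol:
        Tolerance on the realized mean of the sampled degree sequence;
        default ``0.05 * mean_degree``.
    swaps_per_edge:
        Accepted double-edge swaps per edge during randomization.
    connect_each_module:
        If true, rewire each module's within-edges until the module itself is
        connected (only the full graph is required to be connected otherwise).
    max_attempts:
        Budget for each rejection-sampling / retry loop.
    seed:
        Root seed; every stochastic step derives its randomness from it.
    """

    n: int
    degree_spec: object
    target_q: float
    n_modules: int = 1
    module_size_spec: object = "equal"
    within_degree_spec: object | None = None
    epsilon: float = 0.01
    epsilon_dw: float | None = None
    degree_mean_tol: float | None = None
    swaps_per_edge: int = 10
    connect_each_module: bool = False
    max_attempts: int = 1000
    seed: int | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise InputError("n must be at least 1")
        if not (1 <= self.n_modules <= self.n):
            raise InputError("need 1 <= K <= n")
        if self.epsilon <= 0:
            raise InputError("epsilon must be positive")
        if self.n_modules == 1:
            if abs(self.target_q) > 1e-12:
                raise FeasibilityError(
                    "a single-module graph has modularity 0 exactly; "
                    "target_q must be 0 when K = 1"
                )
            return
        qm = q_max(self.n_modules)
        if self.target_q >= qm:
            raise FeasibilityError(
                f"target Q={self.target_q} is not achievable with K={self.n_modules} "
                f"modules: Q_max = 1 - 1/K = {qm:.6g}"
            )

    @property
    def K(self) -> int:  # noqa: N802 - field-standard symbol
        return self.n_modules


@dataclass
class MetricsReport:
    """Structural metrics of one graph/partition (and optionally a partition pair)."""

    q: float
    r: float
    c: float
    l: float
    j: float | None = None
    vi: float | None = None


# ---------------------------------------------------------------------------
# modularity and its inversion
# ---------------------------------------------------------------------------


def modularity(graph: SimpleGraph, partition: Partition) -> float:
    """Newman modularity Q = sum_k (e_kk - a_k^2) of ``partition`` on ``graph``."""
    if partition.n_nodes != graph.n_nodes:
        raise InputError(
            f"partition covers {partition.n_nodes} nodes but graph has {graph.n_nodes}"
        )
    m = graph.n_edges
    if m == 0:
        raise InputError("modularity is undefined for a graph with no edges")
    K = partition.n_modules
    labels = partition.assignment
    within = np.zeros(K + 1, dtype=np.int64)  # edges with both endpoints in module k
    stubs = np.zeros(K + 1, dtype=np.int64)  # degree sum of module k
    for i, j in graph.edges:
        ki, kj = labels[i], labels[j]
        stubs[ki] += 1
        stubs[kj] += 1
        if ki == kj:
            within[ki] += 1
    e_kk = within[1:] / m
    a_k = stubs[1:] / (2 * m)
    return float(np.sum(e_kk - a_k**2))


def expected_modularity(
    d_w_mean: float, sizes: Sequence[int], d_mean: float, n: int
) -> float:
    """Expected modularity of the planted partition.

    ``E[Q] = sum_k [ dw_bar * s_k / M - (d_bar * s_k / M)^2 ]`` with
    ``M = n * d_bar`` the total degree sum.  For equal module sizes this
    reduces to ``dw_bar / d_bar - 1/K``.
    """
    sizes = np.asarray(sizes, dtype=float)
    if not math.isclose(sizes.sum(), n):
        raise InputError("module sizes must sum to n")
    if d_w_mean > d_mean + 1e-12:
        raise InputError("mean within-degree cannot exceed the mean degree")
    M = n * d_mean
    return float(np.sum(d_w_mean * sizes / M - (d_mean * sizes / M) ** 2))


def _size_share_sq(sizes: Sequence[int], n: int) -> float:
    sizes = np.asarray(sizes, dtype=float)
    return float(np.sum((sizes / n) ** 2))


def solve_mean_within_degree(
    target_q: float, d_mean: float, sizes: Sequence[int]
) -> float:
    """Invert the expected-modularity relation for the mean within-degree.

    Returns ``dw_bar = d_bar * (Q + sum_k (s_k/n)^2)``; the admissible target
    range is ``-sum_k (s_k/n)^2 <= Q < 1 - sum_k (s_k/n)^2`` (the lower end
    gives dw_bar = 0, i.e. a fully disassortative community structure).
    """
    n = int(np.sum(sizes))
    share = _size_share_sq(sizes, n)
    lo, hi = -share, 1.0 - share
    if not (lo - 1e-12 <= target_q < hi - 1e-12):
        raise FeasibilityError(
            f"target Q={target_q} is infeasible for these module sizes: "
            f"admissible range is [{lo:.6g}, {hi:.6g})"
        )
    return d_mean * (target_q + share)


def q_max(n_modules: int) -> float:
    """Supremum of modularity for K modules: ``Q_max = 1 - 1/K``.

    Evaluated as (K-1)/K, which is exact in floating point where the
    literal subtraction is not (e.g. K=3 gives exactly 2/3).
    """
    if n_modules < 1:
        raise InputError("K must be at least 1")
    return (n_modules - 1) / n_modules


def block_densities(
    d_mean: float, d_w_mean: float, s_mean: float, n_modules: int
) -> BlockDensities:
    """Linking and cross-linking probabilities of the equivalent planted model.

    ``p_in = dw_bar / (s_bar - 1)`` and
    ``p_out = (d_bar - dw_bar) / (s_bar * (K - 1))``.
    """
    if s_mean <= 1:
        raise InputError("mean module size must exceed 1")
    if n_modules <= 1:
        raise InputError("block densities require K > 1")
    return BlockDensities(
        p_in=d_w_mean / (s_mean - 1.0),
        p_out=(d_mean - d_w_mean) / (s_mean * (n_modules - 1.0)),
    )


# ---------------------------------------------------------------------------
# structural metrics
# ---------------------------------------------------------------------------


def degree_assortativity(graph: SimpleGraph) -> float:
    """Pearson correlation of the degrees at the two ends of each edge.

    Each edge is counted in both orientations.  Undefined (NaN, with a
    warning) when the endpoint degrees have zero variance, e.g. on a
    k-regular graph.
    """
    if graph.n_edges < 2:
        warnings.warn("assortativity undefined with fewer than 2 edges")
        return float("nan")
    deg = graph.degrees()
    ij = np.array(sorted(graph.edges), dtype=np.int64)
    x = np.concatenate([deg[ij[:, 0]], deg[ij[:, 1]]]).astype(float)
    y = np.concatenate([deg[ij[:, 1]], deg[ij[:, 0]]]).astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("assortativity undefined: zero degree variance at edge endpoints")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def clustering_coefficient(graph: SimpleGraph, method: str = "mean-local") -> float:
    """Clustering coefficient of the graph.

    ``mean-local`` (default) is the mean over nodes of the local clustering
    coefficient, with nodes of degree < 2 contributing 0; ``transitivity``
    is the global triangle density 3*triangles / connected triples.
    """
    g = graph.to_networkx()
    if method == "mean-local":
        return float(nx.average_clustering(g)) if graph.n_nodes else 0.0
    if method == "transitivity":
        return float(nx.transitivity(g))
    raise InputError(f"unknown clustering method {method!r}")


def average_path_length(graph: SimpleGraph) -> float:
    """Mean shortest-path length over unordered node pairs.

    On a disconnected graph the mean is taken over the largest connected
    component, with a warning (the convention used for empirical networks
    that contain disconnected components).
    """
    g = graph.to_networkx()
    if graph.n_nodes < 2:
        raise InputError("average path length needs at least 2 nodes")
    if not nx.is_connected(g):
        warnings.warn(
            "graph is disconnected; average path length computed on the "
            "largest connected component"
        )
        g = g.subgraph(max(nx.connected_components(g), key=len))
    return float(nx.average_shortest_path_length(g))


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------


def _contingency(p1: Partition, p2: Partition) -> np.ndarray:
    if p1.n_nodes != p2.n_nodes:
        raise InputError("partitions must cover the same node set")
    k1, k2 = p1.n_modules, p2.n_modules
    table = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(table, (p1.assignment - 1, p2.assignment - 1), 1)
    return table


def partition_jaccard(p1: Partition, p2: Partition) -> float:
    """Pair-counting Jaccard similarity of two partitions of the same nodes.

    J = n11 / (n11 + n10 + n01) over unordered node pairs, where n11 counts
    pairs co-clustered in both partitions and n10/n01 pairs co-clustered in
    exactly one.  If no pair is co-clustered in either partition (both
    all-singletons) the measure is undefined and 1.0 is returned with a
    warning.
    """
    table = _contingency(p1, p2)

    def _pairs(counts):
        counts = counts.astype(np.int64)
        return int(np.sum(counts * (counts - 1) // 2))

    n11 = _pairs(table.ravel())
    co1 = _pairs(table.sum(axis=1))
    co2 = _pairs(table.sum(axis=0))
    denom = co1 + co2 - n11
    if denom == 0:
        warnings.warn(
            "Jaccard similarity undefined (no co-clustered pair in either "
            "partition); returning 1.0 by convention"
        )
        return 1.0
    return n11 / denom


def variation_of_information(
    p1: Partition, p2: Partition, base: float | None = None
) -> float:
    """Variation of information VI = H(p1) + H(p2) - 2 I(p1; p2).

    Computed from the K1 x K2 confusion matrix of co-membership counts
    divided by n; natural logarithm by default (``base`` overrides).
    """
    table = _contingency(p1, p2)
    n = table.sum()
    if n == 0:
        raise InputError("partitions must be non-empty")
    p = table / n
    p1m = p.sum(axis=1)
    p2m = p.sum(axis=0)

    def _h(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    h1, h2 = _h(p1m), _h(p2m)
    nz = p > 0
    mi = float(np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(p1m, p2m)[nz]))))
    vi = h1 + h2 - 2.0 * mi
    if base is not None:
        vi /= math.log(base)
    return max(vi, 0.0)  # clip tiny negative rounding


def metrics_report(
    graph: SimpleGraph,
    partition: Partition,
    other_partition: Partition | None = None,
    clustering: str = "mean-local",
) -> MetricsReport:
    """Compute Q, r, C, L for a graph/partition (and J, VI against a second partition)."""
    rep = MetricsReport(
        q=modularity(graph, partition),
        r=degree_assortativity(graph),
        c=clustering_coefficient(graph, method=clustering),
        l=average_path_length(graph),
    )
    if other_partition is not None:
        rep.j = partition_jaccard(partition, other_partition)
        rep.vi = variation_of_information(partition, other_partition)
    return rep
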