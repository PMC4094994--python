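"""Edge realization: constrained Havel–Hakimi wiring, double-edge-swap
randomization, and degree-preserving connectivity repair.

Between-edges are wired with a modified Havel–Hakimi scheme: nodes are
prioritized by their module's total residual between-degree, then by their
own residual between-degree, and the top node is connected to uniformly
random eligible partners (different module, not already adjacent, not both
within-degree zero).  Within-edges use the standard Havel–Hakimi algorithm
independently per module (skipping partners when both endpoints have
between-degree zero, unless the module has no between-edges at all).  Both
edge classes are then randomized by degree-preserving double-edge swaps that
respect the class constraints, and the full graph is finally made connected
by same-class cross-component swaps.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .errors import GenerationError, InputError, WiringError
from .graph_core import DegreeTriples, Partition, _canonical_edge

__all__ = [
    "connect_between_edges",
    "connect_within_edges",
    "double_edge_swap",
    "connect_module_taylor",
    "ensure_global_connectivity",
]


# ---------------------------------------------------------------------------
# between-edge wiring (modified Havel-Hakimi)
# ---------------------------------------------------------------------------


def _between_repair(top, edges, adj, residual, labels, d_w, rng) -> bool:
    """Stall repair: relocate an existing between-edge so ``top`` can place a
    stub.  Degrees of all other nodes are preserved exactly.

    With residual >= 2: replace (x, y) by (top, x) and (top, y).
    With residual == 1: replace (x, y) by (top, x); y's stub is re-opened.
    """

    def _ok(node):
        return (
            node != top
            and node not in adj[top]
            and labels[node] != labels[top]
            and not (d_w[top] == 0 and d_w[node] == 0)
        )

    pool = sorted(edges)
    order = rng.permutation(len(pool))
    need_two = residual[top] >= 2
    for idx in order[: min(len(pool), 500)]:
        x, y = pool[idx]
        if need_two:
            if _ok(x) and _ok(y):
                edges.discard((x, y))
                adj[x].discard(y)
                adj[y].discard(x)
                for node in (x, y):
                    edges.add(_canonical_edge(top, node))
                    adj[top].add(node)
                    adj[node].add(top)
                residual[top] -= 2
                return True
        else:
            if rng.random() < 0.5:
                x, y = y, x
            if _ok(x):
                edges.discard(_canonical_edge(x, y))
                adj[x].discard(y)
                adj[y].discard(x)
                edges.add(_canonical_edge(top, x))
                adj[top].add(x)
                adj[x].add(top)
                residual[top] -= 1
                residual[y] += 1
                return True
    return False


def _between_once(triples: DegreeTriples, partition: Partition, rng) -> set:
    n = triples.n_nodes
    labels = partition.assignment
    K = partition.n_modules
    residual = triples.d_b.copy()
    d_w = triples.d_w
    edges: set = set()
    adj = [set() for _ in range(n)]
    max_repairs = 2 * int(residual.sum()) + 10
    repairs = 0
    while True:
        total = int(residual.sum())
        if total == 0:
            return edges
        mod_tot = np.bincount(labels, weights=residual, minlength=K + 1)
        active = np.flatnonzero(residual > 0)
        # top node: highest module residual total, then highest own residual
        key = mod_tot[labels[active]] * (residual.max() + 1) + residual[active]
        top_candidates = active[key == key.max()]
        top = int(rng.choice(top_candidates))
        while residual[top] > 0:
            mask = (residual > 0) & (labels != labels[top])
            if adj[top]:
                mask[list(adj[top])] = False
            mask[top] = False
            if d_w[top] == 0 and (mask & (d_w > 0)).any():
                # avoid pairing two within-degree-zero nodes, unless they are
                # the only partners left (connectivity is re-checked later)
                mask &= d_w > 0
            eligible = np.flatnonzero(mask)
            if eligible.size == 0:
                repairs += 1
                if repairs > max_repairs or not _between_repair(
                    top, edges, adj, residual, labels, d_w, rng
                ):
                    raise WiringError("between-edge wiring stalled")
                continue
            tgt = int(rng.choice(eligible))
            edges.add(_canonical_edge(top, tgt))
            adj[top].add(tgt)
            adj[tgt].add(top)
            residual[top] -= 1
            residual[tgt] -= 1


def connect_between_edges(
    triples: DegreeTriples,
    partition: Partition,
    rng: np.random.Generator,
    max_restarts: int = 50,
) -> set:
    """Wire every node's between-degree as inter-module edges.

    Restarts with fresh randomness on a stall; raises
    :class:`~modgen.errors.WiringError` when the restart budget is exhausted.
    """
    for _ in range(max_restarts):
        try:
            return _between_once(triples, partition, rng)
        except WiringError:
            continue
    raise WiringError(
        f"between-edge wiring stalled in all {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# within-edge wiring (standard Havel-Hakimi per module)
# ---------------------------------------------------------------------------


def _within_module_once(
    members: np.ndarray,
    d_w: np.ndarray,
    d_b: np.ndarray,
    rng,
    enforce_rule: bool,
) -> set:
    residual = {int(v): int(d_w[v]) for v in members}
    edges: set = set()
    adj = {int(v): set() for v in members}
    while True:
        pending = [v for v, r in residual.items() if r > 0]
        if not pending:
            return edges
        rng.shuffle(pending)  # randomize tie order between restarts
        pending.sort(key=lambda v: -residual[v])
        top = pending[0]
        need = residual[top]
        partners = [
            v
            for v in pending[1:]
            if v not in adj[top]
            and not (enforce_rule and d_b[top] == 0 and d_b[v] == 0)
        ]
        if len(partners) < need:
            raise WiringError("within-edge wiring stalled")
        for tgt in partners[:need]:
            edges.add(_canonical_edge(top, tgt))
            adj[top].add(tgt)
            adj[tgt].add(top)
            residual[tgt] -= 1
        residual[top] = 0


def connect_within_edges(
    triples: DegreeTriples,
    partition: Partition,
    rng: np.random.Generator,
    max_restarts: int = 50,
) -> set:
    """Wire every node's within-degree inside its own module.

    Standard Havel–Hakimi per module: the highest-residual node is connected
    to the next-highest residual nodes.  Partners where both endpoints have
    between-degree zero are avoided (to discourage disconnected components)
    except in modules that have no between-edges at all; after repeated
    stalls the rule is dropped for that module, since global connectivity is
    verified and repaired afterwards.
    """
    edges: set = set()
    for k in range(1, partition.n_modules + 1):
        members = partition.members(k)
        has_between = bool((triples.d_b[members] > 0).any())
        module_edges = None
        for restart in range(max_restarts):
            enforce = has_between and restart < max_restarts // 2
            try:
                module_edges = _within_module_once(
                    members, triples.d_w, triples.d_b, rng, enforce
                )
                break
            except WiringError:
                continue
        if module_edges is None:
            raise WiringError(
                f"within-edge wiring of module {k} stalled in all "
                f"{max_restarts} restarts"
            )
        edges |= module_edges
    return edges


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------


def double_edge_swap(
    edges: set,
    partition: Partition,
    n_swaps: int,
    rng: np.random.Generator,
    scope: str = "between",
) -> set:
    """Randomize one edge class by degree-preserving double-edge swaps.

    Two random edges (u,v), (x,y) are replaced by (u,x), (v,y); attempts
    that would create a self loop, a multi-edge, or (for ``scope="between"``)
    an intra-module edge are rejected and retried.  Performs ``n_swaps``
    accepted swaps or gives up with a warning after ``100 * n_swaps``
    attempts.  Node degrees and the within/between class of every edge are
    invariant.
    """
    if scope not in ("between", "within"):
        raise InputError(f"unknown swap scope {scope!r}")
    edge_list = sorted(edges)
    if len(edge_list) < 2 or n_swaps <= 0:
        return set(edge_list)
    edge_set = set(edge_list)
    labels = partition.assignment
    accepted = 0
    budget = 100 * n_swaps
    attempts = 0
    while accepted < n_swaps and attempts < budget:
        attempts += 1
        i, j = rng.integers(0, len(edge_list), size=2)
        if i == j:
            continue
        u, v = edge_list[i]
        x, y = edge_list[j]
        if rng.random() < 0.5:
            x, y = y, x
        if u == x or v == y:
            continue
        e1, e2 = _canonical_edge(u, x), _canonical_edge(v, y)
        if e1 in edge_set or e2 in edge_set:
            continue
        if scope == "between" and (labels[u] == labels[x] or labels[v] == labels[y]):
            continue
        edge_set.discard(edge_list[i])
        edge_set.discard(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i], edge_list[j] = e1, e2
        accepted += 1
    if accepted < n_swaps:
        warnings.warn(
            f"double-edge swap accepted only {accepted}/{n_swaps} swaps within "
            f"the attempt budget; returning the current state"
        )
    return edge_set


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------


def connect_module_taylor(
    edges: set,
    members,
    rng: np.random.Generator,
    max_iters: int = 10000,
) -> set:
    """Rewire a module's within-edges until the module is connected.

    Cross-component pair rewiring: pick edges (u,v) and (x,y) in two
    different components and replace them with (u,x) and (v,y) (always
    simple, as the components are disjoint).  The within-degree sequence is
    unchanged.  A connected realization must exist:
    ``sum(d_w)/2 >= s_k - 1`` and no member may be isolated.
    """
    members = [int(v) for v in members]
    if len(members) <= 1:
        return set(edges)
    deg = {v: 0 for v in members}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    if len(edges) < len(members) - 1 or any(d == 0 for d in deg.values()):
        raise InputError(
            "no connected realization: a module needs at least s_k - 1 "
            "within-edges and no isolated member"
        )
    edges = set(edges)
    for _ in range(max_iters):
        g = nx.Graph()
        g.add_nodes_from(members)
        g.add_edges_from(edges)
        comps = list(nx.connected_components(g))
        if len(comps) == 1:
            return edges
        in_a = comps[0]
        a_edges = sorted(e for e in edges if e[0] in in_a)
        b_edges = sorted(e for e in edges if e[0] not in in_a)
        u, v = a_edges[int(rng.integers(len(a_edges)))]
        x, y = b_edges[int(rng.integers(len(b_edges)))]
        edges.discard((u, v))
        edges.discard((x, y))
        edges.add(_canonical_edge(u, x))
        edges.add(_canonical_edge(v, y))
    raise WiringError("module connectivity rewiring did not converge")


def _edge_class(edge, labels) -> tuple:
    u, v = edge
    return ("within", int(labels[u])) if labels[u] == labels[v] else ("between",)


def ensure_global_connectivity(
    edges: set,
    partition: Partition,
    triples: DegreeTriples,
    rng: np.random.Generator,
    max_iters: int = 2000,
) -> set:
    """Make the full graph connected by same-class cross-component swaps.

    Repeatedly picks one edge in the largest component and one in another
    component, of the same class (and, for within-edges, the same module),
    and swaps endpoints.  Degrees and per-node within/between counts are
    unchanged.  Raises :class:`~modgen.errors.GenerationError` (a signal to
    regenerate) when no valid repair swap can be found.
    """
    labels = partition.assignment
    n = triples.n_nodes
    edges = set(edges)
    for _ in range(max_iters):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        if len(comps) == 1:
            return edges
        main = comps[0]
        other = set().union(*comps[1:])
        main_edges = sorted(e for e in edges if e[0] in main)
        other_edges = sorted(e for e in edges if e[0] in other)
        swapped = False
        for _try in range(200):
            u, v = main_edges[int(rng.integers(len(main_edges)))]
            x, y = other_edges[int(rng.integers(len(other_edges)))]
            if rng.random() < 0.5:
                x, y = y, x
            c1 = _edge_class((u, v), labels)
            if c1 != _edge_class((x, y), labels):
                continue
            if c1[0] == "between" and (labels[u] == labels[x] or labels[v] == labels[y]):
                continue
            if c1[0] == "within" and labels[u] != labels[x]:
                continue
            edges.discard(_canonical_edge(u, v))
            edges.discard(_canonical_edge(x, y))
            edges.add(_canonical_edge(u, x))
            edges.add(_canonical_edge(v, y))
            swapped = True
            break
        if not swapped:
            raise GenerationError(
                "connectivity repair found no valid same-class cross-component "
                "swap; the graph should be regenerated",
                stage="connectivity",
            )
    raise GenerationError(
        "connectivity repair budget exhausted", stage="connectivity"
    )
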