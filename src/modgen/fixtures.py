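"""Deterministic small test objects with analytically known properties."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degree_sampling import DegreeDistribution
from .graph_core import GraphSpec, Partition, SimpleGraph

__all__ = ["Fixtures", "make_fixtures", "disjoint_cliques", "bridged_triangles"]


def disjoint_cliques(n_cliques: int, size: int) -> tuple[SimpleGraph, Partition]:
    """K disjoint cliques of the given size; modularity of the planted
    partition is exactly 1 - 1/K."""
    edges = []
    for k in range(n_cliques):
        base = k * size
        for i in range(size):
            for j in range(i + 1, size):
                edges.append((base + i, base + j))
    return (
        SimpleGraph.from_edges(n_cliques * size, edges),
        Partition.from_sizes([size] * n_cliques),
    )


def bridged_triangles() -> tuple[SimpleGraph, Partition]:
    """Two triangles joined by one bridge edge (7 edges on 6 nodes).

    With the triangles as modules: e_kk = 3/7 each, a_k = 1/2 each, so
    Q = 6/7 - 2 (1/2)^2 = 5/14.
    """
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    return SimpleGraph.from_edges(6, edges), Partition.from_sizes([3, 3])


@dataclass
class Fixtures:
    """A bundle of deterministic fixtures for testing."""

    cliques: tuple  # (graph, partition) with Q = 3/4 (K=4 cliques of 5)
    bridged: tuple  # (graph, partition) with Q = 5/14
    non_graphical_sequence: tuple  # fails the Erdős–Gallai criterion
    two_component_graph: SimpleGraph  # disconnected, for repair tests
    two_component_partition: Partition
    tiny_specs: dict  # one small GraphSpec per degree family


def make_fixtures(seed: int = 0) -> Fixtures:
    """Build the standard fixture set (deterministic for a given seed)."""
    # two components, each with within- and between-edges under the partition
    # modules {0..3} and {4..7}: component A = nodes 0,1,4,5; B = 2,3,6,7
    two_comp_edges = [
        (0, 1), (4, 5), (0, 4), (1, 5),  # component A
        (2, 3), (6, 7), (2, 6), (3, 7),  # component B
    ]
    tiny_specs = {
        family: GraphSpec(
            n=60,
            degree_spec=DegreeDistribution(family, mean=6.0),
            target_q=0.3,
            n_modules=3,
            seed=seed,
        )
        for family in ("poisson", "geometric", "powerlaw")
    }
    return Fixtures(
        cliques=disjoint_cliques(4, 5),
        bridged=bridged_triangles(),
        non_graphical_sequence=(3, 3, 1, 1),
        two_component_graph=SimpleGraph.from_edges(8, two_comp_edges),
        two_component_partition=Partition(np.array([1, 1, 1, 1, 2, 2, 2, 2])),
        tiny_specs=tiny_specs,
    )
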