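"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit enumeration, double loops)
and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_modularity(n, edges, membership) -> float:
    """Q by explicit double loop over edges and degree sums."""
    m = len(edges)
    labels = sorted(set(membership))
    deg = [0] * n
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    q = 0.0
    for lab in labels:
        within = sum(1 for i, j in edges if membership[i] == lab and membership[j] == lab)
        stubs = sum(deg[v] for v in range(n) if membership[v] == lab)
        q += within / m - (stubs / (2 * m)) ** 2
    return q


def brute_graphical(seq) -> bool:
    """Existence of a simple graph realizing ``seq``, by exhaustive
    enumeration over all edge subsets (use only for len(seq) <= 5)."""
    seq = list(seq)
    n = len(seq)
    if any(d < 0 for d in seq):
        return False
    if sum(seq) == 0:
        return True
    pairs = list(combinations(range(n), 2))
    for mask in range(1 << len(pairs)):
        deg = [0] * n
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                deg[i] += 1
                deg[j] += 1
        if deg == seq:
            return True
    return False


def brute_multigraph_realizable(seq, b) -> bool:
    """Existence of a loopless multigraph with degrees ``seq`` and edge
    multiplicities at most ``b``, by branch-and-prune over pair
    multiplicities (use for len(seq) <= 5, entries <= 6, b <= 3)."""
    seq = list(seq)
    n = len(seq)
    if any(d < 0 for d in seq):
        return False
    pairs = list(combinations(range(n), 2))

    def rec(idx, residual):
        if all(r == 0 for r in residual):
            return True
        if idx == len(pairs):
            return False
        i, j = pairs[idx]
        # prune: remaining capacity at i and j
        cap_i = sum(b for k, (x, y) in enumerate(pairs) if k >= idx and i in (x, y))
        if residual[i] > cap_i:
            return False
        hi = min(b, residual[i], residual[j])
        for mult in range(hi + 1):
            residual[i] -= mult
            residual[j] -= mult
            if rec(idx + 1, residual):
                residual[i] += mult
                residual[j] += mult
                return True
            residual[i] += mult
            residual[j] += mult
        return False

    return rec(0, seq)


def brute_pair_counts(assign1, assign2):
    """(n11, n10, n01) over all unordered node pairs."""
    n = len(assign1)
    n11 = n10 = n01 = 0
    for i, j in combinations(range(n), 2):
        a = assign1[i] == assign1[j]
        b = assign2[i] == assign2[j]
        if a and b:
            n11 += 1
        elif a:
            n10 += 1
        elif b:
            n01 += 1
    return n11, n10, n01


def brute_vi(assign1, assign2) -> float:
    """Variation of information from entropies of the label distributions."""
    n = len(assign1)

    def h(labels):
        out = 0.0
        for lab in set(labels):
            p = sum(1 for x in labels if x == lab) / n
            out -= p * np.log(p)
        return out

    joint = [(a, b) for a, b in zip(assign1, assign2)]
    return 2 * h(joint) - h(list(assign1)) - h(list(assign2))


def nonincreasing_sequences(max_len, max_entry, min_len=1):
    """All non-increasing integer sequences with the given bounds."""

    def rec(length, cap):
        if length == 0:
            yield ()
            return
        for first in range(cap, -1, -1):
            for rest in rec(length - 1, first):
                yield (first,) + rest

    for length in range(min_len, max_len + 1):
        yield from rec(length, max_entry)


def random_simple_graph(n, p, rng):
    """Edge list of a G(n, p) draw (independent coin per pair)."""
    return [(i, j) for i, j in combinations(range(n), 2) if rng.random() < p]
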