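"""Sampling of module sizes, degree sequences and within-/between-degrees.

Implements the realizability machinery behind steps 1-2 of the generation
pipeline:

* rejection sampling of degree sequences from Poisson, geometric or
  power-law families, zero-truncated (no node may have degree zero) and
  constrained by the handshake theorem and the Erdős–Gallai graphicality
  criterion;
* rejection sampling of within-degree sequences from the same family with a
  mean solved from the target modularity, subject to sorted dominance by the
  degree sequence (Condition 1), per-module graphicality (Condition 2),
  the module-size bound max[d_w] <= min[s_k], and the Chungphaisan
  realizability criterion for the coarse between-module multigraph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import FeasibilityError, InputError, SamplingError
from .graph_core import DegreeTriples, Partition

__all__ = [
    "DegreeDistribution",
    "CoarseMultigraphSequence",
    "sample_module_sizes",
    "handshake_check",
    "erdos_gallai_check",
    "sample_degree_sequence",
    "sample_within_degree_sequence",
    "chungphaisan_check",
]

_FAMILIES = ("poisson", "geometric", "powerlaw")


@dataclass(frozen=True)
class DegreeDistribution:
    """One of the three supported degree families, parameterized by its mean.

    * ``poisson``: P(k) ~ lam^k e^-lam / k!; zero-truncated when used for
      total degrees (lam is then solved so the truncated mean matches).
    * ``geometric``: P(k) = p (1-p)^(k-1) on k >= 1, mean 1/p.
    * ``powerlaw``: P(k) ~ k^-alpha on k in [k_min, k_max]; alpha is solved
      numerically so the truncated mean matches, unless given explicitly.
      ``k_min`` defaults to 1; raising it thins the degree-1 leaf mass,
      which strongly modular heavy-tailed specifications require (a module
      dominated by leaves cannot carry a large mean within-degree).
    """

    family: str
    mean: float | None = None
    alpha: float | None = None
    k_min: int = 1

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise InputError(f"unknown degree family {self.family!r}")
        if self.mean is None and not (self.family == "powerlaw" and self.alpha):
            raise InputError("a target mean (or alpha for powerlaw) is required")

    # -- parameter resolution ------------------------------------------------

    def _powerlaw_support(self, k_max: int) -> np.ndarray:
        lo = min(self.k_min, k_max)
        return np.arange(lo, k_max + 1, dtype=float)

    def _powerlaw_probs(self, k_max: int, alpha: float) -> np.ndarray:
        k = self._powerlaw_support(k_max)
        w = k**-alpha
        return w / w.sum()

    def _solve_alpha(self, k_max: int) -> float:
        if self.alpha is not None:
            return self.alpha
        k = self._powerlaw_support(k_max)

        def mean_at(alpha):
            w = k**-alpha
            return float((k * w).sum() / w.sum())

        lo, hi = 1.0001, 60.0
        if not (mean_at(hi) <= self.mean <= mean_at(lo)):
            raise FeasibilityError(
                f"power-law mean {self.mean} unreachable on support [1, {k_max}] "
                f"(achievable range [{mean_at(hi):.4g}, {mean_at(lo):.4g}])"
            )
        return float(brentq(lambda a: mean_at(a) - self.mean, lo, hi, xtol=1e-10))

    def _solve_truncated_poisson_lambda(self) -> float:
        # mean of the zero-truncated Poisson: lam / (1 - exp(-lam))
        if self.mean <= 1.0:
            raise FeasibilityError(
                "zero-truncated Poisson cannot have mean <= 1"
            )
        f = lambda lam: lam / (1.0 - math.exp(-lam)) - self.mean
        return float(brentq(f, 1e-9, 2.0 * self.mean + 10.0, xtol=1e-12))

    # -- sampling ------------------------------------------------------------

    def sample(
        self,
        size: int,
        rng: np.random.Generator,
        k_max: int,
        allow_zero: bool = False,
    ) -> np.ndarray:
        """Draw ``size`` degrees on support ``[0 or 1, k_max]``.

        ``allow_zero`` only affects the Poisson family (within-degrees may
        legitimately be zero); geometric and power-law supports start at 1.
        """
        if self.family == "poisson":
            if allow_zero:
                lam = self.mean
            else:
                lam = self._solve_truncated_poisson_lambda()
            out = rng.poisson(lam, size=size)
        elif self.family == "geometric":
            if self.mean < 1.0:
                raise FeasibilityError("geometric family requires mean >= 1")
            out = rng.geometric(1.0 / self.mean, size=size)
        else:  # powerlaw
            alpha = self._solve_alpha(k_max)
            probs = self._powerlaw_probs(k_max, alpha)
            support = self._powerlaw_support(k_max).astype(np.int64)
            out = rng.choice(support, size=size, p=probs)
        lo = 0 if (allow_zero and self.family == "poisson") else 1
        bad = (out < lo) | (out > k_max)
        while bad.any():
            out[bad] = self.sample(int(bad.sum()), rng, k_max, allow_zero=allow_zero)
            bad = (out < lo) | (out > k_max)
        return out.astype(np.int64)

    def with_mean(self, mean: float) -> "DegreeDistribution":
        """Same family, different target mean (alpha re-solved for powerlaw).

        The within-degree support always starts at 1 regardless of ``k_min``
        (a node may have a single within-neighbour even if total degrees
        start higher).
        """
        return DegreeDistribution(self.family, mean=mean, k_min=1)


@dataclass(frozen=True)
class CoarseMultigraphSequence:
    """Degree sequence of the coarse module graph H.

    ``module_degrees[k]`` is the total between-degree of module k's nodes;
    ``b`` caps the edge multiplicity between any pair of modules (the
    maximum between-degree of any single node).
    """

    module_degrees: tuple
    b: int

    def __post_init__(self):
        if self.b < 0:
            raise InputError("multiplicity cap b must be non-negative")
        if any(d < 0 for d in self.module_degrees):
            raise InputError("module between-degree sums must be non-negative")


# ---------------------------------------------------------------------------
# realizability checks
# ---------------------------------------------------------------------------


def handshake_check(seq: Sequence[int]) -> bool:
    """True iff the degree sum is even (the handshake theorem)."""
    return int(np.sum(np.asarray(seq, dtype=np.int64))) % 2 == 0


def erdos_gallai_check(seq: Sequence[int]) -> bool:
    """True iff ``seq`` is graphical as a simple graph (Erdős–Gallai).

    Sorted non-increasingly, the sequence is graphical iff its sum is even
    and for every prefix length j:
    ``sum_{i<=j} d_i <= j(j-1) + sum_{i>j} min(j, d_i)``.
    """
    d = np.sort(np.asarray(seq, dtype=np.int64))[::-1]
    if d.size == 0:
        return True
    if (d < 0).any():
        raise InputError("degrees must be non-negative")
    if d.sum() % 2:
        return False
    if d[0] >= d.size:
        return False
    prefix = np.cumsum(d)
    for j in range(1, d.size + 1):
        tail = np.minimum(d[j:], j).sum()
        if prefix[j - 1] > j * (j - 1) + tail:
            return False
    return True


def chungphaisan_check(seq: CoarseMultigraphSequence) -> bool:
    """True iff ``seq`` is realizable as a loopless multigraph with edge
    multiplicities at most ``b`` (Chungphaisan's criterion).

    Sorted non-increasingly: the sum must be even and for each
    j = 1..K-1, ``sum_{k<=j} d_k - b j(j-1) <= sum_{k>j} min(j b, d_k)``.
    """
    d = np.sort(np.asarray(seq.module_degrees, dtype=np.int64))[::-1]
    b = seq.b
    if d.size == 0 or d.sum() == 0:
        return True
    if d.sum() % 2:
        return False
    if b == 0 or d.size == 1:
        return False  # positive degrees but no edge can be placed
    prefix = np.cumsum(d)
    for j in range(1, d.size):
        tail = np.minimum(d[j:], j * b).sum()
        if prefix[j - 1] - b * j * (j - 1) > tail:
            return False
    return True


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def sample_module_sizes(
    n: int,
    n_modules: int,
    module_size_spec,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Draw K positive module sizes summing to n.

    ``"equal"`` yields floor(n/K) with the remainder spread one node per
    module; an explicit list is validated and returned; a
    :class:`DegreeDistribution` is rejection-sampled until the K draws sum
    to n.
    """
    if n_modules < 1 or n < n_modules:
        raise InputError("need 1 <= K <= n")
    if isinstance(module_size_spec, str):
        if module_size_spec != "equal":
            raise InputError(f"unknown module size spec {module_size_spec!r}")
        base, rem = divmod(n, n_modules)
        sizes = np.full(n_modules, base, dtype=np.int64)
        sizes[:rem] += 1
        return sizes
    if isinstance(module_size_spec, DegreeDistribution):
        for _ in range(max_attempts):
            sizes = module_size_spec.sample(n_modules, rng, k_max=n)
            if sizes.sum() == n and (sizes > 0).all():
                return sizes.astype(np.int64)
        raise SamplingError(
            f"could not sample {n_modules} module sizes summing to {n} in "
            f"{max_attempts} attempts"
        )
    sizes = np.asarray(module_size_spec, dtype=np.int64)
    if sizes.size != n_modules or (sizes <= 0).any() or sizes.sum() != n:
        raise InputError("explicit module sizes must be K positive integers summing to n")
    return sizes


def sample_degree_sequence(
    dist,
    n: int,
    rng: np.random.Generator,
    target_mean: float | None = None,
    tol: float | None = None,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Sample an n-node graphical degree sequence from ``dist``.

    Rejection sampling until the sequence has no zeros, a sample mean within
    ``tol`` of ``target_mean`` (default 0.05 * mean), an even sum, and passes
    the Erdős–Gallai criterion.  An explicit sequence is validated and
    returned unchanged.
    """
    if not isinstance(dist, DegreeDistribution):
        seq = np.asarray(dist, dtype=np.int64)
        if seq.size != n:
            raise InputError(f"explicit degree sequence has length {seq.size}, not {n}")
        if (seq < 1).any():
            raise InputError("explicit degree sequence contains a zero degree")
        if not erdos_gallai_check(seq):
            raise InputError("explicit degree sequence is not graphical")
        return seq
    if target_mean is None:
        target_mean = dist.mean
    if tol is None:
        tol = 0.05 * target_mean
    reasons = {"mean": 0, "handshake": 0, "erdos_gallai": 0}
    for _ in range(max_attempts):
        seq = dist.sample(n, rng, k_max=n - 1)
        if abs(seq.mean() - target_mean) > tol:
            reasons["mean"] += 1
            continue
        if seq.sum() % 2:
            reasons["handshake"] += 1
            continue
        if not erdos_gallai_check(seq):
            reasons["erdos_gallai"] += 1
            continue
        return seq
    worst = max(reasons, key=reasons.get)
    raise SamplingError(
        f"no admissible degree sequence in {max_attempts} attempts "
        f"(most frequent failure: {worst}; counts {reasons})"
    )


def _between_gale_ryser_ok(d_b: np.ndarray, partition: Partition) -> bool:
    """Necessary condition for realizing ``d_b`` as a simple inter-module graph.

    For every module k and prefix length j, the j largest between-degrees
    inside k must not exceed the distinct-partner capacity of the outside,
    ``sum_{u not in k} min(d_b(u), j)``.
    """
    for k in range(1, partition.n_modules + 1):
        inside = partition.assignment == k
        mine = np.sort(d_b[inside])[::-1]
        mine = mine[mine > 0]
        if mine.size == 0:
            continue
        other = d_b[~inside]
        other = other[other > 0]
        prefix = np.cumsum(mine)
        # capacity(j) = sum min(other, j); evaluate for all j at once
        other_sorted = np.sort(other)
        csum = np.concatenate([[0], np.cumsum(other_sorted)])
        for j in range(1, mine.size + 1):
            # elements < j contribute themselves; the rest contribute j
            idx = np.searchsorted(other_sorted, j)
            capacity = csum[idx] + j * (other_sorted.size - idx)
            if prefix[j - 1] > capacity:
                return False
    return True


def _module_eg_repair(
    d_w: np.ndarray,
    members: np.ndarray,
    node_cap: np.ndarray,
    rng: np.random.Generator,
    budget: int = 500,
) -> bool:
    """Make a module's within-degree multiset graphical by redistribution.

    Erdős–Gallai violations are top-heavy, so one stub is moved from the
    largest within-degree to a random member that is still below its own
    capacity ``min(d, s_k - 1)``.  The module sum (hence parity and the
    global mean) is unchanged.  Returns False when the budget runs out or no
    receiver exists.
    """
    for _ in range(budget):
        if erdos_gallai_check(d_w[members]):
            return True
        top = members[int(np.argmax(d_w[members]))]
        receivers = members[
            (d_w[members] < node_cap[members])
            & (d_w[members] < d_w[top] - 1)
            & (members != top)
        ]
        if d_w[top] < 1 or receivers.size == 0:
            return False
        d_w[top] -= 1
        d_w[rng.choice(receivers)] += 1
    return erdos_gallai_check(d_w[members])


def _parity_repair(d_w: np.ndarray, members: np.ndarray, rng: np.random.Generator) -> bool:
    """Make a module's within-degree sum even by decrementing one random
    positive within-degree (d_b grows by one, so d = d_w + d_b is kept)."""
    if d_w[members].sum() % 2 == 0:
        return True
    candidates = members[d_w[members] >= 1]
    if candidates.size == 0:
        return False
    d_w[rng.choice(candidates)] -= 1
    return True


def sample_within_degree_sequence(
    degrees: Sequence[int],
    partition: Partition,
    d_w_mean: float,
    dist,
    epsilon_dw: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> DegreeTriples:
    """Sample per-node within-degrees consistent with ``degrees``.

    The within-degrees are drawn from ``dist`` (same family as the degree
    distribution, mean ``d_w_mean``) and accepted when

    * the sample mean is within ``epsilon_dw`` of ``d_w_mean``;
    * Condition 1 holds: with both sequences sorted non-increasingly,
      ``d_(i) >= d_w(i)`` at every rank (within-degrees are then matched to
      nodes through this sorted pairing, largest with largest);
    * ``max[d_w] <= min[s_k]`` so every module can absorb the largest
      within-degree;
    * Condition 2 holds: each module's within-degree multiset has an even
      sum (repaired by decrementing one random node if needed) and is
      graphical;
    * the between-degrees ``d_b = d - d_w`` form a realizable coarse
      multigraph sequence under the Chungphaisan criterion with
      ``b = max[d_b]``.

    An explicit within-degree multiset may be passed as ``dist``; it is then
    paired to nodes the same way and validated once.  ``dist=None`` selects
    conditional binomial thinning instead of family sampling: each node draws
    ``d_w ~ Binomial(d, dw_bar/d_bar)`` (capped at its module capacity), so
    dominance holds per node by construction.  This is the fallback for
    regimes where no i.i.d. same-family within-sequence can be dominated by
    the degree sequence (heavy-tailed degrees at high target modularity).
    """
    D = np.asarray(degrees, dtype=np.int64)
    n = D.size
    if partition.n_nodes != n:
        raise InputError("partition and degree sequence disagree on n")
    sizes = partition.sizes
    order = np.argsort(-D, kind="stable")  # nodes by descending degree

    thinning = dist is None
    explicit = not thinning and not isinstance(dist, DegreeDistribution)
    if explicit:
        w_pool = np.sort(np.asarray(dist, dtype=np.int64))[::-1]
        if w_pool.size != n:
            raise InputError("explicit within-degree sequence has wrong length")

    if d_w_mean > D.mean() + 1e-9:
        raise FeasibilityError("mean within-degree cannot exceed the realized mean degree")

    # exact single-module shortcut: all edges are within-edges
    if partition.n_modules == 1 and abs(d_w_mean - D.mean()) <= 1e-9 and not explicit:
        return DegreeTriples.from_within(D, D.copy())

    reasons = {
        "mean": 0,
        "condition1": 0,
        "module_size": 0,
        "condition2": 0,
        "coarse": 0,
        "between_feasible": 0,
    }
    # within-degrees live on [0 or 1, min(s_k) - 1]: a node cannot have more
    # within-neighbours than its module has other members.  Sampling from the
    # family truncated to that support (mean re-solved on it) enforces
    # max[d_w] <= min[s_k] by construction.
    w_cap = int(min(n - 1, sizes.min() - 1)) if sizes.min() > 1 else 0
    attempts = max_attempts if not explicit else 1
    if not explicit and w_cap < 1:
        raise FeasibilityError("modules of size 1 cannot carry any within-degree")
    if thinning:
        # conditional thinning: each of a node's d edges is a within-edge
        # independently with probability dw_bar / d_bar, capped at the
        # node's own module capacity.  Dominance (d_w <= d) holds per node by
        # construction; for a Poisson degree distribution the thinned
        # within-degrees are again Poisson.
        p_thin = min(1.0, d_w_mean / float(D.mean()))
        node_cap = np.minimum(D, sizes[partition.assignment - 1] - 1)
        saturated = 0
    for _ in range(attempts):
        if explicit:
            w = w_pool.copy()
        elif thinning:
            d_w = np.minimum(rng.binomial(D, p_thin), node_cap).astype(np.int64)
            realized = d_w.mean()
            if abs(realized - d_w_mean) > epsilon_dw:
                reasons["mean"] += 1
                # capacity caps bias the realized mean downward; adapt p
                if realized > 0:
                    p_thin = min(1.0, p_thin * d_w_mean / realized)
                if p_thin >= 1.0 - 1e-12 and realized < d_w_mean - epsilon_dw:
                    saturated += 1
                    if saturated >= 20:
                        # even w = min(d, cap) cannot reach the target mean:
                        # this degree sequence is infeasible for the target
                        break
                continue
        else:
            w = np.sort(dist.sample(n, rng, k_max=w_cap, allow_zero=True))[::-1]
            if abs(w.mean() - d_w_mean) > epsilon_dw:
                reasons["mean"] += 1
                continue
        if not thinning:
            if (D[order] < w).any():
                reasons["condition1"] += 1
                if explicit:
                    raise InputError(
                        "explicit within-degree sequence violates sorted dominance "
                        "by the degree sequence (Condition 1)"
                    )
                continue
            if w.max() > sizes.min():
                reasons["module_size"] += 1
                if explicit:
                    raise InputError(
                        "explicit within-degree sequence violates max[d_w] <= min[s_k]; "
                        "resample module sizes or relax the sequence"
                    )
                continue
            d_w = np.zeros(n, dtype=np.int64)
            d_w[order] = w
        ok = True
        for k in range(1, partition.n_modules + 1):
            members = partition.members(k)
            if not _parity_repair(d_w, members, rng):
                ok = False
                break
            if not erdos_gallai_check(d_w[members]):
                # thinning can leave a module top-heavy (hubs capped at
                # s_k - 1 next to thinned near-zero members); repair by
                # moving stubs from the top down, which keeps the module sum
                if not (
                    thinning and _module_eg_repair(d_w, members, node_cap, rng)
                ):
                    ok = False
                    break
        if not ok:
            reasons["condition2"] += 1
        if not ok:
            if explicit:
                raise InputError(
                    "explicit within-degree sequence is not graphical inside "
                    "every module (Condition 2)"
                )
            continue
        d_b = D - d_w
        # between-edge feasibility at node level: the between-graph restricted
        # to (module k) x (rest) is bipartite, so for each module the top-j
        # between-degrees must satisfy the Gale-Ryser-type bound
        # sum_{top j} d_b <= sum_{u outside k} min(d_b(u), j).  Necessary
        # (foreign capacity is shared between modules), and a cheap filter
        # against sequences the wiring stage cannot realize.
        if not _between_gale_ryser_ok(d_b, partition):
            reasons["between_feasible"] += 1
            if explicit:
                raise InputError(
                    "the implied between-degree sequence is not realizable as "
                    "a simple inter-module graph (distinct-partner capacity "
                    "exceeded)"
                )
            continue
        # Chungphaisan on the coarse module graph H.  The multiplicity cap of
        # a module pair (k, l) in H is the bipartite bound s_k * s_l; the
        # product of the two largest sizes is a uniform upper bound, so the
        # criterion below is a necessary condition for realizability.
        if partition.n_modules >= 2:
            s_sorted = np.sort(sizes)[::-1]
            b_cap = int(s_sorted[0]) * int(s_sorted[1])
        else:
            b_cap = 0
        coarse = CoarseMultigraphSequence(
            tuple(int(d_b[partition.members(k)].sum()) for k in range(1, partition.n_modules + 1)),
            b=b_cap,
        )
        if not chungphaisan_check(coarse):
            reasons["coarse"] += 1
            if explicit:
                raise InputError(
                    "between-degrees implied by the explicit within-degree "
                    "sequence fail the Chungphaisan realizability criterion"
                )
            continue
        return DegreeTriples(D, d_w, d_b)
    worst = max(reasons, key=reasons.get)
    raise SamplingError(
        f"no admissible within-degree sequence in {max_attempts} attempts "
        f"(most frequent failure: {worst}; counts {reasons})"
    )
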