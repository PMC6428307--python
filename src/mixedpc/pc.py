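"""Order-independent PC (PC-stable) structure learning.

The skeleton phase removes edges level by level: at level k every still
adjacent pair (X, Y) is tested against all size-k subsets of the
neighbors of X and of Y *as they stood at the start of the level*, and
all deletions are applied only when the level ends.  This makes the
output invariant to the order in which variables are stored.  The first
conditioning set with p > alpha is recorded as the pair's separating set
and later drives the collider orientation; Meek's rules then propagate
orientations to the maximally oriented PDAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, FrozenSet, List, Optional, Set

from .citests import symmetric_test
from .graphs import GraphError, Pdag
from .variables import MixedDataset

log = logging.getLogger(__name__)

SepsetTable = Dict[FrozenSet[str], Set[str]]


@dataclass
class PcResult:
    pdag: Pdag
    sepsets: SepsetTable
    tests_per_level: List[int] = field(default_factory=list)


def pc_skeleton(
    data: MixedDataset,
    test: Callable,
    alpha: float,
    max_k: Optional[int] = None,
):
    """PC-stable skeleton search.

    ``test(x, y, z)`` must return an object with a ``pvalue`` attribute
    (e.g. a closure over :func:`mixedpc.citests.symmetric_test`).
    Returns (adjacency dict, sepsets, tests-per-level list).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    nodes = sorted(data.names)
    p = len(nodes)
    if max_k is None:
        max_k = max(p - 2, 0)
    adj: Dict[str, Set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: SepsetTable = {}
    tests_per_level: List[int] = []

    k = 0
    while k <= max_k:
        frozen = {v: sorted(adj[v]) for v in nodes}
        if not any(len(frozen[v]) - 1 >= k for v in nodes):
            break
        n_tests = 0
        removals: Dict[FrozenSet[str], Set[str]] = {}
        for x, y in combinations(nodes, 2):
            if y not in adj[x]:
                continue
            tried: Set[FrozenSet[str]] = set()
            found = False
            for a, b in ((x, y), (y, x)):
                cand = [v for v in frozen[a] if v != b]
                if len(cand) < k:
                    continue
                for s in combinations(cand, k):
                    fs = frozenset(s)
                    if fs in tried:
                        continue
                    tried.add(fs)
                    res = test(a, b, sorted(s))
                    n_tests += 1
                    if res.pvalue > alpha:
                        removals[frozenset((x, y))] = set(s)
                        found = True
                        break
                if found:
                    break
        for pair, s in removals.items():
            u, v = tuple(pair)
            adj[u].discard(v)
            adj[v].discard(u)
            sepsets[pair] = s
        tests_per_level.append(n_tests)
        k += 1
    return adj, sepsets, tests_per_level


def orient_v_structures(adj, sepsets, nodes=None) -> Pdag:
    """Orient unshielded colliders X -> Z <- Y where Z is not in sepset(X, Y).

    Conflicting arrowhead claims on the same edge are resolved by leaving
    that edge undirected (logged), a conservative policy.
    """
    if nodes is None:
        nodes = sorted(adj)
    undirected = {frozenset((a, b)) for a in adj for b in adj[a]}
    pdag = Pdag(nodes, undirected=[tuple(e) for e in undirected])
    arrows: Set[tuple] = set()
    for z in sorted(adj):
        nbrs = sorted(adj[z])
        for x, y in combinations(nbrs, 2):
            if y in adj[x]:
                continue  # shielded
            pair = frozenset((x, y))
            if pair not in sepsets:
                raise GraphError(
                    f"non-adjacent pair ({x!r}, {y!r}) has no recorded sepset"
                )
            if z not in sepsets[pair]:
                arrows.add((x, z))
                arrows.add((y, z))
    for a, b in sorted(arrows):
        if (b, a) in arrows:
            log.info("conflicting collider orientations on %s-%s; "
                     "leaving undirected", a, b)
            continue
        if pdag.has_undirected(a, b):
            pdag.orient(a, b)
    return pdag


def apply_meek_rules(pdag: Pdag) -> Pdag:
    """Meek rules R1-R4 applied to a fixpoint; never retracts an arrowhead."""
    g = pdag.copy()
    changed = True
    while changed:
        changed = False
        for e in sorted(g.undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                if _meek_applies(g, x, y):
                    g.orient(x, y)
                    changed = True
                    break
            if changed:
                break
    return g


def _meek_applies(g: Pdag, x: str, y: str) -> bool:
    """Should the undirected edge x-y be oriented x -> y by R1-R4?"""
    nbrs_x = set(g.neighbors(x))
    nbrs_y = set(g.neighbors(y))
    # R1: z -> x, z and y non-adjacent  =>  x -> y
    for z in nbrs_x:
        if g.has_directed(z, x) and not g.adjacent(z, y):
            return True
    # R2: directed path x -> z -> y  =>  x -> y
    for z in nbrs_x & nbrs_y:
        if g.has_directed(x, z) and g.has_directed(z, y):
            return True
    # R3: x - z1 -> y and x - z2 -> y with z1, z2 non-adjacent  =>  x -> y
    zs = [z for z in nbrs_x & nbrs_y
          if g.has_undirected(x, z) and g.has_directed(z, y)]
    for z1, z2 in combinations(sorted(zs), 2):
        if not g.adjacent(z1, z2):
            return True
    # R4: x - z, z -> w, w -> y, x - w (z, y non-adjacent)  =>  x -> y
    for w in nbrs_x & nbrs_y:
        if not g.has_directed(w, y):
            continue
        for z in set(g.neighbors(w)) & nbrs_x:
            if (g.has_undirected(x, z) and g.has_directed(z, w)
                    and not g.adjacent(z, y)):
                return True
    return False


def pc(
    data: MixedDataset,
    alpha: float = 0.01,
    method: str = "mm",
    max_k: Optional[int] = None,
) -> PcResult:
    """Full PC-stable run: skeleton, collider orientation, Meek completion."""

    def test(x, y, z):
        return symmetric_test(x, y, z, data, method=method)

    adj, sepsets, tests_per_level = pc_skeleton(data, test, alpha, max_k)
    pdag = orient_v_structures(adj, sepsets)
    pdag = apply_meek_rules(pdag)
    return PcResult(pdag=pdag, sepsets=sepsets, tests_per_level=tests_per_level)
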