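"""Causal graph containers: DAGs and partially directed graphs (PDAGs).

A :class:`Dag` is a plain directed acyclic graph over named variables; a
:class:`Pdag` mixes directed edges (arrowheads shared by every member of
a Markov equivalence class) with undirected ones (orientation varies
within the class).  Both are small wrappers over edge sets — the PC
algorithm and the evaluation metrics need exact, hashable edge-mark
semantics rather than a general graph library's flexibility.
"""

from __future__ import annotations

from typing import Iterable, Tuple

import networkx as nx


class GraphError(ValueError):
    pass


class Dag:
    """Directed acyclic graph over a fixed node set."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[Tuple[str, str]] = (),
                 specs=None):
        """``specs``: optional mapping node -> VariableSpec (set by simulate)."""
        self.nodes = tuple(nodes)
        self.specs = dict(specs) if specs else {}
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise GraphError("duplicate node names")
        self.edges = set()
        for a, b in edges:
            if a not in node_set or b not in node_set:
                raise GraphError(f"edge ({a!r}, {b!r}) uses unknown node")
            if a == b:
                raise GraphError(f"self-loop on {a!r}")
            self.edges.add((a, b))
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, v: str):
        return sorted(a for a, b in self.edges if b == v)

    def topological_order(self):
        # lexicographic tie-break keeps the order deterministic
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def __eq__(self, other):
        return (isinstance(other, Dag) and set(self.nodes) == set(other.nodes)
                and self.edges == other.edges)

    def __repr__(self):
        return f"Dag({len(self.nodes)} nodes, {len(self.edges)} edges)"


class Pdag:
    """Partially directed graph: directed plus undirected edges.

    Invariants enforced: no self-loops, no pair carrying two marks (an
    edge is directed one way, or undirected, never both).
    """

    def __init__(self, nodes, directed=(), undirected=()):
        self.nodes = tuple(nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise GraphError("duplicate node names")
        self.directed = set()
        self.undirected = set()
        for a, b in directed:
            self._check(a, b, node_set)
            self.directed.add((a, b))
        for a, b in undirected:
            self._check(a, b, node_set)
            self.undirected.add(frozenset((a, b)))
        for a, b in self.directed:
            if (b, a) in self.directed:
                raise GraphError(f"edge {a!r}-{b!r} directed both ways")
            if frozenset((a, b)) in self.undirected:
                raise GraphError(f"edge {a!r}-{b!r} both directed and undirected")

    @staticmethod
    def _check(a, b, node_set):
        if a not in node_set or b not in node_set:
            raise GraphError(f"edge ({a!r}, {b!r}) uses unknown node")
        if a == b:
            raise GraphError(f"self-loop on {a!r}")

    # -- queries ---------------------------------------------------------
    def adjacent(self, a, b) -> bool:
        return ((a, b) in self.directed or (b, a) in self.directed
                or frozenset((a, b)) in self.undirected)

    def has_directed(self, a, b) -> bool:
        return (a, b) in self.directed

    def has_undirected(self, a, b) -> bool:
        return frozenset((a, b)) in self.undirected

    def neighbors(self, v):
        """All adjacent nodes, irrespective of edge marks."""
        out = set()
        for a, b in self.directed:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        for e in self.undirected:
            if v in e:
                out.add(next(iter(e - {v})))
        return sorted(out)

    def skeleton_pairs(self):
        """Unordered adjacent pairs as a set of frozensets."""
        pairs = {frozenset(e) for e in self.directed}
        return pairs | set(self.undirected)

    @property
    def n_edges(self):
        return len(self.directed) + len(self.undirected)

    # -- mutation (used by the orientation phase) ------------------------
    def orient(self, a, b):
        """Turn the undirected edge a-b into a -> b."""
        e = frozenset((a, b))
        if e not in self.undirected:
            raise GraphError(f"no undirected edge {a!r}-{b!r} to orient")
        self.undirected.discard(e)
        self.directed.add((a, b))

    def unorient(self, a, b):
        """Turn a directed edge (either way) back into an undirected one."""
        if (a, b) in self.directed:
            self.directed.discard((a, b))
        elif (b, a) in self.directed:
            self.directed.discard((b, a))
        else:
            raise GraphError(f"no directed edge between {a!r} and {b!r}")
        self.undirected.add(frozenset((a, b)))

    def copy(self) -> "Pdag":
        return Pdag(self.nodes,
                    directed=set(self.directed),
                    undirected={tuple(e) for e in self.undirected})

    def __eq__(self, other):
        return (isinstance(other, Pdag)
                and set(self.nodes) == set(other.nodes)
                and self.directed == other.directed
                and self.undirected == other.undirected)

    def __repr__(self):
        return (f"Pdag({len(self.nodes)} nodes, {len(self.directed)} directed, "
                f"{len(self.undirected)} undirected)")
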