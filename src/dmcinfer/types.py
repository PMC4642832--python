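"""Core containers for DMC network inference.

The observed data for the inference problem is a pair: an undirected,
simple protein--protein interaction graph ``G`` and a *duplication
forest* ``Gamma`` -- a pair of rooted binary trees whose leaves are
exactly the nodes of ``G``.  Each internal tree node records one
duplication event, so a forest over ``n + 2`` leaves encodes ``n``
growth steps back to the two-node seed graph.

Trees are represented structurally: a leaf is a positive ``int`` node
id, an internal node is a 2-tuple ``(left, right)``.  This keeps the
containers immutable and cheap to copy, which matters inside the
particle filter; converters to/from :mod:`networkx` are provided for
interoperability.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, NamedTuple, Sequence, Union

__all__ = [
    "Tree",
    "PPIGraph",
    "DuplicationForest",
    "DMCParams",
    "GrowthHistory",
    "Cherry",
    "ValidationReport",
    "count_cherries",
    "validate_pair",
]

#: A rooted binary tree: a leaf is a positive int, an internal node a 2-tuple.
Tree = Union[int, tuple]


def _iter_leaves(tree: Tree) -> Iterator[int]:
    stack = [tree]
    while stack:
        node = stack.pop()
        if isinstance(node, tuple):
            stack.extend(node)
        else:
            yield node


def _iter_internal(tree: Tree) -> Iterator[tuple]:
    stack = [tree]
    while stack:
        node = stack.pop()
        if isinstance(node, tuple):
            yield node
            stack.extend(node)


def _check_tree(tree: Tree) -> None:
    stack = [tree]
    while stack:
        node = stack.pop()
        if isinstance(node, tuple):
            if len(node) != 2:
                raise ValueError("forest must be binary: internal node with "
                                 f"{len(node)} children")
            stack.extend(node)
        elif isinstance(node, bool) or not isinstance(node, int):
            raise TypeError(f"leaf labels must be ints, got {node!r}")
        elif node < 1:
            raise ValueError(f"node ids must be positive integers, got {node}")


class Cherry(NamedTuple):
    """An internal forest node whose two children are both leaves.

    Cherries are the only positions where a backward (un-duplication)
    move is possible: merging the two leaves undoes one growth step.
    """

    parent: tuple
    leaf_ids: tuple  # (min, max) of the two leaf ids


class PPIGraph:
    """Undirected simple graph of proteins (nodes) and interactions (edges).

    Node ids are positive integers.  Self-loops and multi-edges are
    rejected; isolated nodes are permitted (a duplicate that lost every
    copied edge and was not homodimerized is isolated).
    """

    __slots__ = ("_adj",)

    def __init__(self, edges: Iterable = (), nodes: Iterable[int] = ()):
        adj: dict = {}
        for v in nodes:
            self._check_id(v)
            adj.setdefault(v, set())
        for e in edges:
            a, b = e
            self._check_id(a)
            self._check_id(b)
            if a == b:
                raise ValueError(f"self-loop ({a}, {b}) not permitted")
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        self._adj = {v: frozenset(nb) for v, nb in adj.items()}

    @staticmethod
    def _check_id(v) -> None:
        if isinstance(v, bool) or not isinstance(v, (int,)):
            try:
                if int(v) != v:
                    raise TypeError
            except (TypeError, ValueError):
                raise TypeError(f"node ids must be integers, got {v!r}") from None
        if int(v) < 1:
            raise ValueError(f"node ids must be positive integers, got {v}")

    @classmethod
    def _from_adj(cls, adj: dict) -> "PPIGraph":
        """Trusted constructor from a validated {node: frozenset} mapping."""
        g = object.__new__(cls)
        g._adj = adj
        return g

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._adj)

    @property
    def edges(self) -> frozenset:
        return frozenset(
            (v, w) if v < w else (w, v)
            for v, nb in self._adj.items() for w in nb if v < w
        )

    @property
    def num_nodes(self) -> int:
        return len(self._adj)

    @property
    def num_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def neighbors(self, v: int) -> frozenset:
        return self._adj[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def has_node(self, v: int) -> bool:
        return v in self._adj

    def has_edge(self, a: int, b: int) -> bool:
        nb = self._adj.get(a)
        return nb is not None and b in nb

    def __contains__(self, v: int) -> bool:
        return v in self._adj

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPIGraph):
            return NotImplemented
        return self._adj == other._adj

    def __hash__(self) -> int:
        return hash((frozenset(self._adj), self.edges))

    def __repr__(self) -> str:
        return f"PPIGraph(|V|={self.num_nodes}, |E|={self.num_edges})"

    # -- interop ---------------------------------------------------------

    def to_networkx(self):
        """Export as a :class:`networkx.Graph`."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, graph) -> "PPIGraph":
        return cls(edges=graph.edges(), nodes=graph.nodes())

    @classmethod
    def seed(cls) -> "PPIGraph":
        """The seed graph K2: nodes 1 and 2, connected."""
        return cls(edges=[(1, 2)])


class DuplicationForest:
    """A collection of rooted binary trees encoding a duplication history.

    When paired with an observed graph the leaf ids biject onto the
    graph's node set.  A history that starts from the two-node seed
    graph always yields exactly two trees; the trivial forest is two
    single-leaf trees.
    """

    __slots__ = ("_trees",)

    def __init__(self, trees: Sequence[Tree]):
        trees = tuple(trees)
        seen: set = set()
        for t in trees:
            _check_tree(t)
            for leaf in _iter_leaves(t):
                if leaf in seen:
                    raise ValueError(f"duplicate leaf label {leaf}")
                seen.add(leaf)
        self._trees = trees

    @property
    def trees(self) -> tuple:
        return self._trees

    @property
    def num_trees(self) -> int:
        return len(self._trees)

    @property
    def leaf_ids(self) -> frozenset:
        return frozenset(l for t in self._trees for l in _iter_leaves(t))

    @property
    def num_leaves(self) -> int:
        return sum(1 for t in self._trees for _ in _iter_leaves(t))

    @property
    def num_internal(self) -> int:
        return sum(1 for t in self._trees for _ in _iter_internal(t))

    def cherries(self) -> list:
        """All cherries, sorted by (min leaf id, max leaf id).

        The canonical ordering makes seeded proposal sampling
        bit-reproducible regardless of tree construction order.
        """
        out = []
        for t in self._trees:
            for node in _iter_internal(t):
                a, b = node
                if not isinstance(a, tuple) and not isinstance(b, tuple):
                    out.append(Cherry(node, (a, b) if a < b else (b, a)))
        out.sort(key=lambda c: c.leaf_ids)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, DuplicationForest):
            return NotImplemented
        return self._trees == other._trees

    def __hash__(self) -> int:
        return hash(self._trees)

    def __repr__(self) -> str:
        return (f"DuplicationForest({self.num_trees} trees, "
                f"{self.num_leaves} leaves)")

    @classmethod
    def trivial(cls) -> "DuplicationForest":
        """The forest paired with the seed graph: two single-leaf trees."""
        return cls((1, 2))


@dataclasses.dataclass(frozen=True)
class DMCParams:
    """The DMC parameter pair.

    ``p`` is the mutation parameter: after a node's neighborhood is
    duplicated, each copied edge pair keeps both edges with probability
    ``p`` and otherwise loses one of the two uniformly at random.
    ``p_c`` is the homodimerization parameter: the probability that the
    anchor and its duplicate are joined by an edge.  Both are kept
    strictly inside (0, 1) so that every backward reconstruction move
    has positive probability.
    """

    p: float
    p_c: float

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not (0.0 < self.p_c < 1.0):
            raise ValueError(f"p_c must be in (0, 1), got {self.p_c}")


@dataclasses.dataclass
class GrowthHistory:
    """A full growth trajectory from the seed graph to the observed graph.

    ``graphs[t]`` and ``forests[t]`` are the state after ``t`` growth
    steps; ``anchors[t-1]`` / ``duplicates[t-1]`` are the anchor node
    u_t chosen at step t and the new duplicate node v_t it spawned.
    The duplicate sequence (v_1, ..., v_n) together with the final
    forest suffices to replay the history backward deterministically.
    """

    graphs: list
    forests: list
    anchors: list
    duplicates: list

    @property
    def n_steps(self) -> int:
        return len(self.anchors)

    @property
    def final_graph(self) -> PPIGraph:
        return self.graphs[-1]

    @property
    def final_forest(self) -> DuplicationForest:
        return self.forests[-1]

    @property
    def theta(self) -> tuple:
        """The duplicate-node sequence (v_1, ..., v_n)."""
        return tuple(self.duplicates)

    def __post_init__(self):
        if not (len(self.graphs) == len(self.forests)
                == len(self.anchors) + 1 == len(self.duplicates) + 1):
            raise ValueError("inconsistent history lengths")


@dataclasses.dataclass
class ValidationReport:
    ok: bool
    messages: list

    def __bool__(self) -> bool:
        return self.ok


def count_cherries(forest: DuplicationForest) -> int:
    """Number of internal forest nodes whose two children are both leaves.

    The backward proposal chooses uniformly among ``2 * count_cherries``
    cherry-leaf pairs, so this is the proposal's support size divided
    by two.  The trivial forest has no internal node and hence zero
    cherries.
    """
    return len(forest.cherries())


def validate_pair(graph: PPIGraph, forest: DuplicationForest,
                  require_two_trees: bool = True) -> ValidationReport:
    """Check that a graph and a duplication forest form a coherent pair.

    Verifies that forest leaves biject onto graph nodes, that the
    forest has exactly two trees (the seed graph has two nodes; relax
    with ``require_two_trees=False`` for non-standard seeds), and that
    the graph has at least two nodes.  Never raises; all violations are
    listed in the report.
    """
    messages = []
    if graph.num_nodes < 2:
        messages.append("graph must have at least 2 nodes")
    if forest.leaf_ids != graph.nodes:
        messages.append("leaf/node mismatch: forest leaves must biject onto "
                        "graph nodes")
    if require_two_trees and forest.num_trees != 2:
        messages.append("forest must contain exactly 2 trees")
    return ValidationReport(ok=not messages, messages=messages)
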