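"""The DMC growth kernel: forward simulation and backward reconstruction.

One growth step of the duplication--mutation-with-complementarity model
transforms ``G_{t-1}`` into ``G_t``:

1. *Duplication*: an anchor ``u`` is drawn uniformly from the current
   nodes and a new duplicate node ``v`` is attached to every neighbor
   of ``u``.
2. *Mutation*: for each neighbor ``w`` of ``u``, with probability
   ``1 - p`` one of the two parallel edges ``(u, w)``, ``(v, w)`` is
   chosen uniformly and deleted; with probability ``p`` both survive.
   Choices are independent across neighbors.
3. *Homodimerization*: the edge ``(u, v)`` is added with probability
   ``p_c``.

The matching duplication-forest step replaces the leaf ``u`` by the
cherry ``(u, v)`` and is deterministic given ``(u, v)``.  The step is
invertible given the forest: a duplicate must be a cherry leaf, its
anchor is the cherry sibling, and merging their neighborhoods restores
the pre-duplication graph exactly.

All probabilities are carried in natural-log space; the anchor-choice
factor ``1/|V(G_{t-1})|`` is included in the transition probability so
that kernel values match exhaustive forward-simulation frequencies.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .types import (Cherry, DMCParams, DuplicationForest, GrowthHistory,
                    PPIGraph)

__all__ = [
    "TransitionRecord",
    "simulate_dmc",
    "forward_step",
    "backward_merge",
    "transition_log_prob",
    "transition_record",
    "proposal_log_prob",
    "sample_duplicate",
]

NEG_INF = float("-inf")


@dataclasses.dataclass(frozen=True)
class TransitionRecord:
    """Latent outcomes of one growth step, read off a realized transition.

    ``kept_both`` and ``kept_one`` partition the anchor's
    pre-duplication neighborhood by whether both parallel edges
    survived the mutation step or only one did; ``homodimer`` records
    whether the anchor--duplicate edge was added.
    """

    anchor: int
    duplicate: int
    kept_both: frozenset
    kept_one: frozenset
    homodimer: bool


# ---------------------------------------------------------------------------
# Fast internal representation: adjacency dicts {node: frozenset} and
# structural tree tuples.  The particle filter runs millions of backward
# steps, so these helpers avoid container re-validation on the hot path.
# ---------------------------------------------------------------------------

def _tree_merge(tree, parent, anchor):
    """Replace the cherry node ``parent`` by a leaf ``anchor``; None if absent."""
    if tree == parent:
        return anchor
    if not isinstance(tree, tuple):
        return None
    left, right = tree
    new_left = _tree_merge(left, parent, anchor)
    if new_left is not None:
        return (new_left, right)
    new_right = _tree_merge(right, parent, anchor)
    if new_right is not None:
        return (left, new_right)
    return None


def _forest_merge(trees, parent, anchor):
    for i, t in enumerate(trees):
        merged = _tree_merge(t, parent, anchor)
        if merged is not None:
            return trees[:i] + (merged,) + trees[i + 1:]
    raise ValueError("cherry not found in forest")


def _adj_merge(adj, duplicate, anchor):
    """Undo one duplication on an adjacency dict: drop ``duplicate`` and
    give ``anchor`` the union neighborhood."""
    nb_u = adj[anchor]
    nb_v = adj[duplicate]
    union = (nb_u | nb_v) - {anchor, duplicate}
    new_adj = {}
    for x, nb in adj.items():
        if x == duplicate:
            continue
        if x == anchor:
            new_adj[x] = union
        elif duplicate in nb:
            new_adj[x] = (nb - {duplicate}) | {anchor}
        elif x in union and anchor not in nb:
            new_adj[x] = nb | {anchor}
        else:
            new_adj[x] = nb
    return new_adj, union


def _step_log_prob(adj_curr, anchor, duplicate, union, log_p, log_half_q,
                   log_pc, log_1mpc):
    """log p_M(G_t | G_{t-1}) for a merge-consistent transition.

    ``union`` is the anchor's pre-duplication neighborhood.  Assumes the
    transition is structurally valid (every ``w`` in ``union`` is
    adjacent to the anchor or the duplicate in ``G_t``), which holds by
    construction for any cherry-leaf backward move.
    """
    nb_u = adj_curr[anchor]
    nb_v = adj_curr[duplicate]
    n_both = len(nb_u & nb_v)
    n_one = len(union) - n_both
    lp = -math.log(len(adj_curr) - 1) + n_both * log_p + n_one * log_half_q
    lp += log_pc if duplicate in nb_u else log_1mpc
    return lp


def _find_cherry(forest: DuplicationForest, duplicate: int) -> Cherry:
    for cherry in forest.cherries():
        if duplicate in cherry.leaf_ids:
            return cherry
    raise ValueError(f"not a valid duplicate at this step: node {duplicate} "
                     "is not a leaf of any cherry")


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def simulate_dmc(params: DMCParams, target_size: int,
                 seed=None) -> GrowthHistory:
    """Simulate a growth history from the seed graph up to ``target_size`` nodes.

    The seed graph is K2 on nodes {1, 2} with the trivial two-leaf
    forest; the duplicate created at step ``t`` receives id ``t + 2``.
    ``target_size = 2`` returns the zero-step history.

    Parameters
    ----------
    params
        Mutation and homodimerization probabilities.
    target_size
        Number of nodes in the final graph; must be >= 2.
    seed
        Int seed or :class:`numpy.random.Generator`.
    """
    if target_size < 2:
        raise ValueError(f"target_size must be >= 2, got {target_size}")
    rng = np.random.default_rng(seed)

    adj = {1: frozenset({2}), 2: frozenset({1})}
    trees: tuple = (1, 2)
    graphs = [PPIGraph._from_adj(adj)]
    forests = [DuplicationForest(trees)]
    anchors: list = []
    duplicates: list = []

    for step in range(1, target_size - 1):
        adj, trees, u, v = _forward_step(adj, trees, params.p, params.p_c,
                                         step + 2, rng)
        graphs.append(PPIGraph._from_adj(adj))
        forests.append(DuplicationForest(trees))
        anchors.append(u)
        duplicates.append(v)

    return GrowthHistory(graphs, forests, anchors, duplicates)


def _forward_step(adj, trees, p, p_c, v, rng):
    """One duplication-mutation-homodimerization step on the fast state."""
    node_list = sorted(adj)
    u = node_list[rng.integers(len(node_list))]

    new_adj = dict(adj)
    nb_v = set()
    for w in adj[u]:
        r = rng.random()
        if r < p:                     # keep both parallel edges
            nb_v.add(w)
            new_adj[w] = new_adj[w] | {v}
        elif r < p + (1.0 - p) / 2.0:  # delete (u, w), keep (v, w)
            nb_v.add(w)
            new_adj[w] = (new_adj[w] - {u}) | {v}
            new_adj[u] = new_adj[u] - {w}
        # else delete (v, w): nothing to do
    if rng.random() < p_c:
        nb_v.add(u)
        new_adj[u] = new_adj[u] | {v}
    new_adj[v] = frozenset(nb_v)
    return new_adj, _forest_replace_leaf(trees, u, (u, v)), u, v


def forward_step(graph: PPIGraph, forest: DuplicationForest,
                 params: DMCParams, duplicate: int | None = None,
                 seed=None):
    """Apply one random growth step to an arbitrary (graph, forest) state.

    The anchor is drawn uniformly from the graph's nodes; ``duplicate``
    is the id given to the new node (default: one past the largest
    existing id, which must not collide with an existing node).

    Returns
    -------
    (PPIGraph, DuplicationForest, int, int)
        The grown graph and forest, the anchor id and the duplicate id.
    """
    rng = np.random.default_rng(seed)
    if duplicate is None:
        duplicate = max(graph.nodes) + 1
    elif graph.has_node(duplicate):
        raise ValueError(f"duplicate id {duplicate} already in the graph")
    adj, trees, u, v = _forward_step(dict(graph._adj), forest.trees,
                                     params.p, params.p_c, duplicate, rng)
    return (PPIGraph._from_adj(adj), DuplicationForest(trees), u, v)


def _tree_replace_leaf(tree, leaf, replacement):
    if tree == leaf and not isinstance(tree, tuple):
        return replacement
    if not isinstance(tree, tuple):
        return None
    left, right = tree
    new_left = _tree_replace_leaf(left, leaf, replacement)
    if new_left is not None:
        return (new_left, right)
    new_right = _tree_replace_leaf(right, leaf, replacement)
    if new_right is not None:
        return (left, new_right)
    return None


def _forest_replace_leaf(trees, leaf, replacement):
    for i, t in enumerate(trees):
        replaced = _tree_replace_leaf(t, leaf, replacement)
        if replaced is not None:
            return trees[:i] + (replaced,) + trees[i + 1:]
    raise ValueError(f"leaf {leaf} not found in forest")


def backward_merge(graph: PPIGraph, forest: DuplicationForest,
                   duplicate: int):
    """Undo the growth step that created ``duplicate``.

    The duplicate must be a cherry leaf; its cherry sibling is the
    anchor.  The merged graph drops the duplicate and assigns the
    anchor the union of both neighborhoods (minus the pair itself);
    the merged forest collapses the cherry to a single anchor leaf.
    Deterministic.

    Returns
    -------
    (PPIGraph, DuplicationForest, int)
        The previous graph, previous forest, and the anchor node id.
    """
    if not graph.has_node(duplicate):
        raise ValueError(f"not a valid duplicate at this step: node "
                         f"{duplicate} is not in the graph")
    cherry = _find_cherry(forest, duplicate)
    a, b = cherry.leaf_ids
    anchor = a if b == duplicate else b
    new_adj, _ = _adj_merge(dict(graph._adj), duplicate, anchor)
    new_trees = _forest_merge(forest.trees, cherry.parent, anchor)
    return (PPIGraph._from_adj(new_adj), DuplicationForest(new_trees), anchor)


def transition_record(prev_graph: PPIGraph, curr_graph: PPIGraph,
                      anchor: int, duplicate: int) -> TransitionRecord:
    """Read the latent mutation/homodimerization outcomes off a transition."""
    nb_u = curr_graph.neighbors(anchor)
    nb_v = curr_graph.neighbors(duplicate)
    both = (nb_u & nb_v) - {anchor, duplicate}
    prev_nb = prev_graph.neighbors(anchor)
    return TransitionRecord(
        anchor=anchor,
        duplicate=duplicate,
        kept_both=frozenset(both),
        kept_one=frozenset(prev_nb - both),
        homodimer=duplicate in nb_u,
    )


def transition_log_prob(prev_graph: PPIGraph, curr_graph: PPIGraph,
                        anchor: int, duplicate: int,
                        params: DMCParams) -> float:
    """log p_M(G_t | G_{t-1}) for one growth step, anchor choice included.

    The probability factorizes as ``1/|V(G_{t-1})|`` for the uniform
    anchor draw, times ``p`` per neighbor that kept both parallel
    edges, ``(1-p)/2`` per neighbor that kept exactly one, and ``p_c``
    or ``1-p_c`` for the homodimer edge.  Transitions the step cannot
    generate (a neighbor that lost both edges, a duplicate edge to a
    non-neighbor of the anchor, or any change away from the
    duplicated pair) have probability zero and return ``-inf``.

    Raises on precondition violations: ``anchor`` must be a node of
    ``prev_graph``, ``duplicate`` a node of ``curr_graph`` but not of
    ``prev_graph``, and the node sets must differ by exactly the
    duplicate.
    """
    if not prev_graph.has_node(anchor):
        raise ValueError(f"anchor {anchor} not in previous graph")
    if prev_graph.has_node(duplicate):
        raise ValueError(f"duplicate {duplicate} already in previous graph")
    if not curr_graph.has_node(duplicate):
        raise ValueError(f"duplicate {duplicate} not in current graph")
    if curr_graph.nodes != prev_graph.nodes | {duplicate}:
        raise ValueError("current graph nodes must be previous nodes plus "
                         "the duplicate")

    # A transition is generatable iff merging (duplicate -> anchor) in the
    # current graph reproduces the previous graph exactly.
    merged_adj, union = _adj_merge(dict(curr_graph._adj), duplicate, anchor)
    if merged_adj != dict(prev_graph._adj):
        return NEG_INF

    p, p_c = params.p, params.p_c
    return _step_log_prob(curr_graph._adj, anchor, duplicate, union,
                          math.log(p), math.log((1.0 - p) / 2.0),
                          math.log(p_c), math.log(1.0 - p_c))


def proposal_log_prob(forest: DuplicationForest) -> float:
    """log q(v) of the backward proposal: uniform over cherry-leaf choices.

    A proposal picks one of the forest's cherries uniformly at random
    and then one of its two leaves uniformly, so every particular
    duplicate-leaf choice has probability ``1 / (2 * #cherries)``.
    """
    c = len(forest.cherries())
    if c == 0:
        raise ValueError("backward proposal undefined on trivial forest")
    return -math.log(2 * c)


def sample_duplicate(forest: DuplicationForest, seed=None) -> int:
    """Draw a duplicate node: a uniformly chosen leaf of a uniformly chosen cherry."""
    cherries = forest.cherries()
    if not cherries:
        raise ValueError("backward proposal undefined on trivial forest")
    rng = np.random.default_rng(seed)
    idx = int(rng.integers(2 * len(cherries)))
    return cherries[idx >> 1].leaf_ids[idx & 1]
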