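"""Brute-force enumeration oracle for small observed pairs.

For a pair ``(G, Gamma)`` the likelihood is a sum over every duplicate
sequence ``theta = (v_1, ..., v_n)`` compatible with the forest, of the
product of per-step growth probabilities along the backward
reconstruction that ``theta`` induces.  Because each backward step must
pick a cherry leaf, the recursion branches over at most
``2 * #cherries`` choices per step and terminates at the seed graph.

This module exists as the exact ground truth against which the particle
filter's unbiasedness and the PMMH posterior are validated; it is a
desk-scale tool, capped by default at histories of length 8.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
from scipy.special import logsumexp

from .model import (_adj_merge, _forest_merge, _step_log_prob)
from .types import DMCParams, DuplicationForest, PPIGraph, validate_pair

__all__ = [
    "GridPosterior",
    "enumerate_theta",
    "exact_log_likelihood",
    "grid_posterior",
]

DEFAULT_ENUMERATION_CAP = 8


def _forest_cherry_nodes(trees):
    """(parent, min_leaf, max_leaf) for every cherry, canonically sorted."""
    out = []
    stack = list(trees)
    while stack:
        node = stack.pop()
        if isinstance(node, tuple):
            a, b = node
            if not isinstance(a, tuple) and not isinstance(b, tuple):
                out.append((node, a, b) if a < b else (node, b, a))
            else:
                stack.extend(node)
    out.sort(key=lambda c: (c[1], c[2]))
    return out


def _check_enumerable(graph, forest, cap):
    report = validate_pair(graph, forest)
    if not report.ok:
        raise ValueError("invalid (graph, forest) pair: "
                         + "; ".join(report.messages))
    n = graph.num_nodes - 2
    if n > cap:
        raise ValueError(
            f"history length {n} exceeds the enumeration cap {cap}; "
            "use the SMC estimator for pairs of this size")
    return n


def enumerate_theta(graph: PPIGraph, forest: DuplicationForest,
                    cap: int = DEFAULT_ENUMERATION_CAP) -> list:
    """Every duplicate sequence (v_1, ..., v_n) compatible with the pair.

    Depth-first recursion: at each backward step, branch over every
    cherry-leaf choice, merge, and recurse down to the seed.  Each
    compatible sequence appears exactly once; the result is sorted
    lexicographically.  The zero-step pair yields the single empty
    sequence.
    """
    _check_enumerable(graph, forest, cap)

    results: list = []

    def recurse(adj, trees, suffix):
        if len(adj) == 2:
            results.append(suffix)
            return
        for parent, a, b in _forest_cherry_nodes(trees):
            for dup, anchor in ((a, b), (b, a)):
                new_adj, _ = _adj_merge(adj, dup, anchor)
                new_trees = _forest_merge(trees, parent, anchor)
                recurse(new_adj, new_trees, (dup,) + suffix)

    recurse(dict(graph._adj), forest.trees, ())
    return sorted(results)


def exact_log_likelihood(graph: PPIGraph, forest: DuplicationForest,
                         params: DMCParams,
                         cap: int = DEFAULT_ENUMERATION_CAP) -> float:
    """log p_M(G, Gamma): the exhaustive sum over compatible histories.

    Computes ``log sum_theta prod_t p_M(G_t, Gamma_t | G_{t-1},
    Gamma_{t-1})`` by branching over all backward cherry-leaf choices,
    accumulating per-step log-probabilities, and combining complete
    paths with log-sum-exp.  Finite for any parameters in (0, 1)^2:
    every cherry-leaf merge is forward-reachable with positive
    probability.
    """
    n = _check_enumerable(graph, forest, cap)
    if n == 0:
        return 0.0  # p_M(G_0, Gamma_0) = 1 for the fixed seed

    p, p_c = params.p, params.p_c
    log_p = math.log(p)
    log_half_q = math.log((1.0 - p) / 2.0)
    log_pc = math.log(p_c)
    log_1mpc = math.log(1.0 - p_c)

    path_logs: list = []

    def recurse(adj, trees, acc):
        if len(adj) == 2:
            path_logs.append(acc)
            return
        for parent, a, b in _forest_cherry_nodes(trees):
            # merging with anchor x collapses the cherry to leaf x
            new_trees_a = _forest_merge(trees, parent, a)
            new_trees_b = _forest_merge(trees, parent, b)
            for dup, anchor, new_trees in ((a, b, new_trees_b),
                                           (b, a, new_trees_a)):
                new_adj, union = _adj_merge(adj, dup, anchor)
                lp = _step_log_prob(adj, anchor, dup, union, log_p,
                                    log_half_q, log_pc, log_1mpc)
                recurse(new_adj, new_trees, acc + lp)

    recurse(dict(graph._adj), forest.trees, 0.0)
    return float(logsumexp(path_logs))


@dataclasses.dataclass
class GridPosterior:
    """Discretized joint posterior over (p, p_c) on a uniform grid.

    ``grid`` holds the cell-center parameter pairs in row-major order
    (p varies slowest) and ``masses`` the matching normalized
    probabilities.  ``resolution`` and ``box`` allow histogramming MCMC
    output onto the identical cells.
    """

    grid: np.ndarray        # shape (R*R, 2)
    masses: np.ndarray      # shape (R*R,)
    resolution: int
    box: tuple              # (lo, hi), shared by both axes

    @property
    def cell_edges(self) -> np.ndarray:
        lo, hi = self.box
        return np.linspace(lo, hi, self.resolution + 1)

    def marginal(self, axis: int) -> np.ndarray:
        """Marginal masses for p (axis=0) or p_c (axis=1)."""
        m = self.masses.reshape(self.resolution, self.resolution)
        return m.sum(axis=1 - axis)

    @property
    def mean(self) -> np.ndarray:
        return self.masses @ self.grid

    @property
    def mode(self) -> np.ndarray:
        return self.grid[int(np.argmax(self.masses))]


def grid_posterior(graph: PPIGraph, forest: DuplicationForest,
                   grid_resolution: int = 17,
                   prior_box: tuple = (0.1, 0.9),
                   cap: int = DEFAULT_ENUMERATION_CAP) -> GridPosterior:
    """Exact posterior over (p, p_c) on a uniform grid of cell centers.

    The prior is flat on ``prior_box`` (squared), so cell masses are
    proportional to the exact likelihood evaluated at the cell center.
    A single-cell grid has mass one by normalization.
    """
    if grid_resolution < 1:
        raise ValueError("grid_resolution must be >= 1")
    lo, hi = prior_box
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"prior box must satisfy 0 < lo < hi < 1, got "
                         f"({lo}, {hi})")
    edges = np.linspace(lo, hi, grid_resolution + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pairs = np.array(list(itertools.product(centers, centers)))
    logliks = np.array([
        exact_log_likelihood(graph, forest, DMCParams(p=pp, p_c=pc), cap=cap)
        for pp, pc in pairs
    ])
    masses = np.exp(logliks - logsumexp(logliks))
    masses /= masses.sum()
    return GridPosterior(grid=pairs, masses=masses,
                         resolution=grid_resolution, box=(lo, hi))
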