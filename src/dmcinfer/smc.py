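"""Backward sequential Monte Carlo over growth histories.

Given an observed pair ``(G, Gamma)`` and fixed parameters, the filter
runs ``n = |V(G)| - 2`` backward steps.  Each particle proposes a
duplicate node uniformly among the cherry-leaf choices of its current
forest, merges it away, and is weighted by the ratio of the forward
growth probability of the undone step to the proposal probability.
Multinomial resampling is applied between every pair of steps.  The
product over steps of the mean unnormalized weight,

    p_hat(G, Gamma) = prod_{t=0}^{n-1} [ (1/N) sum_i W_t^i ],

is an unbiased estimate of the likelihood p_M(G, Gamma) and is the
quantity the pseudo-marginal sampler consumes.  Every backward proposal
is forward-reachable with positive probability, so no particle ever
receives zero weight and the estimate is finite for parameters in
(0, 1)^2.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import logsumexp

from .model import _adj_merge, _forest_merge, _step_log_prob
from .exact import _forest_cherry_nodes
from .types import DMCParams, DuplicationForest, PPIGraph, validate_pair

__all__ = [
    "ParticleSystem",
    "run_smc",
    "log_likelihood_estimate",
    "relative_variance",
]


@dataclasses.dataclass
class ParticleSystem:
    """Complete record of one particle-filter run.

    Step arrays are stored in the order computed, i.e. row ``k``
    corresponds to backward step ``t = n - k`` and carries the weights
    ``W_{t-1}^{1:N}``; the final row holds ``W_0``.  ``ancestors`` has
    one row per resampling event (between consecutive steps).
    ``thetas`` holds, per particle, the full reconstructed duplicate
    sequence (v_1, ..., v_n).
    """

    n_particles: int
    n_steps: int
    log_weights: np.ndarray      # shape (n_steps, N)
    ancestors: np.ndarray        # shape (n_steps - 1, N)
    duplicates: np.ndarray       # shape (n_steps, N), proposed v_t per particle
    thetas: list                 # N tuples, each of length n_steps

    @property
    def log_likelihood(self) -> float:
        """The unbiased estimate, on the log scale (log-sum-exp per step)."""
        n = self.n_particles
        return float(sum(logsumexp(row) - math.log(n)
                         for row in self.log_weights))

    def normalized_weights(self, step: int) -> np.ndarray:
        row = self.log_weights[step]
        w = np.exp(row - logsumexp(row))
        return w / w.sum()

    def select_particle(self, seed=None) -> int:
        """Draw a particle index proportional to the final-step weights."""
        rng = np.random.default_rng(seed)
        w = self.normalized_weights(-1)
        return int(rng.choice(self.n_particles, p=w))


def run_smc(graph: PPIGraph, forest: DuplicationForest, params: DMCParams,
            n_particles: int, seed=None,
            resampling: str = "multinomial") -> ParticleSystem:
    """Run the backward particle filter on an observed pair.

    Parameters
    ----------
    graph, forest
        The observed pair; must validate and must not be the two-node
        seed pair (whose likelihood is identically one).
    params
        Fixed mutation/homodimerization parameters.
    n_particles
        Number of particles N >= 1.
    seed
        Int seed or :class:`numpy.random.Generator`; a single stream
        drives proposals and resampling, in particle order.
    resampling
        ``"multinomial"`` (the stated algorithm) or ``"systematic"``.
    """
    report = validate_pair(graph, forest)
    if not report.ok:
        raise ValueError("invalid (graph, forest) pair: "
                         + "; ".join(report.messages))
    n = graph.num_nodes - 2
    if n == 0:
        raise ValueError("observed graph is a seed graph; its likelihood "
                         "is 1 and there is nothing to filter")
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if resampling not in ("multinomial", "systematic"):
        raise ValueError(f"unknown resampling scheme {resampling!r}")
    rng = np.random.default_rng(seed)

    p, p_c = params.p, params.p_c
    log_p = math.log(p)
    log_half_q = math.log((1.0 - p) / 2.0)
    log_pc = math.log(p_c)
    log_1mpc = math.log(1.0 - p_c)

    N = n_particles
    adj0 = dict(graph._adj)
    trees0 = forest.trees
    # particle state: (adjacency dict, forest tuple, reversed theta tuple)
    adjs = [adj0] * N
    forests = [trees0] * N
    thetas = [()] * N

    all_log_w = np.empty((n, N))
    all_anc = np.empty((n - 1, N), dtype=np.intp)
    all_dup = np.empty((n, N), dtype=np.intp)

    log_w = None
    for k in range(n):          # backward step t = n - k
        if k > 0:
            if resampling == "multinomial":
                w = np.exp(log_w - logsumexp(log_w))
                w /= w.sum()
                anc = rng.choice(N, size=N, p=w)
            else:
                w = np.exp(log_w - logsumexp(log_w))
                w /= w.sum()
                positions = (rng.random() + np.arange(N)) / N
                anc = np.searchsorted(np.cumsum(w), positions)
            all_anc[k - 1] = anc
            adjs = [adjs[j] for j in anc]
            forests = [forests[j] for j in anc]
            thetas = [thetas[j] for j in anc]

        # cherries are identical for particles sharing a resampled ancestor
        cherry_cache: dict = {}
        log_w = np.empty(N)
        new_adjs, new_forests, new_thetas = [], [], []
        for i in range(N):
            trees = forests[i]
            cherries = cherry_cache.get(trees)
            if cherries is None:
                cherries = _forest_cherry_nodes(trees)
                cherry_cache[trees] = cherries
            idx = int(rng.integers(2 * len(cherries)))
            parent, a, b = cherries[idx >> 1]
            dup, anchor = (a, b) if (idx & 1) == 0 else (b, a)

            adj = adjs[i]
            new_adj, union = _adj_merge(adj, dup, anchor)
            lp = _step_log_prob(adj, anchor, dup, union, log_p, log_half_q,
                                log_pc, log_1mpc)
            # W = p_M(step) / q(v), q uniform over 2 * #cherries choices
            log_w[i] = lp + math.log(2 * len(cherries))
            all_dup[k, i] = dup
            new_adjs.append(new_adj)
            new_forests.append(_forest_merge(trees, parent, anchor))
            new_thetas.append(thetas[i] + (dup,))
        adjs, forests, thetas = new_adjs, new_forests, new_thetas
        all_log_w[k] = log_w

    return ParticleSystem(
        n_particles=N,
        n_steps=n,
        log_weights=all_log_w,
        ancestors=all_anc,
        duplicates=all_dup,
        thetas=[tuple(reversed(th)) for th in thetas],
    )


def log_likelihood_estimate(system: ParticleSystem) -> float:
    """The unbiased likelihood estimate of a completed run, in log space.

    Sums, over backward steps, the log of the mean unnormalized weight;
    each per-step mean is computed with log-sum-exp for stability.
    """
    return system.log_likelihood


def relative_variance(values) -> float:
    """Sample variance divided by squared sample mean.

    The standard yardstick for likelihood-estimator quality: invariant
    to rescaling, so log-scale estimates may be shifted by any constant
    before exponentiation.  Requires at least two values and a nonzero
    mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean == 0.0:
        raise ValueError("mean of values is zero; relative variance undefined")
    return float(arr.var(ddof=1) / mean ** 2)
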