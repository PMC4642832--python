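# Methods

## The model

The duplication–mutation-with-complementarity (DMC) model grows an
undirected simple graph — a protein–protein interaction (PPI) network —
from a two-node connected seed `G_0`. One growth step `G_{t-1} → G_t`:

1. **Duplication.** An anchor `u_t` is drawn uniformly from
   `V(G_{t-1})`; a duplicate `v_t` is added and connected to every
   neighbor of `u_t`.
2. **Mutation.** For each neighbor `w` of the anchor, with probability
   `1 − p` one of the two parallel edges `(u_t, w)`, `(v_t, w)` is
   chosen uniformly and deleted; with probability `p` both survive.
   Neighbor choices are independent (the standard reading of the
   per-edge rule).
3. **Homodimerization.** Edge `(u_t, v_t)` is added with probability
   `p_c`.

The per-step transition probability therefore factorizes as

    p_M(G_t | G_{t-1}) = (1/|V(G_{t-1})|) · ∏_w m(w) · h,

with `m(w) = p` for a neighbor keeping both edges, `(1 − p)/2` for a
neighbor keeping exactly one, `0` otherwise, and `h = p_c` or
`1 − p_c` for the homodimer edge. The anchor factor `1/|V|` is kept
*inside* the kernel: over a whole history it contributes the
parameter-free constant `∏_t 1/(t+1)`, so posterior inference over
`(p, p_c)` is unaffected, while kernel values become directly
comparable to forward-simulation frequencies (which is how the kernel
is unit-tested).

Alongside the graph grows a **duplication forest**: two rooted binary
trees whose leaves are the graph's nodes. Each duplication replaces
the anchor's leaf by a cherry over `{u_t, v_t}`. Given the forest, a
growth step is invertible: a duplicate must be a cherry leaf, its
anchor is the cherry sibling, and merging their neighborhoods restores
the previous graph exactly. The likelihood of an observed pair is the
sum over all compatible duplicate sequences `θ = (v_1, …, v_n)` of the
product of step probabilities along the backward reconstruction.

## Inference machinery

**Exact enumeration** (`exact`) recurses over every backward
cherry-leaf choice, combining complete paths with log-sum-exp. It is
deliberately plain (no memoization) and capped at `n = 8` steps by
default — it exists as the ground-truth oracle for validating the
stochastic machinery, not as a production method. The grid posterior
evaluates the exact likelihood at the centers of a uniform grid over
the flat prior box.

**Sequential Monte Carlo** (`smc`) runs `n = |V| − 2` backward steps
with `N` particles. The proposal picks a cherry uniformly and then one
of its two leaves uniformly, so `q(v) = 1/(2·#cherries)`; the weight is
the forward step probability over `q`. Multinomial resampling is
applied between every pair of steps, exactly as the stated algorithm
prescribes (no ESS-triggered adaptation; a `systematic` option exists
but is not the default). The product over steps of the mean
unnormalized weight is the likelihood estimate; it is unbiased by the
standard normalizing-constant argument and is computed in log space
throughout (a 40-node pair underflows linear space). Every cherry-leaf
merge is forward-reachable with positive probability for parameters in
the open unit square, so no particle ever receives zero weight —
which is why the parameter container enforces strict bounds
`0 < p, p_c < 1`.

On pairs whose every backward step offers only mirror-symmetric
choices (e.g. the 3-node path with forest cherry{1,3} + leaf 2) all
particle weights coincide and the estimator is *exact* with zero
variance; this yields the package's sharpest regression fixture.

**PMMH** (`pmmh`) is random-walk Metropolis on `(p, p_c)` with the SMC
estimate standing in for the likelihood in the acceptance ratio — the
standard pseudo-marginal construction, which leaves the exact posterior
invariant. The proposal is a componentwise Gaussian reflected at the
prior-box boundary: reflection makes the kernel symmetric (verified
numerically by mirror-image summation) and confines the chain to the
box, so both proposal and flat prior cancel from the ratio. The
default proposal scale is 0.05, roughly half the posterior standard
deviation observed on 15-node recovery runs; larger scales (0.25–0.3)
mix faster on the very smooth small fixtures and are used there.
Initialization draws from the prior. Default priors are independent
uniforms on [0.1, 0.9].

Growth histories can be stored per iteration: after each filter run a
particle is selected proportionally to the final-step weights and its
duplicate sequence recorded. The selection draw is made whether or not
storage is enabled, so a chain's random stream does not depend on the
storage flag.

## Randomness and reproducibility

Every algorithm invocation accepts an integer seed or a numpy
`Generator`; a single stream drives proposals, resampling and
acceptance in a fixed (particle-order) sequence, so runs are
bit-reproducible. Cherry lists are canonically sorted by leaf ids for
the same reason. Experiment drivers derive child streams from the
master seed plus per-row counters (`default_rng([seed, counters...])`),
so any row of a study can be reproduced in isolation.

The simulator's id convention — seed nodes 1 and 2, step-`t` duplicate
labeled `t + 2` — makes simulated histories readable and reproducible.
One consequence worth knowing: the likelihood sums over *all*
compatible duplicate sequences, including reconstructions whose
two-node seed carries labels other than {1, 2}, whereas the simulator
realizes exactly one convention-consistent sequence per labeled pair.
The forward frequency of a labeled pair therefore equals the single
convention-consistent history's probability product and is strictly
dominated by the likelihood; the test suite asserts precisely this
identity.

## What the synthetic data does and does not cover

All inputs are produced by the package's own forward simulator, so
test data are exactly DMC-distributed and the duplication forest is
known without error. Real PPI data differ in ways deliberately out of
scope: forests would be *inferred* from sequence phylogenetics (with
topology uncertainty), real networks carry observation noise (spurious
and missing interactions), and real growth is not purely DMC
(gene loss, horizontal transfer, preferential attachment components).
Passing tests therefore demonstrate correctness of the inference
machinery under the model, not robustness to model misspecification.

Default generating conditions mirror the reference study: parameters
(0.7, 0.7), a 40-node trajectory for the variance study, a 15-node
pair for recovery, uniform [0.1, 0.9] priors, `N = 2000` particles and
10000 iterations as the `run_pmmh`/`recovery_experiment` defaults.

## Problem sizes used by the test suite and acceptance script

The package's own validation runs at desk scale, chosen so the whole
suite completes in minutes on one core while still exercising every
claimed behavior:

- unbiasedness: fixtures with `n ∈ {2, 3, 5}` backward steps, the
  3×3 parameter grid {0.3, 0.5, 0.7}², 500 runs of `N = 100`,
  asserted within 3 Monte-Carlo standard errors of the enumeration
  oracle;
- variance scaling: one trajectory to 20 nodes, multipliers {5, 20},
  20 replicates in the test (the acceptance script uses the reference
  50). Sample relative variances are heavy-tailed — a single
  weight-degenerate replicate can dominate a row — so the script
  summarizes the multiplier effect by the median over sizes of the
  per-size ratio rather than a mean across sizes;
- recovery: 15-node pair, `N = 200`, 3000 iterations, 20% burn-in,
  posterior means asserted within ±0.15 of the generating values;
- sampled-vs-exact posterior: the path fixture (where the estimate is
  exact and each iteration costs microseconds) with a 100000-iteration
  chain at proposal scale 0.25, compared to the 17×17 grid posterior
  at total variation < 0.05.

## Numerical choices and edge cases

- All probabilities in natural logs; per-step weight means via
  log-sum-exp; relative variances of log-scale estimates computed
  after subtracting the maximum (the statistic is scale-invariant).
- Impossible transitions (a neighbor losing both parallel edges, any
  edge change away from the duplicated pair) return `−inf` from the
  kernel — a probability-zero transition, not an error; malformed
  arguments (anchor not in the previous graph, wrong node sets) raise.
- Transition validity is decided by a single reconstruction check:
  merging the duplicate into the anchor must reproduce the previous
  graph exactly.
- The autocorrelation of a constant sequence is defined as 1 at lag 0
  and 0 elsewhere, with a warning.
- A backward reconstruction may terminate in a two-node seed with or
  without its edge; the seed term is taken as 1 either way (it carries
  no parameter information).
- File writes are atomic (temp file + rename); identical config and
  seed reproduce byte-identical outputs.

## Known limitations

- The enumeration oracle is exponential in `n`; beyond the cap the SMC
  estimate is the only likelihood access, and its own validation is
  necessarily statistical.
- The backward proposal is the naive uniform-cherry choice; for large
  graphs with small `N` the estimator's relative variance grows like
  `O(n/N)` and PMMH mixing degrades accordingly. Smarter proposals
  (and the discrete particle filter) are out of scope.
- The duplication forest is assumed observed and error-free; inferring
  it is delegated to phylogenetics.
- Only the two-node connected seed is supported end-to-end (forests
  must have exactly two trees); the containers accept general forests
  for forward compatibility.
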