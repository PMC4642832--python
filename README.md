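# dmcinfer

Bayesian inference for **duplication–mutation-with-complementarity
(DMC)** models of protein–protein interaction (PPI) network growth.

PPI networks grow mainly by gene duplication followed by divergence: a
duplicated protein initially shares all of its ancestor's interaction
partners, then loses some of them, and may bind its own ancestor
(homodimerization). The DMC model formalizes one growth step from
`G_{t-1}` to `G_t`: an anchor node `u_t` is duplicated, each copied
edge pair survives intact with probability `p` (the *mutation*
parameter) or loses one of its two edges uniformly at random, and the
anchor–duplicate edge appears with probability `p_c` (the
*homodimerization* parameter).

Given an observed network `G` **and** its duplication forest `Γ` (two
rooted binary trees over the proteins, one internal node per
duplication event — obtainable independently by phylogenetics), the
parameter posterior is

    π(p, p_c | G, Γ) ∝ p(p, p_c) · Σ_θ Π_t p_M(G_t, Γ_t | G_{t-1}, Γ_{t-1}),

where the sum runs over every duplicate sequence `θ = (v_1, …, v_n)`
compatible with the forest. The sum is intractable for all but tiny
networks, so the package provides:

- **a forward simulator** of DMC growth histories (`simulate_dmc`);
- **exact enumeration** of the likelihood for small pairs, as a
  validation oracle (`exact_log_likelihood`, `grid_posterior`);
- **a backward sequential Monte Carlo filter** over growth histories
  whose per-step mean weights multiply into an *unbiased* estimate of
  the likelihood (`run_smc`);
- **particle marginal Metropolis–Hastings (PMMH)**: random-walk
  Metropolis on `(p, p_c)` with the SMC estimate replacing the
  likelihood in the acceptance ratio, which targets the exact
  posterior (`run_pmmh`);
- experiment drivers reproducing the estimator-variance and
  parameter-recovery study designs (`variance_experiment`,
  `recovery_experiment`), and a CLI.

## Worked example

The 3-node path `1–2–3` with forest `{cherry(1,3), leaf 2}` has
exactly two compatible histories, mirror images of each other, each
with probability `½ · p · (1 − p_c)`. At `p = p_c = 0.7` the
likelihood is `0.21`, and because the two backward choices carry
identical weight the particle filter reproduces it *exactly*:

```python
from dmcinfer import (DMCParams, DuplicationForest, PPIGraph,
                      exact_log_likelihood, run_smc, run_pmmh)

graph  = PPIGraph(edges=[(1, 2), (2, 3)])
forest = DuplicationForest([(1, 3), 2])   # a leaf is an int, a node a pair
params = DMCParams(p=0.7, p_c=0.7)

print("exact :", exact_log_likelihood(graph, forest, params))
print("smc   :", run_smc(graph, forest, params, n_particles=100,
                         seed=0).log_likelihood)

chain = run_pmmh(graph, forest, n_particles=2, n_iterations=20000,
                 proposal_scale=0.25, seed=0)
s = chain.posterior_samples(burn_in=0.2)
print("posterior mean p   :", round(s[:, 0].mean(), 3))
print("posterior mean p_c :", round(s[:, 1].mean(), 3))
print("acceptance rate    :", round(chain.acceptance_rate, 3))
```

prints

```
exact : -1.5606477482646683
smc   : -1.5606477482646683
posterior mean p   : 0.608
posterior mean p_c : 0.395
acceptance rate    : 0.768
```

`exp(-1.5606…) = 0.21` is the likelihood above. The posterior means
reflect what one short path can tell you: the single kept edge pair
pulls `p` up, the absent homodimer edge pulls `p_c` down, both
moderated by the uniform [0.1, 0.9] prior.

The same workflow from the shell, on simulated data:

```sh
dmcinfer simulate --size 15 --p 0.7 --pc 0.7 --seed 1 --out-dir sim
dmcinfer smc --graph sim/graph.tsv --forest sim/forest.nwk \
             --p 0.7 --pc 0.7 -N 1000 --seed 2
# -33.93948319        <- log-likelihood estimate at the true parameters
dmcinfer pmmh --graph sim/graph.tsv --forest sim/forest.nwk \
              -N 500 --iterations 5000 --seed 3 --out-dir posterior
```

Graphs travel as two-column TSV edge lists, forests as Newick (one
rooted tree per line, integer leaf labels), chains as CSV with a JSON
metadata sidecar.

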