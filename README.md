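# iwesse

Phylogenetic inference of CpG methylation dynamics with island-wide events
(the IWE-SSE model).

## The problem

Methylation states of CpG sites change along cell-type genealogies, and
branch lengths of such genealogies — expected numbers of methylation events
per CpG — are a natural measure of epigenetic divergence between cell types.
Standard phylogenetic treatments assume sites evolve independently, but CpG
sites cluster into CpG islands, and a single regulatory event can remethylate
or demethylate an entire island at once. Ignoring this dependence inflates
branch-length estimates wherever island-wide changes occur.

`iwesse` is for researchers analysing categorized methylomes (e.g. RRBS
data thresholded into unmethylated / partially methylated / methylated
states) across a known tree of cell types who want branch lengths and
island-wide-event histories inferred jointly.

## The model

Each CpG site takes a state in {u, p, m}. Within an island with equilibrium
frequencies π = (π_u, π_p, π_m), single-site events (SSEs) occur at rate R
per site and redraw the site's state from π (possibly silently), an F81-type
process with rate matrix off-diagonals Q_ij = R·π_j and closed-form
transition probabilities

    P_ij(t) = (1 − e^{−Rt}) π_j   (i ≠ j),
    P_ii(t) = π_i + (1 − π_i) e^{−Rt}.

R follows an invariant+gamma mixture: R = 0 with probability r, else one of
three discretized-gamma categories (shape α, mean 1). Island-wide events
(IWEs) hit each island as a Poisson process of rate μ per island per SSE
time unit; an IWE replaces π by a fresh Dirichlet(1,1,1) draw π′ and moves
every site by a minimal-motion stochastic matrix M with π·M = π′, so state
frequencies match the new equilibrium immediately. The likelihood of
observed states is computed by Felsenstein pruning with the IWE transition
matrices interleaved within branches, and a reversible-jump MCMC sampler
explores IWE configurations, island frequencies, branch lengths B and the
global parameters θ = (r, α, μ). A null model with μ = 0 (island-specific
but constant frequencies) is included for comparison.

See `docs/methods.md` for priors, proposal mechanics and numerical details.

## Worked example

Simulate a dataset from the model and re-infer its parameters:

```python
import numpy as np
from iwesse import SimulationDesign, simulate_dataset, run_mcmc, credibility_interval
from iwesse.model_core import GlobalParams

design = SimulationDesign(n_islands=20, site_range=(10, 100),
                          theta=GlobalParams(r=0.3, alpha=1.0, mu=1.5),
                          branch_lengths=(0.4, 0.2, 0.3, 0.5, 0.25, 0.35))
ds = simulate_dataset(design, np.random.default_rng(7))
print("true IWE total:", ds.truth.total_iwe_count())

trace = run_mcmc(ds.tree, ds.data, n_sweeps=20_000, burn_in=10_000, seed=1)
print("posterior mean mu: %.2f" % trace.mu.mean())
print("95% CI for mu:", tuple(round(x, 2) for x in credibility_interval(trace.mu)))
print("posterior mean IWE total: %.1f" % trace.total_iwe_counts.mean())
print("branch lengths:", np.round(trace.branch_lengths.mean(axis=0), 2))
```

prints

```
true IWE total: 70
posterior mean mu: 1.53
95% CI for mu: (1.03, 2.34)
posterior mean IWE total: 71.7
branch lengths: [0.48 0.27 0.38 0.58 0.34 0.36]
```

The simulated dataset carried 70 island-wide events; from the methylation
states alone the sampler recovers the IWE rate (truth 1.5, interval
1.03–2.34), the event count (71.7 vs 70) and the six branch lengths (truth
0.4, 0.2, 0.3, 0.5, 0.25, 0.35; posterior means a touch higher after this
short 20,000-sweep run).

The same workflow is available from the shell:

```bash
iwesse simulate --seed 7 --out sim/
iwesse infer --tree sim/tree.nwk --states sim/states.tsv \
             --model iwe-sse --steps 20000 --burn-in 10000 --seed 1 --out run/
iwesse distances --states sim/states.tsv sim/states.tsv --node A
```

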