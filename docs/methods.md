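# Methods

## The model

`iwesse` models the evolution of CpG methylation states on a rooted cell-type
tree. Each CpG site is in one of three states — unmethylated (`u`), partially
methylated (`p`), methylated (`m`) — and sites are grouped into CpG islands
that evolve independently of one another.

**Single-site events (SSEs).** Within an island, between island-wide events,
each site evolves independently by a three-state process of F81 type: at rate
`R` the site redraws its state from the island's current equilibrium triple
`(pi_u, pi_p, pi_m)`. The redraw may reproduce the current state (a *silent*
event); the expected silent fraction is `pi_u^2 + pi_p^2 + pi_m^2 >= 1/3`,
with equality at the simplex center. Transition probabilities over an
interval of length `t` have the closed form `P_ij = (1 - e^{-Rt}) pi_j`
(off-diagonal) and `P_ii = pi_i + (1 - pi_i) e^{-Rt}`, which equals
`expm(Q t)` for the redraw rate matrix `Q`.

**Rate heterogeneity.** The per-site rate factor `R` follows an
invariant+gamma mixture: `R = 0` with probability `r`, otherwise one of three
discretized-gamma categories with shape `alpha` and mean 1, each with
conditional probability 1/3. Discretization uses equal-probability slice
*means* (not medians), renormalized so the category mean is exactly 1 — means
preserve the unit expectation exactly, which the medians would not. A site
keeps its category across the whole tree; the likelihood mixes over the four
categories once per site, outside the tree recursion.

Note that the overall mean rate is `E[R] = 1 - r`, not 1: the invariant
fraction removes rate mass that the gamma part does not compensate. Branch
lengths are reported in *SSE units* — for the non-invariant sites, one unit
is one expected SSE per CpG; a site with invariant fraction `r` experiences
`(1-r) l` expected events on a branch of length `l`. The event-count identity
`l = E[S+W] / (n mu + sum_i n_i)` (with `S` all SSEs including silent ones
and `W` all island-wide events on the branch) is therefore exact at `r = 0`,
and that is the setting in which the simulator's event mode verifies it.

**Island-wide events (IWEs).** Each island is hit by a Poisson process of
rate `mu` per SSE time unit. An IWE draws a fresh equilibrium triple
`pi'` from Dirichlet(1,1,1) — the same distribution that assigns islands
their root triples — and simultaneously moves every site of the island by a
minimal-motion stochastic matrix `M`: states whose frequency decreases keep
their state with probability `pi'_s / pi_s` and move to frequency-gaining
states with the complementary mass split proportionally to the gains; states
whose frequency does not decrease stay put. This yields `pi M = pi'`, so the
expected state frequencies match the new equilibrium immediately after the
event. States with unchanged frequency get an identity row, which makes the
two case formulas (one state gains / one state loses) coincide — the tie case
has measure zero under Dirichlet draws but needs a defined behaviour; the
identity row is the continuity limit of both cases. Triple components are
floored at 1e-12 before division; exact zeros raise an error, since they
cannot arise from the samplers and signal a caller bug.

## Likelihood

Conditioned on an island's IWE configuration (event positions and triples on
every branch, plus the root triple), the island's sites are independent and
each site's probability is computed by Felsenstein pruning with the IWE
matrices interleaved on branches: across a branch carrying events at offsets
`t_1 < ... < t_h`, the transition matrix is `P_0 M_1 P_1 ... M_h P_h`, where
each `P_k` uses the triple in force on its segment. Partial likelihood
vectors carry an explicit log-scale factor and are rescaled at every node, so
deep trees do not underflow (verified on a 321-branch path whose site
probabilities are ~1e-650). Tips contribute indicator vectors; missing
states contribute all-ones vectors (standard ambiguity handling — the choice
matters only for data read from files, the simulator never produces missing
states at observed nodes); observed internal nodes mask the product of their
children's vectors to the observed state; an unobserved root is summed over
with the island's root triple as weights.

Two implementations compute this likelihood: a vectorized numpy reference
(`iwesse.likelihood`) and a numba kernel used by the sampler
(`iwesse._kernel`). The test suite holds them together to 1e-9 and checks
both against exhaustive enumeration over hidden node states, within-branch
IWE states and rate categories on small trees.

## MCMC

The sampler is a reversible-jump Metropolis-Hastings scheme over IWE
configurations, island triples, log branch lengths and the global parameters
`theta = (r, alpha, mu)`.

* **Birth/death of IWEs.** A birth picks a branch uniformly, a position
  uniformly on it, and a triple from Dirichlet(1,1,1); a death picks a branch
  uniformly and one of its events uniformly. Under exactly this pairing the
  proposal terms cancel against the Poisson-process and Dirichlet priors and
  the acceptance ratio reduces to `LR * mu l / (n+1)` for a birth onto a
  branch holding `n` events, and its reciprocal for a death. The uncapped
  birth and death ratios are exact reciprocals (tested).
* **Island frequencies.** The root triple or one event triple is redrawn
  from Dirichlet(1,1,1); since proposal and prior coincide, the acceptance
  probability is the bare likelihood ratio (1 for a re-proposal of the same
  triple).
* **Branch lengths.** A symmetric two-component Gaussian mixture walk on the
  log length (scales 0.1 and 1.0 with weights 0.9/0.1: small steps for
  mixing, occasional large jumps). Event offsets on the branch rescale
  proportionally; the `(l'/l)^n` acceptance factor is exactly the density
  ratio of the rescaled Poisson process. The null model (`mu = 0`, no IWEs)
  drops the event terms.
* **Globals.** `r` moves by a reflected uniform walk on [0,1] (uniform
  prior); `log alpha` and `log mu` by Gaussian walks. The `mu` update needs
  no likelihood: its conditional is the prior times
  `mu^{n_tot} e^{-mu N L_tot}`. Both conditionals are verified against 1-D
  quadrature in the tests.

**Schedule.** One sweep = per island one birth/death attempt and one
frequency update, then one update per branch length and one per global
parameter. Burn-in and thinning are counted in sweeps (each sweep is many
elementary Metropolis-Hastings steps). Chains start with zero IWEs and all
parameters at their prior means; runs are bit-reproducible given a seed.

**Priors (defaults).** log branch length ~ Normal(-2, 2) (the lognormal with
sigma 2 used for simulated branch lengths), log alpha ~ Normal(0, 1),
r ~ Uniform(0, 1), log mu ~ Normal(0, 1), triples ~ Dirichlet(1,1,1). The
log-mu scale of 1 was chosen because a lognormal(0, 2) IWE rate has mean
`e^2 ~ 7.4` with a very heavy tail, implying simulated datasets routinely
dominated by dozens of island-wide events per island — an intensity we do
not consider biologically plausible for island-level regulatory events; the
unit scale keeps the rate within roughly [0.05, 20] while remaining weakly
informative. All hyperparameters are configurable.

**Engines.** Every move exists twice: as a readable Python function over an
`MCMCState` (the unit-testing surface, `engine="python"`) and inside a numba
sweep kernel (`engine="numba"`, default). The kernel stores configurations
in fixed-capacity arrays that grow on demand, compresses each island's data
to unique site patterns with multiplicities, and caches per-branch
per-category pattern factors for islands whose nodes are all observed so
that branch-length moves and event updates that do not change the
downstream equilibrium recompose a single branch. Cached island
log-likelihoods are exact, not approximations: the Python engine re-verifies
them against full recomputation at the end of every run, and the kernel's
factorized fast path is tested against the numpy pruning reference.

## Simulator

`simulate_dataset` draws all parameters from the priors (or accepts fixed
values), places IWEs as a Poisson process with Dirichlet triples, draws root
states from island root triples and propagates states root-to-tips. Matrix
mode samples child states from the composed branch transition matrices;
event mode simulates the SSE point process per site (exponential waiting
times, state redrawn from the current triple at every event, silent events
counted) and applies each IWE matrix site by site, logging per-branch event
counts. The two modes agree in distribution (chi-square tested). All
randomness flows from one seeded generator; identical seeds give identical
datasets.

What the simulator emulates is the model itself — it generates perfectly
model-faithful data with states known at every node. It does not emulate
read sampling, coverage-dependent missingness, island-boundary uncertainty
or neighbor-dependent methylation dynamics, so passing calibration tests
demonstrates correctness of the inference machinery, not robustness of the
model on real bisulfite data.

## Calibration study (reduced design)

The calibration ("coverage") study simulates replicates with parameters
drawn from the priors and checks that 95% equal-tailed credibility intervals
cover the generating values at the nominal rate. The package's reduced
design uses 30 replicates on a balanced 4-tip tree (6 branches) with 20
islands of 10-100 sites, inferred with 20,000 burn-in plus 20,000 sampling
sweeps thinned to every 10th — problem sizes chosen so the full study runs
in minutes on a single core while the binomial uncertainty at 30 replicates
remains wide enough for a meaningful equivalence check against the nominal
level. A larger design (more replicates, 100 islands of 10-400 sites) only
tightens the same comparison.

## Null-model IWE test

To ask whether data require island-wide events at all, datasets are
simulated under the fitted null model (`mu = 0`, island-specific constant
triples) and re-inferred with the full model; the summary is the posterior
total IWE count and the largest per-edge percentage of islands carrying an
event (posterior mean of the per-sample fraction). On null data these stay
near zero; a positive control with a high IWE rate is detected with large
counts. The desk-scale configuration uses 50 islands and 5 replicates.

## Numerical choices and limitations

* Incomplete-gamma functions (series/continued-fraction, Halley-refined
  inverse) are implemented in numba for use inside the sweep kernel and
  match scipy to ~1e-10 over shapes 1e-3..1e4.
* Equal-tailed intervals use `numpy.quantile` (linear interpolation);
  level 1 returns the sample range.
* Per-branch IWE-rate intervals use log(count/length) with a +0.5
  continuity correction for zero-count samples (flagged when a branch is
  zero throughout) and Bonferroni adjustment across branches.
* RRBS fractions categorize as `u` below 0.1, `m` above 0.8, `p` on the
  closed interval [0.1, 0.8] (boundaries read as inclusive for the partial
  class); island-level classification requires a strict majority of sites.
* Island mean-methylation distances encode u/p/m as 0/0.5/1, the natural
  ordinal midpoint scheme.
* The proportional-regression fit of branch lengths on time differences
  reports the no-intercept (uncentered) adjusted R-squared, the convention
  of standard linear-model summaries.
* Mixing of the IWE dimension is slow when expected event counts are large
  (counts change by at most one per island per sweep); prior-only validation
  runs therefore use long, heavily thinned chains. Chains on data with many
  hundreds of true events need correspondingly long burn-in.
* Topology search, neighbor-dependent (Ising) site interactions, per-branch
  IWE rates and general reversible 3x3 rate matrices are out of scope.
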