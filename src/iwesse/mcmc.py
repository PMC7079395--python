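"""Reversible-jump Metropolis-Hastings sampler for the IWE-SSE model.

The sampler explores IWE configurations (birth/death of events with
Dirichlet-prior triples and uniform positions), island equilibrium triples,
log branch lengths, and the global parameters (r, alpha, mu).  The null
model fixes mu = 0 and carries no IWEs, leaving island-specific but
time-constant equilibrium triples.

One *sweep* consists of, per island, one IWE birth/death attempt and one
frequency update, then one update per branch length and one per global
parameter; burn-in and thinning are counted in sweeps.

Two engines produce the same posterior: a readable Python implementation of
every move (exposed as functions below, used by the unit tests) and a numba
kernel (:mod:`iwesse._kernel`, the default) fast enough for simulation
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import _kernel
from .likelihood import (
    IslandConfig,
    IWEvent,
    MethylationData,
    island_log_likelihood,
    island_site_log_likelihoods,
)
from .model_core import GlobalParams, discretize_gamma
from .tree import Tree

__all__ = [
    "Priors",
    "ProposalConfig",
    "MCMCState",
    "Trace",
    "run_mcmc",
    "credibility_interval",
    "iwe_birth_acceptance",
    "iwe_death_acceptance",
    "branch_length_acceptance",
    "null_branch_length_acceptance",
    "propose_iwe_birth",
    "iwe_birth_death_move",
    "update_island_frequencies",
    "update_branch_length",
    "update_global_params",
]


# ---------------------------------------------------------------------------
# Priors and proposals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters.

    Log branch lengths, log gamma shape and log IWE rate carry normal priors
    (location, scale); the invariant fraction ``r`` is uniform on [0, 1];
    island root triples and IWE triples are Dirichlet(1,1,1); IWE positions
    form a Poisson process of intensity ``mu`` per island.
    """

    log_length: tuple = (-2.0, 2.0)
    log_alpha: tuple = (0.0, 1.0)
    log_mu: tuple = (0.0, 1.0)

    def __post_init__(self):
        for name in ("log_length", "log_alpha", "log_mu"):
            loc, scale = getattr(self, name)
            if not scale > 0:
                raise ValueError(f"{name} prior scale must be positive, got {scale}")

    @staticmethod
    def _normal_logpdf(x, loc, scale):
        return -0.5 * ((x - loc) / scale) ** 2 - math.log(scale) - 0.5 * math.log(2 * math.pi)

    def log_length_logpdf(self, ell: float) -> float:
        return self._normal_logpdf(ell, *self.log_length)

    def log_alpha_logpdf(self, la: float) -> float:
        return self._normal_logpdf(la, *self.log_alpha)

    def log_mu_logpdf(self, lm: float) -> float:
        return self._normal_logpdf(lm, *self.log_mu)

    def sample_global_params(self, rng: np.random.Generator) -> GlobalParams:
        return GlobalParams(
            r=rng.uniform(),
            alpha=float(np.exp(rng.normal(*self.log_alpha))),
            mu=float(np.exp(rng.normal(*self.log_mu))),
        )

    def sample_branch_lengths(self, rng: np.random.Generator, n_branches: int) -> np.ndarray:
        return np.exp(rng.normal(self.log_length[0], self.log_length[1], size=n_branches))

    def mean_state(self, tree: Tree) -> tuple:
        """Prior-mean starting point: log-params at prior locations, r at 1/2."""
        theta = GlobalParams(
            r=0.5,
            alpha=float(np.exp(self.log_alpha[0])),
            mu=float(np.exp(self.log_mu[0])),
        )
        lengths = np.full(tree.n_branches, float(np.exp(self.log_length[0])))
        return theta, lengths


@dataclass(frozen=True)
class ProposalConfig:
    """Step sizes and move switches.

    The log-length proposal is a symmetric two-component Gaussian mixture
    (small steps for mixing, occasional large jumps).  New IWE triples come
    from the Dirichlet(1,1,1) prior and positions are uniform on the branch,
    which makes the printed birth/death Hastings ratio exact.
    """

    length_scales: tuple = (0.1, 1.0)
    length_weights: tuple = (0.9, 0.1)
    r_step: float = 0.15
    alpha_step: float = 0.4
    mu_step: float = 0.4
    update_iwe: bool = True
    update_frequencies: bool = True
    update_lengths: bool = True
    update_r: bool = True
    update_alpha: bool = True
    update_mu: bool = True

    def __post_init__(self):
        if abs(sum(self.length_weights) - 1.0) > 1e-12 or len(self.length_weights) != 2:
            raise ValueError("length_weights must be two weights summing to 1")

    def draw_log_length_step(self, rng: np.random.Generator) -> float:
        scale = self.length_scales[0] if rng.uniform() < self.length_weights[0] else self.length_scales[1]
        return float(rng.normal(0.0, scale))


# ---------------------------------------------------------------------------
# Acceptance probabilities (the printed reversible-jump ratios)
# ---------------------------------------------------------------------------

def iwe_birth_log_ratio(loglik_new: float, loglik_old: float, mu: float, l: float, n: int) -> float:
    """Uncapped log Metropolis-Hastings ratio of a birth move: LR * mu*l/(n+1)."""
    if mu * l <= 0.0:
        return -np.inf
    return (loglik_new - loglik_old) + math.log(mu * l) - math.log(n + 1.0)


def iwe_death_log_ratio(loglik_new: float, loglik_old: float, mu: float, l: float, n_current: int) -> float:
    """Uncapped log ratio of a death move from ``n_current`` IWEs: LR * n/(mu*l)."""
    if n_current < 1:
        raise ValueError("death move requires at least one IWE on the branch")
    if mu * l <= 0.0:
        return np.inf
    return (loglik_new - loglik_old) + math.log(float(n_current)) - math.log(mu * l)


def iwe_birth_acceptance(loglik_new: float, loglik_old: float, mu: float, l: float, n: int) -> float:
    """min(1, LR * mu*l / (n+1)) for adding an IWE to a branch holding n of them."""
    ratio = iwe_birth_log_ratio(loglik_new, loglik_old, mu, l, n)
    return 0.0 if ratio == -np.inf else math.exp(min(0.0, ratio))


def iwe_death_acceptance(loglik_new: float, loglik_old: float, mu: float, l: float, n_current: int) -> float:
    """min(1, LR * n/(mu*l)) for removing one of ``n_current`` IWEs; inverse of the birth ratio."""
    ratio = iwe_death_log_ratio(loglik_new, loglik_old, mu, l, n_current)
    return 1.0 if ratio == np.inf else math.exp(min(0.0, ratio))


def branch_length_acceptance(
    loglik_new: float,
    loglik_old: float,
    l_new: float,
    l_old: float,
    n: int,
    mu: float,
    N: int,
    prior: Priors,
) -> float:
    """min(1, LR * (l'/l)^n * exp(-mu N (l'-l)) * p(l')/p(l)) on the log scale.

    ``n`` counts IWEs of all islands on the branch; the (l'/l)^n factor is
    the density ratio of proportionally rescaled event positions.
    """
    if l_new <= 0.0:
        return 0.0
    ell_new, ell_old = math.log(l_new), math.log(l_old)
    log_ratio = (
        (loglik_new - loglik_old)
        + n * (ell_new - ell_old)
        - mu * N * (l_new - l_old)
        + prior.log_length_logpdf(ell_new)
        - prior.log_length_logpdf(ell_old)
    )
    return math.exp(min(0.0, log_ratio))


def null_branch_length_acceptance(
    loglik_new: float, loglik_old: float, log_prior_new: float, log_prior_old: float
) -> float:
    """min(1, LR * p(l')/p(l)): the length acceptance without IWE terms."""
    log_ratio = (loglik_new - loglik_old) + log_prior_new - log_prior_old
    return math.exp(min(0.0, log_ratio))


def credibility_interval(values, level: float = 0.95) -> tuple:
    """Equal-tailed quantile interval of posterior samples."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a credibility interval from an empty trace")
    if values.size < 2:
        raise ValueError("need at least two samples")
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must lie in (0, 1], got {level}")
    if level == 1.0:
        return float(values.min()), float(values.max())
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [a, 1.0 - a])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Sampler state and Python-engine moves
# ---------------------------------------------------------------------------

@dataclass
class MCMCState:
    """Full sampler state: theta, branch lengths, IWE configs, cached log-likelihoods."""

    tree: Tree
    data: MethylationData
    theta: GlobalParams
    configs: list
    priors: Priors = field(default_factory=Priors)
    proposals: ProposalConfig = field(default_factory=ProposalConfig)
    mode: str = "iwe-sse"
    likelihood_on: bool = True
    island_ll: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mode not in ("iwe-sse", "null"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "null":
            if any(c.n_events() for c in self.configs):
                raise ValueError("null model carries no IWEs")
            self.theta = GlobalParams(self.theta.r, self.theta.alpha, 0.0)
        if self.island_ll is None:
            self.refresh_cache()

    def island_loglik(self, i: int, configs=None, theta=None, tree=None) -> float:
        if not self.likelihood_on:
            return 0.0
        configs = self.configs if configs is None else configs
        return island_log_likelihood(
            self.data.island_states(i),
            configs[i] if isinstance(configs, list) else configs,
            tree or self.tree,
            theta or self.theta,
        )

    def refresh_cache(self) -> None:
        self.island_ll = np.asarray(
            [self.island_loglik(i) for i in range(self.data.n_islands)]
        )

    def total_loglik(self) -> float:
        return float(self.island_ll.sum())

    def check_cache(self, atol: float = 1e-9) -> None:
        fresh = np.asarray([self.island_loglik(i) for i in range(self.data.n_islands)])
        if not np.allclose(fresh, self.island_ll, atol=atol, rtol=0):
            raise AssertionError("cached island log-likelihoods drifted from full recomputation")

    def iwe_counts_by_branch(self) -> np.ndarray:
        counts = np.zeros(self.tree.n_branches, dtype=np.int64)
        for c in self.configs:
            counts += c.counts_by_branch(self.tree)
        return counts


def propose_iwe_birth(state: MCMCState, island: int, rng: np.random.Generator):
    """Propose one extra IWE: uniform branch, uniform position, Dirichlet triple.

    Returns ``(proposed_config, branch_node)``.
    """
    b = int(state.tree.branch_nodes[rng.integers(state.tree.n_branches)])
    l = float(state.tree.lengths[b])
    pos = float(rng.uniform(0.0, l))
    triple = rng.dirichlet(np.ones(3))
    config = state.configs[island].copy()
    evs = config.events.setdefault(b, [])
    k = sum(1 for e in evs if e.position < pos)
    evs.insert(k, IWEvent(pos, triple))
    return config, b


def iwe_birth_death_move(state: MCMCState, island: int, rng: np.random.Generator) -> bool:
    """One reversible-jump birth/death attempt on a random branch of one island."""
    mu = state.theta.mu
    if rng.uniform() < 0.5:
        config, b = propose_iwe_birth(state, island, rng)
        l = float(state.tree.lengths[b])
        n = len(state.configs[island].events_on(b))
        if mu * l <= 0.0:
            return False
        ll_new = state.island_loglik(island, configs=config)
        acc = iwe_birth_acceptance(ll_new, state.island_ll[island], mu, l, n)
    else:
        b = int(state.tree.branch_nodes[rng.integers(state.tree.n_branches)])
        evs = state.configs[island].events_on(b)
        n = len(evs)
        if n == 0:
            return False
        k = int(rng.integers(n))
        config = state.configs[island].copy()
        del config.events[b][k]
        l = float(state.tree.lengths[b])
        ll_new = state.island_loglik(island, configs=config)
        acc = iwe_death_acceptance(ll_new, state.island_ll[island], mu, l, n)
    if rng.uniform() < acc:
        state.configs[island] = config
        state.island_ll[island] = ll_new
        return True
    return False


def update_island_frequencies(state: MCMCState, island: int, rng: np.random.Generator) -> bool:
    """MH update of the island's root triple or one IWE triple.

    The proposal is an independent Dirichlet(1,1,1) redraw — identical to the
    prior, so the acceptance probability is just the likelihood ratio (and 1
    for a re-proposal of the same triple).
    """
    config = state.configs[island].copy()
    slots = [None] + [
        (b, k) for b in state.tree.branch_nodes for k in range(len(config.events_on(int(b))))
    ]
    pick = slots[int(rng.integers(len(slots)))]
    triple = rng.dirichlet(np.ones(3))
    if pick is None:
        config.root_triple = triple
    else:
        b, k = pick
        config.events[int(b)][k] = IWEvent(config.events[int(b)][k].position, triple)
    ll_new = state.island_loglik(island, configs=config)
    if math.log(rng.uniform() + 1e-320) < ll_new - state.island_ll[island]:
        state.configs[island] = config
        state.island_ll[island] = ll_new
        return True
    return False


def update_branch_length(state: MCMCState, branch_node: int, rng: np.random.Generator) -> bool:
    """Symmetric Gaussian-mixture walk on the log length; IWE offsets rescale."""
    b = int(branch_node)
    l = float(state.tree.lengths[b])
    ell2 = math.log(l) + state.proposals.draw_log_length_step(rng)
    l2 = math.exp(ell2)
    new_tree = state.tree.with_lengths(
        np.where(state.tree.branch_nodes == b, l2, state.tree.lengths[state.tree.branch_nodes])
    )
    ratio = l2 / l
    new_configs = []
    n_tot = 0
    for c in state.configs:
        n_tot += len(c.events_on(b))
        cc = c.copy()
        if b in cc.events:
            cc.events[b] = [IWEvent(e.position * ratio, e.triple) for e in cc.events[b]]
        new_configs.append(cc)
    ll_new = np.asarray(
        [
            state.island_loglik(i, configs=new_configs, tree=new_tree)
            for i in range(state.data.n_islands)
        ]
    )
    if state.mode == "null":
        acc = null_branch_length_acceptance(
            float(ll_new.sum()),
            state.total_loglik(),
            state.priors.log_length_logpdf(ell2),
            state.priors.log_length_logpdf(math.log(l)),
        )
    else:
        acc = branch_length_acceptance(
            float(ll_new.sum()),
            state.total_loglik(),
            l2,
            l,
            n_tot,
            state.theta.mu,
            state.data.n_islands,
            state.priors,
        )
    if rng.uniform() < acc:
        state.tree = new_tree
        state.configs = new_configs
        state.island_ll = ll_new
        return True
    return False


def update_global_params(state: MCMCState, rng: np.random.Generator) -> None:
    """MH updates of r (reflected uniform walk), log-alpha and log-mu (Gaussian walks).

    The mu update involves no likelihood: its conditional posterior is the
    prior times the Poisson-process factor mu^n_tot * exp(-mu N L_tot).
    """
    p = state.proposals
    # r
    if p.update_r:
        r2 = state.theta.r + rng.uniform(-p.r_step, p.r_step)
        while r2 < 0.0 or r2 > 1.0:
            r2 = -r2 if r2 < 0.0 else 2.0 - r2
        theta2 = GlobalParams(r2, state.theta.alpha, state.theta.mu)
        ll_new = np.asarray(
            [state.island_loglik(i, theta=theta2) for i in range(state.data.n_islands)]
        )
        if math.log(rng.uniform() + 1e-320) < ll_new.sum() - state.total_loglik():
            state.theta = theta2
            state.island_ll = ll_new
    # alpha
    if p.update_alpha:
        la = math.log(state.theta.alpha)
        la2 = la + rng.normal(0.0, p.alpha_step)
        theta2 = GlobalParams(state.theta.r, math.exp(la2), state.theta.mu)
        ll_new = np.asarray(
            [state.island_loglik(i, theta=theta2) for i in range(state.data.n_islands)]
        )
        log_acc = (
            ll_new.sum()
            - state.total_loglik()
            + state.priors.log_alpha_logpdf(la2)
            - state.priors.log_alpha_logpdf(la)
        )
        if math.log(rng.uniform() + 1e-320) < log_acc:
            state.theta = theta2
            state.island_ll = ll_new
    # mu
    if p.update_mu and state.mode != "null":
        lm = math.log(state.theta.mu)
        lm2 = lm + rng.normal(0.0, p.mu_step)
        mu2 = math.exp(lm2)
        n_tot = int(sum(c.n_events() for c in state.configs))
        L_tot = state.tree.total_length
        N = state.data.n_islands
        log_acc = (
            n_tot * (lm2 - lm)
            - N * L_tot * (mu2 - state.theta.mu)
            + state.priors.log_mu_logpdf(lm2)
            - state.priors.log_mu_logpdf(lm)
        )
        if math.log(rng.uniform() + 1e-320) < log_acc:
            state.theta = GlobalParams(state.theta.r, state.theta.alpha, mu2)


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Thinned MCMC trace: scalar parameters and per-branch summaries."""

    step: np.ndarray
    loglik: np.ndarray
    r: np.ndarray
    alpha: np.ndarray
    mu: np.ndarray
    branch_lengths: np.ndarray  # (n_rec, n_branches)
    iwe_counts: np.ndarray  # (n_rec, n_branches) totals across islands
    islands_with_iwe: np.ndarray  # (n_rec, n_branches)
    branch_names: list
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.step)

    @property
    def total_iwe_counts(self) -> np.ndarray:
        return self.iwe_counts.sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "step": self.step,
            "loglik": self.loglik,
            "r": self.r,
            "alpha": self.alpha,
            "mu": self.mu,
        }
        for j, name in enumerate(self.branch_names):
            cols[f"log_length.{name}"] = np.log(self.branch_lengths[:, j])
        for j, name in enumerate(self.branch_names):
            cols[f"iwe_count.{name}"] = self.iwe_counts[:, j]
        for j, name in enumerate(self.branch_names):
            cols[f"islands_with_iwe.{name}"] = self.islands_with_iwe[:, j]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _initial_state(tree, data, priors, proposals, mode, likelihood_on, init, rng):
    if init is not None:
        return init
    theta, lengths = priors.mean_state(tree)
    if mode == "null":
        theta = GlobalParams(theta.r, theta.alpha, 0.0)
    start_tree = tree.with_lengths(lengths)
    configs = [
        IslandConfig(np.full(3, 1.0 / 3.0), {}) for _ in range(data.n_islands)
    ]
    return MCMCState(
        tree=start_tree,
        data=data,
        theta=theta,
        configs=configs,
        priors=priors,
        proposals=proposals,
        mode=mode,
        likelihood_on=likelihood_on,
    )


def _diagnose_nonfinite(state):
    for i in range(state.data.n_islands):
        if not np.isfinite(state.island_ll[i]):
            site_ll = island_site_log_likelihoods(
                state.tree, state.data.island_states(i), state.configs[i], state.theta
            )
            bad = np.flatnonzero(~np.isfinite(site_ll))
            name = (
                state.data.island_names[i]
                if state.data.island_names is not None
                else str(i)
            )
            raise ValueError(
                f"non-finite initial log-likelihood in island {name} "
                f"(sites {bad.tolist()}); data impossible under the initial configuration"
            )


def run_mcmc(
    tree: Tree,
    data: MethylationData,
    *,
    n_sweeps: int,
    burn_in: int,
    thin: int = 10,
    mode: str = "iwe-sse",
    priors: Optional[Priors] = None,
    proposals: Optional[ProposalConfig] = None,
    seed: int = 0,
    engine: str = "numba",
    init: Optional[MCMCState] = None,
    likelihood_on: bool = True,
) -> Trace:
    """Run the sampler and return the thinned trace.

    The initial state has zero IWEs and parameters at their prior means
    unless ``init`` is given.  The run is deterministic given ``seed``.
    ``likelihood_on=False`` forces the likelihood to 1 (prior sampling).
    """
    if mode not in ("iwe-sse", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    if burn_in < 0 or n_sweeps <= burn_in:
        raise ValueError("need n_sweeps > burn_in >= 0")
    priors = priors or Priors()
    proposals = proposals or ProposalConfig()
    rng = np.random.default_rng(seed)
    state = _initial_state(tree, data, priors, proposals, mode, likelihood_on, init, rng)
    _diagnose_nonfinite(state)
    meta = {
        "seed": seed,
        "mode": mode,
        "engine": engine,
        "n_sweeps": n_sweeps,
        "burn_in": burn_in,
        "thin": thin,
        "priors": asdict(priors),
        "proposals": asdict(proposals),
    }
    if engine == "numba":
        trace = _run_numba(state, n_sweeps, burn_in, thin, seed)
    elif engine == "python":
        trace = _run_python(state, n_sweeps, burn_in, thin, rng)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    trace.meta.update(meta)
    return trace


def _record_capacity(n_sweeps, burn_in, thin):
    return (n_sweeps - burn_in + thin - 1) // thin


def _run_python(state, n_sweeps, burn_in, thin, rng):
    n_rec = _record_capacity(n_sweeps, burn_in, thin)
    nb = state.tree.n_branches
    out = Trace(
        step=np.empty(n_rec, dtype=np.int64),
        loglik=np.empty(n_rec),
        r=np.empty(n_rec),
        alpha=np.empty(n_rec),
        mu=np.empty(n_rec),
        branch_lengths=np.empty((n_rec, nb)),
        iwe_counts=np.empty((n_rec, nb), dtype=np.int64),
        islands_with_iwe=np.empty((n_rec, nb), dtype=np.int64),
        branch_names=state.tree.branch_names(),
    )
    p = state.proposals
    for sweep in range(n_sweeps):
        for i in range(state.data.n_islands):
            if p.update_iwe and state.mode != "null":
                iwe_birth_death_move(state, i, rng)
            if p.update_frequencies:
                update_island_frequencies(state, i, rng)
        if p.update_lengths:
            for b in state.tree.branch_nodes:
                update_branch_length(state, int(b), rng)
        update_global_params(state, rng)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            row = (sweep - burn_in) // thin
            out.step[row] = sweep
            out.loglik[row] = state.total_loglik()
            out.r[row] = state.theta.r
            out.alpha[row] = state.theta.alpha
            out.mu[row] = state.theta.mu if state.mode != "null" else 0.0
            out.branch_lengths[row] = state.tree.lengths[state.tree.branch_nodes]
            counts = np.zeros(nb, dtype=np.int64)
            with_iwe = np.zeros(nb, dtype=np.int64)
            for c in state.configs:
                cb = c.counts_by_branch(state.tree)
                counts += cb
                with_iwe += cb > 0
            out.iwe_counts[row] = counts
            out.islands_with_iwe[row] = with_iwe
    state.check_cache()
    out.meta["final_state"] = state
    return out


def _kernel_arrays(state, maxev):
    tree, data = state.tree, state.data
    n_isl, n_nodes = data.n_islands, tree.n_nodes
    children_off = np.zeros(n_nodes + 1, dtype=np.int64)
    flat = []
    for node in range(n_nodes):
        children_off[node + 1] = children_off[node] + len(tree.children[node])
        flat.extend(tree.children[node])
    children_flat = np.asarray(flat, dtype=np.int64)
    # Site-pattern compression: the data are fixed during a run, so each
    # island's unique site columns (with multiplicities) suffice.
    island_fast = np.zeros(n_isl, dtype=np.uint8)
    pat_blocks, mult_blocks = [], []
    poffsets = np.zeros(n_isl + 1, dtype=np.int64)
    for i in range(n_isl):
        block = data.island_states(i)
        island_fast[i] = 1 if not np.any(block == 3) else 0
        if block.shape[1]:
            uniq, counts = np.unique(block, axis=1, return_counts=True)
        else:
            uniq = block
            counts = np.zeros(0)
        pat_blocks.append(uniq)
        mult_blocks.append(counts.astype(float))
        poffsets[i + 1] = poffsets[i] + uniq.shape[1]
    pstates = (
        np.concatenate(pat_blocks, axis=1).astype(np.int8)
        if pat_blocks
        else np.zeros((n_nodes, 0), dtype=np.int8)
    )
    pmult = np.concatenate(mult_blocks) if mult_blocks else np.zeros(0)
    ev_count = np.zeros((n_isl, n_nodes), dtype=np.int64)
    ev_pos = np.zeros((n_isl, n_nodes, maxev))
    ev_tri = np.zeros((n_isl, n_nodes, maxev, 3))
    root_triples = np.empty((n_isl, 3))
    for i, c in enumerate(state.configs):
        root_triples[i] = c.root_triple
        for b, evs in c.events.items():
            if len(evs) > maxev:
                raise ValueError("initial configuration exceeds event capacity")
            ev_count[i, b] = len(evs)
            for k, e in enumerate(evs):
                ev_pos[i, b, k] = e.position
                ev_tri[i, b, k] = e.triple
    return (children_off, children_flat, island_fast, pstates, poffsets, pmult,
            ev_count, ev_pos, ev_tri, root_triples)


def _run_numba(state, n_sweeps, burn_in, thin, seed):
    tree, data = state.tree, state.data
    nb = tree.n_branches
    n_rec = _record_capacity(n_sweeps, burn_in, thin)
    maxev = 64
    needed = max(
        (len(evs) for c in state.configs for evs in c.events.values()), default=0
    )
    while maxev < needed:
        maxev *= 2
    (children_off, children_flat, island_fast, pstates, poffsets, pmult,
     ev_count, ev_pos, ev_tri, root_triples) = _kernel_arrays(state, maxev)

    blens = state.tree.lengths.copy()
    scalars = np.asarray(
        [state.theta.r, math.log(state.theta.alpha),
         math.log(state.theta.mu) if state.theta.mu > 0 else 0.0]
    )
    rates = np.concatenate([[0.0], discretize_gamma(state.theta.alpha)])
    weights = np.concatenate(
        [[state.theta.r], np.full(3, (1.0 - state.theta.r) / 3.0)]
    )
    island_ll = state.island_ll.copy()
    priors_arr = np.asarray(
        [*state.priors.log_length, *state.priors.log_alpha, *state.priors.log_mu]
    )
    p = state.proposals
    prop_arr = np.asarray(
        [p.length_weights[0], p.length_scales[0], p.length_scales[1],
         p.r_step, p.alpha_step, p.mu_step]
    )
    flags = np.asarray(
        [
            1 if state.mode == "null" else 0,
            1 if p.update_iwe else 0,
            1 if p.update_frequencies else 0,
            1 if p.update_lengths else 0,
            1 if p.update_r else 0,
            1 if p.update_alpha else 0,
            1 if p.update_mu else 0,
            1 if state.likelihood_on else 0,
        ],
        dtype=np.int64,
    )
    rec_ll = np.zeros(n_rec)
    rec_r = np.zeros(n_rec)
    rec_alpha = np.zeros(n_rec)
    rec_mu = np.zeros(n_rec)
    rec_blens = np.zeros((n_rec, nb))
    rec_counts = np.zeros((n_rec, nb), dtype=np.int64)
    rec_islcount = np.zeros((n_rec, nb), dtype=np.int64)

    sweep = 0
    segment = 0
    while True:
        kseed = int(np.random.SeedSequence([int(seed), segment]).generate_state(1)[0] % (2**31))
        status, sweep = _kernel.run_sweeps(
            kseed, n_sweeps, sweep, burn_in, thin,
            tree.preorder, tree.parent, tree.root, children_off, children_flat,
            tree.branch_nodes, pstates, poffsets, island_fast, pmult,
            blens, scalars, root_triples, ev_count, ev_pos, ev_tri, island_ll,
            rates, weights, priors_arr, prop_arr, flags,
            rec_ll, rec_r, rec_alpha, rec_mu, rec_blens, rec_counts, rec_islcount,
        )
        if status == _kernel.STATUS_OK:
            break
        # Grow event capacity and resume (the interrupted sweep restarts).
        new_maxev = maxev * 2
        new_pos = np.zeros((data.n_islands, tree.n_nodes, new_maxev))
        new_tri = np.zeros((data.n_islands, tree.n_nodes, new_maxev, 3))
        new_pos[:, :, :maxev] = ev_pos
        new_tri[:, :, :maxev] = ev_tri
        ev_pos, ev_tri, maxev = new_pos, new_tri, new_maxev
        segment += 1

    steps = np.arange(burn_in, n_sweeps, thin, dtype=np.int64)
    trace = Trace(
        step=steps,
        loglik=rec_ll,
        r=rec_r,
        alpha=rec_alpha,
        mu=rec_mu,
        branch_lengths=rec_blens,
        iwe_counts=rec_counts,
        islands_with_iwe=rec_islcount,
        branch_names=tree.branch_names(),
    )
    final_configs = []
    for i in range(data.n_islands):
        events = {}
        for b in tree.branch_nodes:
            b = int(b)
            if ev_count[i, b]:
                events[b] = [
                    IWEvent(float(ev_pos[i, b, k]), ev_tri[i, b, k].copy())
                    for k in range(ev_count[i, b])
                ]
        final_configs.append(IslandConfig(root_triples[i].copy(), events))
    trace.meta["final"] = {
        "r": float(scalars[0]),
        "alpha": float(math.exp(scalars[1])),
        "mu": float(math.exp(scalars[2])) if state.mode != "null" else 0.0,
        "branch_lengths": blens[tree.branch_nodes].copy(),
        "island_ll": island_ll,
        "configs": final_configs,
    }
    return trace
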