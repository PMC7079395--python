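"""Forward simulation of the IWE-SSE model.

Generates full datasets for calibration studies: global parameters and
branch lengths drawn from their priors, per-island IWE configurations from
the Poisson process, root states from island equilibrium triples, and
states at all other nodes propagated root-to-tips.  Two state-evolution
modes are available: *matrix* mode draws child states from composed
transition matrices, and *event* mode simulates individual SSEs (including
silent ones) and IWE transitions while logging event counts, which ties the
branch-length unit to expected event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .likelihood import IslandConfig, IWEvent, MethylationData
from .mcmc import Priors
from .model_core import MISSING, GlobalParams
from .tree import Tree

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "EventLog",
    "SimulatedDataset",
    "sample_design_from_priors",
    "simulate_iwes",
    "simulate_states",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Shape of a simulated study: tree, island sizes, priors.

    Defaults give the reduced calibration design: a balanced 4-tip tree and
    20 islands of 10-100 CpG sites; the full-size study of the original
    analysis used 100 islands of 10-400 sites.
    """

    n_islands: int = 20
    site_range: tuple = (10, 100)
    tree: Optional[Tree] = None
    priors: Priors = field(default_factory=Priors)
    theta: Optional[GlobalParams] = None  # fix instead of drawing from priors
    branch_lengths: Optional[tuple] = None  # fix instead of drawing from priors
    observe: str = "all"  # "all" nodes or "tips" only

    def resolved_tree(self) -> Tree:
        return self.tree if self.tree is not None else Tree.balanced_quartet()


@dataclass
class GroundTruth:
    """Every latent quantity behind a simulated dataset."""

    theta: GlobalParams
    branch_lengths: np.ndarray  # canonical branch order
    configs: list  # per-island IslandConfig (root triple + IWEs)
    rate_values: np.ndarray  # the 4 rate-category values
    rate_categories: np.ndarray  # per-site category index, island-concatenated
    site_counts: np.ndarray

    @property
    def root_triples(self) -> np.ndarray:
        return np.stack([c.root_triple for c in self.configs])

    def total_iwe_count(self) -> int:
        return int(sum(c.n_events() for c in self.configs))


@dataclass
class EventLog:
    """Per-branch counts of simulated events (canonical branch order).

    ``sse_counts`` includes silent SSEs that redraw the current state;
    ``iwe_counts`` sums island-wide events over all islands.
    """

    sse_counts: np.ndarray
    iwe_counts: np.ndarray


@dataclass
class SimulatedDataset:
    tree: Tree
    data: MethylationData
    truth: GroundTruth
    event_log: Optional[EventLog] = None


def sample_design_from_priors(design: SimulationDesign, rng: np.random.Generator):
    """Draw theta, branch lengths, island sizes/root triples and per-site rates.

    Returns ``(tree, truth)`` where ``tree`` carries the drawn branch lengths
    and ``truth.configs`` holds root triples only (no IWEs yet).
    """
    base = design.resolved_tree()
    theta = design.theta or design.priors.sample_global_params(rng)
    if design.branch_lengths is not None:
        lengths = np.asarray(design.branch_lengths, dtype=float)
    else:
        lengths = design.priors.sample_branch_lengths(rng, base.n_branches)
    tree = base.with_lengths(lengths)

    lo, hi = design.site_range
    site_counts = rng.integers(lo, hi + 1, size=design.n_islands)
    configs = [
        IslandConfig(rng.dirichlet(np.ones(3)), {}) for _ in range(design.n_islands)
    ]
    rate_model = theta.rate_model
    n_total = int(site_counts.sum())
    categories = np.where(
        rng.uniform(size=n_total) < theta.r,
        0,
        rng.integers(1, 4, size=n_total),
    )
    truth = GroundTruth(
        theta=theta,
        branch_lengths=lengths,
        configs=configs,
        rate_values=rate_model.rates,
        rate_categories=categories,
        site_counts=site_counts,
    )
    return tree, truth


def simulate_iwes(tree: Tree, mu: float, n_islands: int, rng: np.random.Generator,
                  root_triples=None) -> list:
    """Place IWEs: per island and branch, Poisson(mu*l) events at uniform positions.

    Event triples are Dirichlet(1,1,1).  Returns per-island IslandConfigs; root
    triples default to fresh Dirichlet draws when not supplied.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    configs = []
    for i in range(n_islands):
        root = root_triples[i] if root_triples is not None else rng.dirichlet(np.ones(3))
        events = {}
        for b in tree.branch_nodes:
            b = int(b)
            l = float(tree.lengths[b])
            k = rng.poisson(mu * l)
            if k:
                pos = np.sort(rng.uniform(0.0, l, size=k))
                events[b] = [IWEvent(p, rng.dirichlet(np.ones(3))) for p in pos]
        configs.append(IslandConfig(np.asarray(root, dtype=float), events))
    return configs


def _draw_categorical(rng, probs, size):
    return rng.choice(3, size=size, p=probs / probs.sum())


def _segments(events, length):
    """(triple_or_None, duration, event) pieces of a branch; event ends each segment."""
    segs = []
    prev = 0.0
    for e in events:
        segs.append((prev, e.position, e))
        prev = e.position
    segs.append((prev, length, None))
    return segs


def simulate_states(
    tree: Tree,
    configs: list,
    truth_rates: np.ndarray,
    rate_categories: np.ndarray,
    site_counts,
    rng: np.random.Generator,
    mode: str = "matrix",
):
    """Evolve site states root-to-tips; returns (MethylationData, EventLog|None).

    Matrix mode samples each child's states from the composed branch
    transition matrix of the site's rate category; event mode simulates the
    SSE point process (exponential waiting times, state redrawn from the
    current triple at every event, silent events counted) and applies each
    IWE's transition matrix site by site.
    """
    from .likelihood import composed_branch_matrix, triples_in_force
    from .model_core import iwe_transition_matrix

    if mode not in ("matrix", "event"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    site_counts = np.asarray(site_counts, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(site_counts)])
    n_sites = int(offsets[-1])
    states = np.full((tree.n_nodes, n_sites), MISSING, dtype=np.int8)
    sse_counts = np.zeros(tree.n_branches, dtype=np.int64)
    iwe_counts = np.zeros(tree.n_branches, dtype=np.int64)
    branch_index = {int(b): j for j, b in enumerate(tree.branch_nodes)}

    for i, config in enumerate(configs):
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        ns = int(site_counts[i])
        cats = rate_categories[sl]
        states[tree.root, sl] = _draw_categorical(rng, config.root_triple, ns)
        start = triples_in_force(tree, config)
        for node in tree.preorder:
            node = int(node)
            if node == tree.root:
                continue
            par = tree.parent[node]
            evs = config.events_on(node)
            l = float(tree.lengths[node])
            iwe_counts[branch_index[node]] += len(evs)
            parent_states = states[par, sl]
            child_states = np.empty(ns, dtype=np.int8)
            if mode == "matrix":
                for x in range(len(truth_rates)):
                    in_cat = np.flatnonzero(cats == x)
                    if in_cat.size == 0:
                        continue
                    P = composed_branch_matrix(start[par], evs, float(truth_rates[x]), l)
                    for ps in range(3):
                        idx = in_cat[parent_states[in_cat] == ps]
                        if idx.size:
                            child_states[idx] = _draw_categorical(rng, P[ps], idx.size)
            else:
                cur = parent_states.copy()
                pi = start[par]
                for seg_start, seg_end, event in _segments(evs, l):
                    d = seg_end - seg_start
                    for j in range(ns):
                        R = float(truth_rates[cats[j]])
                        if R > 0.0 and d > 0.0:
                            t = rng.exponential(1.0 / R)
                            while t < d:
                                cur[j] = _draw_categorical(rng, pi, 1)[0]
                                sse_counts[branch_index[node]] += 1
                                t += rng.exponential(1.0 / R)
                    if event is not None:
                        M = iwe_transition_matrix(pi, event.triple)
                        for ps in range(3):
                            idx = np.flatnonzero(cur == ps)
                            if idx.size:
                                cur[idx] = _draw_categorical(rng, M[ps], idx.size)
                        pi = event.triple
                child_states[:] = cur
            states[node, sl] = child_states

    data = MethylationData(states, offsets)
    log = EventLog(sse_counts, iwe_counts) if mode == "event" else None
    return data, log


def simulate_dataset(
    design: SimulationDesign, rng_or_seed, mode: str = "matrix"
) -> SimulatedDataset:
    """End-to-end generation of one dataset with its full ground truth."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    tree, truth = sample_design_from_priors(design, rng)
    configs = simulate_iwes(
        tree, truth.theta.mu, design.n_islands, rng,
        root_triples=truth.root_triples,
    )
    truth.configs = configs
    data, log = simulate_states(
        tree, configs, truth.rate_values, truth.rate_categories,
        truth.site_counts, rng, mode=mode,
    )
    if design.observe == "tips":
        internal = [n for n in range(tree.n_nodes) if not tree.is_tip(n)]
        data.states[internal, :] = MISSING
    return SimulatedDataset(tree=tree, data=data, truth=truth, event_log=log)
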