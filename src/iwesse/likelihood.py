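"""Exact log-likelihood of observed methylation states under the IWE-SSE model.

The likelihood factorizes over CpG islands; conditioned on an island's IWE
configuration, it factorizes over sites, and each site's probability is a
mixture over the four rate-factor categories of a pruning recursion that
interleaves SSE transition matrices with IWE transition matrices along each
branch.  Partial likelihood vectors carry an explicit log-scale factor so
that products over many branches do not underflow.

This module is the readable numpy reference implementation; the MCMC engine
uses a numba kernel (:mod:`iwesse._kernel`) that is checked against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    MISSING,
    N_STATES,
    GlobalParams,
    iwe_transition_matrix,
    sse_transition_matrix,
    validate_triple,
)
from .tree import Tree

__all__ = [
    "IWEvent",
    "IslandConfig",
    "MethylationData",
    "PartialLikelihoodVector",
    "composed_branch_matrix",
    "branch_partial",
    "node_partial",
    "site_log_likelihood",
    "island_log_likelihood",
    "tree_log_likelihood",
]


@dataclass
class IWEvent:
    """One island-wide event: position on its branch and the new triple."""

    position: float
    triple: np.ndarray

    def __post_init__(self):
        self.triple = validate_triple(self.triple, strict=True)


@dataclass
class IslandConfig:
    """IWE configuration of one island: root triple plus per-branch events.

    ``events`` maps a branch (identified by its child node index) to its
    events sorted by position measured from the branch's parent node.
    """

    root_triple: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        self.root_triple = validate_triple(self.root_triple, strict=True)

    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())

    def events_on(self, branch_node: int) -> list:
        return self.events.get(branch_node, [])

    def counts_by_branch(self, tree: Tree) -> np.ndarray:
        return np.asarray(
            [len(self.events_on(b)) for b in tree.branch_nodes], dtype=np.int64
        )

    def validate(self, tree: Tree) -> None:
        for b, evs in self.events.items():
            l = tree.lengths[b]
            pos = [e.position for e in evs]
            if any(not 0.0 < p < l for p in pos):
                raise ValueError(
                    f"IWE offsets on branch {tree.names[b]!r} must lie strictly "
                    f"inside (0, {l}); got {pos}"
                )
            if pos != sorted(pos):
                raise ValueError(f"IWE offsets on branch {tree.names[b]!r} not sorted")

    def copy(self) -> "IslandConfig":
        return IslandConfig(
            self.root_triple.copy(),
            {b: [IWEvent(e.position, e.triple.copy()) for e in evs]
             for b, evs in self.events.items()},
        )


@dataclass
class MethylationData:
    """Methylation states at tree nodes, grouped into islands.

    ``states`` is an integer matrix of shape (n_nodes, n_sites) with codes
    0=u, 1=p, 2=m, 3=missing/unobserved; sites are stored contiguously per
    island, delimited by ``island_offsets``.  An internal node whose column
    entries are all missing is simply unobserved.
    """

    states: np.ndarray
    island_offsets: np.ndarray
    island_names: list | None = None
    node_names: list | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        self.island_offsets = np.asarray(self.island_offsets, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValueError("states must be a (n_nodes, n_sites) matrix")
        if self.island_offsets[0] != 0 or self.island_offsets[-1] != self.states.shape[1]:
            raise ValueError("island offsets must span all site columns")
        if np.any(np.diff(self.island_offsets) < 0):
            raise ValueError("island offsets must be nondecreasing")

    @property
    def n_islands(self) -> int:
        return len(self.island_offsets) - 1

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def island_slice(self, i: int) -> slice:
        return slice(int(self.island_offsets[i]), int(self.island_offsets[i + 1]))

    def island_states(self, i: int) -> np.ndarray:
        return self.states[:, self.island_slice(i)]

    def site_counts(self) -> np.ndarray:
        return np.diff(self.island_offsets)


@dataclass
class PartialLikelihoodVector:
    """Three partial likelihoods ``(w(u), w(p), w(m))`` with a log-scale factor."""

    values: np.ndarray
    log_scale: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3,):
            raise ValueError("partial likelihood vector must have 3 entries")
        if not np.all(np.isfinite(self.values)) or np.all(self.values == 0):
            raise ValueError("partial likelihood vector must be finite with a nonzero entry")

    def rescaled(self) -> "PartialLikelihoodVector":
        m = self.values.max()
        return PartialLikelihoodVector(self.values / m, self.log_scale + np.log(m))


def composed_branch_matrix(pi_start, events, R: float, length: float) -> np.ndarray:
    """Transition matrix across a whole branch with IWEs interleaved.

    ``pi_start`` is the equilibrium triple in force at the parent node;
    ``events`` are (position, triple) pairs sorted by position.  Returns
    ``P_0 @ prod_k (M_k @ P_k)`` with the SSE closed forms for every ``P``.
    """
    if length < 0:
        raise ValueError("branch length must be nonnegative")
    pi = np.asarray(pi_start, dtype=float)
    prev_t = 0.0
    out = None
    for ev in events:
        pos, tri = (ev.position, ev.triple) if isinstance(ev, IWEvent) else ev
        if not 0.0 < pos < length:
            raise ValueError(f"event offset {pos} outside (0, {length})")
        if pos < prev_t:
            raise ValueError("events must be sorted by position")
        seg = sse_transition_matrix(pi, R, pos - prev_t)
        out = seg if out is None else out @ seg
        out = out @ iwe_transition_matrix(pi, tri)
        pi, prev_t = np.asarray(tri, dtype=float), pos
    seg = sse_transition_matrix(pi, R, length - prev_t)
    return seg if out is None else out @ seg


def branch_partial(
    omega_child: PartialLikelihoodVector,
    events,
    pi_start,
    R: float,
    length: float,
) -> PartialLikelihoodVector:
    """Propagate a partial likelihood vector from a branch's child end to its top.

    Implements ``w_0 = P_0 (prod_j M_j P_j) w_{h+1}`` where each SSE segment
    uses the triple in force on its interval and the site's rate factor.
    """
    C = composed_branch_matrix(pi_start, events, R, length)
    return PartialLikelihoodVector(C @ omega_child.values, omega_child.log_scale).rescaled()


def node_partial(child_omegas, observed_state=None) -> PartialLikelihoodVector:
    """Combine child partials at a node, masking by an observed state.

    A tip contributes the indicator vector of its observed state (all ones if
    missing); an unobserved internal node the entrywise product of its
    children's top-of-branch vectors; an observed internal node the same
    product masked to the observed state.
    """
    if not child_omegas and observed_state is None:
        raise ValueError("a node needs children or an observation")
    vec = np.ones(3)
    scale = 0.0
    for w in child_omegas:
        vec = vec * w.values
        scale += w.log_scale
    if observed_state is not None and observed_state != MISSING:
        mask = np.zeros(3)
        mask[observed_state] = 1.0
        vec = vec * mask
    return PartialLikelihoodVector(vec, scale)


# ---------------------------------------------------------------------------
# Vectorized island likelihood (reference engine)
# ---------------------------------------------------------------------------

def triples_in_force(tree: Tree, config: IslandConfig) -> np.ndarray:
    """Equilibrium triple in force *at* each node (after its branch's events)."""
    out = np.empty((tree.n_nodes, 3))
    out[tree.root] = config.root_triple
    for node in tree.preorder:
        if node == tree.root:
            continue
        evs = config.events_on(int(node))
        out[node] = evs[-1].triple if evs else out[tree.parent[node]]
    return out


def _island_branch_matrices(tree: Tree, config: IslandConfig, rates: np.ndarray):
    """Composed per-branch transition matrices for every rate category."""
    start = triples_in_force(tree, config)
    comp = {}
    for b in tree.branch_nodes:
        b = int(b)
        evs = config.events_on(b)
        comp[b] = np.stack(
            [
                composed_branch_matrix(
                    start[tree.parent[b]], evs, float(R), float(tree.lengths[b])
                )
                for R in rates
            ]
        )
    return comp


def island_site_log_likelihoods(
    tree: Tree,
    island_states: np.ndarray,
    config: IslandConfig,
    theta: GlobalParams,
) -> np.ndarray:
    """Per-site log-likelihoods of one island, mixture over rate categories."""
    rate_model = theta.rate_model
    rates, weights = rate_model.rates, rate_model.weights
    n_cats = len(rates)
    ns = island_states.shape[1]
    comp = _island_branch_matrices(tree, config, rates)

    omega = {}
    scale = {}
    for node in tree.postorder:
        node = int(node)
        s = island_states[node]
        mask = np.zeros((N_STATES, ns))
        obs = s != MISSING
        mask[:, ~obs] = 1.0
        mask[s[obs], np.flatnonzero(obs)] = 1.0
        w = np.broadcast_to(mask, (n_cats, N_STATES, ns)).copy()
        sc = np.zeros((n_cats, ns))
        for c in tree.children[node]:
            down = np.einsum("xij,xjn->xin", comp[c], omega[c])
            w = w * down
            sc = sc + scale[c]
            del omega[c], scale[c]
        mx = w.max(axis=1)
        pos = mx > 0
        w = np.divide(w, mx[:, None, :], out=np.zeros_like(w), where=pos[:, None, :])
        sc = sc + np.log(mx, out=np.full_like(mx, -np.inf), where=pos)
        omega[node], scale[node] = w, sc

    root_sum = np.einsum("j,xjn->xn", config.root_triple, omega[tree.root])
    with np.errstate(divide="ignore"):
        log_terms = np.log(weights[:, None]) + np.log(root_sum) + scale[tree.root]
    mx = log_terms.max(axis=0)
    finite = np.isfinite(mx)
    site_ll = np.full(ns, -np.inf)
    site_ll[finite] = mx[finite] + np.log(
        np.exp(log_terms[:, finite] - mx[finite]).sum(axis=0)
    )
    if not np.all(finite):
        warnings.warn(
            "site(s) with zero likelihood under the current configuration",
            RuntimeWarning,
            stacklevel=2,
        )
    return site_ll


def site_log_likelihood(site_states, config: IslandConfig, tree: Tree, theta: GlobalParams) -> float:
    """Log-likelihood of a single site (column of per-node states)."""
    col = np.asarray(site_states, dtype=np.int8).reshape(-1, 1)
    return float(island_site_log_likelihoods(tree, col, config, theta)[0])


def island_log_likelihood(island_states, config: IslandConfig, tree: Tree, theta: GlobalParams) -> float:
    """Log-likelihood of one island: sum over its (conditionally independent) sites."""
    states = np.asarray(island_states, dtype=np.int8)
    return float(island_site_log_likelihoods(tree, states, config, theta).sum())


def tree_log_likelihood(
    data: MethylationData,
    configs,
    tree: Tree,
    theta: GlobalParams,
    islands=None,
) -> float:
    """Total log-likelihood; ``islands`` restricts to a subset for incremental updates."""
    if len(configs) != data.n_islands:
        raise ValueError("one IWE configuration per island is required")
    idx = range(data.n_islands) if islands is None else islands
    return float(
        sum(
            island_log_likelihood(data.island_states(i), configs[i], tree, theta)
            for i in idx
        )
    )
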