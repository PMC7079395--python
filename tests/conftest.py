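import numpy as np
import pytest

from iwesse.likelihood import IslandConfig, IWEvent
from iwesse.model_core import GlobalParams
from iwesse.tree import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def two_node_tree():
    """Root with a single tip at distance 1."""
    return Tree.from_newick("(tipA:1.0)root;")


@pytest.fixture
def quartet():
    return Tree.balanced_quartet()


_TOPOLOGIES = [
    "(tipA:1.0)root;",
    "(tipA:1.0,tipB:1.0)root;",
    "((tipA:1.0)inner:1.0,tipB:1.0)root;",
    "((tipA:1.0,tipB:1.0)inner:1.0)root;",
]


def random_instance(rng, max_events=2, n_sites=1, observe="all", theta=None):
    """Random small likelihood instance: (tree, config, theta, site-state matrix)."""
    newick = _TOPOLOGIES[rng.integers(len(_TOPOLOGIES))]
    base = Tree.from_newick(newick)
    tree = base.with_lengths(rng.uniform(0.05, 2.0, size=base.n_branches))
    events = {}
    for b in tree.branch_nodes:
        k = rng.integers(0, max_events + 1)
        if k:
            pos = np.sort(rng.uniform(0.0, tree.lengths[b], size=k))
            events[int(b)] = [IWEvent(float(p), rng.dirichlet(np.ones(3))) for p in pos]
    config = IslandConfig(rng.dirichlet(np.ones(3)), events)
    if theta is None:
        theta = GlobalParams(
            r=float(rng.uniform(0.0, 0.9)),
            alpha=float(np.exp(rng.normal(0.0, 1.0))),
            mu=1.0,
        )
    states = rng.integers(0, 3, size=(tree.n_nodes, n_sites)).astype(np.int8)
    if observe == "tips":
        for n in range(tree.n_nodes):
            if not tree.is_tip(n):
                states[n, :] = 3
    elif observe == "mixed":
        for n in range(tree.n_nodes):
            mask = rng.uniform(size=n_sites) < 0.3
            states[n, mask] = 3
        # keep at least one observed entry per site
        for s in range(n_sites):
            if np.all(states[:, s] == 3):
                states[tree.tips[0], s] = rng.integers(0, 3)
    return tree, config, theta, states
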