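"""Pruning likelihood with within-branch IWEs, against enumeration oracles."""

import numpy as np
import pytest

from iwesse import _kernel
from iwesse.likelihood import (
    IslandConfig,
    IWEvent,
    MethylationData,
    PartialLikelihoodVector,
    branch_partial,
    composed_branch_matrix,
    island_log_likelihood,
    node_partial,
    site_log_likelihood,
    tree_log_likelihood,
)
from iwesse.mcmc import MCMCState, _kernel_arrays
from iwesse.model_core import GlobalParams, discretize_gamma
from iwesse.tree import Tree

from .conftest import random_instance
from .oracles import branch_prob, site_loglik_bruteforce


class TestBranchPartial:
    def test_zero_length_no_events_is_identity(self):
        w = PartialLikelihoodVector(np.array([0.1, 0.5, 0.4]))
        out = branch_partial(w, [], (0.2, 0.3, 0.5), 1.0, 0.0)
        np.testing.assert_allclose(out.values * np.exp(out.log_scale), w.values)

    def test_indicator_child_closed_form(self):
        # child in state m, no events: w0(u) = (1 - e^{-R l}) * pi_m
        w = PartialLikelihoodVector(np.array([0.0, 0.0, 1.0]))
        out = branch_partial(w, [], (0.2, 0.3, 0.5), 1.0, 0.5)
        vals = out.values * np.exp(out.log_scale)
        assert vals[0] == pytest.approx((1 - np.exp(-0.5)) * 0.5)

    def test_single_event_matches_enumeration(self, rng):
        for _ in range(20):
            pi0 = rng.dirichlet(np.ones(3))
            tri = rng.dirichlet(np.ones(3))
            l = float(rng.uniform(0.2, 2.0))
            pos = l / 2
            R = float(rng.uniform(0, 3))
            child = rng.integers(0, 3)
            w = np.zeros(3)
            w[child] = 1.0
            out = branch_partial(
                PartialLikelihoodVector(w), [IWEvent(pos, tri)], pi0, R, l
            )
            vals = out.values * np.exp(out.log_scale)
            expected = [
                branch_prob(y, child, [(pos, tri)], pi0, R, l) for y in range(3)
            ]
            np.testing.assert_allclose(vals, expected, atol=1e-12)

    def test_event_outside_branch_rejected(self):
        w = PartialLikelihoodVector(np.ones(3))
        with pytest.raises(ValueError):
            branch_partial(w, [IWEvent(1.5, np.ones(3) / 3)], (0.2, 0.3, 0.5), 1.0, 1.0)


class TestNodePartial:
    def test_tip_indicator_and_missing(self):
        np.testing.assert_allclose(node_partial([], observed_state=1).values, [0, 1, 0])
        np.testing.assert_allclose(node_partial([], observed_state=3).values, [1, 1, 1])

    def test_observed_internal_masks_product(self):
        a = PartialLikelihoodVector(np.array([0.2, 0.5, 0.3]))
        b = PartialLikelihoodVector(np.array([0.4, 0.1, 0.5]))
        out = node_partial([a, b], observed_state=0)
        np.testing.assert_allclose(out.values, [0.08, 0.0, 0.0])

    def test_no_children_no_observation_errors(self):
        with pytest.raises(ValueError):
            node_partial([], observed_state=None)


class TestSiteLogLikelihood:
    def test_single_branch_hand_value(self, two_node_tree):
        cfg = IslandConfig(np.array([0.2, 0.3, 0.5]))
        theta = GlobalParams(r=0.0, alpha=1e9, mu=0.0)
        ll = site_log_likelihood([0, 2], cfg, two_node_tree, theta)
        assert ll == pytest.approx(np.log(0.2 * (1 - np.exp(-1)) * 0.5), abs=1e-7)

    def test_all_invariant_identical_states(self, two_node_tree):
        cfg = IslandConfig(np.array([0.2, 0.3, 0.5]))
        theta = GlobalParams(r=1.0, alpha=1.0, mu=0.0)
        assert site_log_likelihood([0, 0], cfg, two_node_tree, theta) == pytest.approx(
            np.log(0.2)
        )

    def test_all_invariant_with_change_is_impossible(self, two_node_tree):
        cfg = IslandConfig(np.array([0.2, 0.3, 0.5]))
        theta = GlobalParams(r=1.0, alpha=1.0, mu=0.0)
        with pytest.warns(RuntimeWarning):
            assert site_log_likelihood([0, 2], cfg, two_node_tree, theta) == -np.inf

    def test_unobserved_root_sums_over_root_states(self, two_node_tree):
        pi = np.array([0.2, 0.3, 0.5])
        cfg = IslandConfig(pi)
        theta = GlobalParams(r=0.0, alpha=1e9, mu=0.0)
        expected = sum(
            pi[z] * ((1 - np.exp(-1)) * 0.5 if z != 2 else 0.5 + 0.5 * np.exp(-1))
            for z in range(3)
        )
        assert site_log_likelihood([3, 2], cfg, two_node_tree, theta) == pytest.approx(
            np.log(expected), abs=1e-7
        )


class TestIslandAndTreeLikelihood:
    def test_island_of_one_site_equals_site(self, rng):
        tree, cfg, theta, states = random_instance(rng)
        assert island_log_likelihood(states, cfg, tree, theta) == pytest.approx(
            site_log_likelihood(states[:, 0], cfg, tree, theta)
        )

    def test_identical_sites_double(self, rng):
        tree, cfg, theta, states = random_instance(rng)
        two = np.repeat(states, 2, axis=1)
        assert island_log_likelihood(two, cfg, tree, theta) == pytest.approx(
            2 * island_log_likelihood(states, cfg, tree, theta)
        )

    @pytest.mark.parametrize("observe", ["all", "tips", "mixed"])
    def test_matches_bruteforce_enumeration(self, rng, observe):
        for _ in range(25):
            tree, cfg, theta, states = random_instance(
                rng, max_events=2, n_sites=2, observe=observe
            )
            got = island_log_likelihood(states, cfg, tree, theta)
            want = sum(
                site_loglik_bruteforce(tree, cfg, theta, states[:, s])
                for s in range(states.shape[1])
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_tree_likelihood_sums_islands_and_supports_subsets(self, rng):
        tree, cfg0, theta, states0 = random_instance(rng, n_sites=3)
        cfg1 = IslandConfig(rng.dirichlet(np.ones(3)))
        states1 = rng.integers(0, 3, size=(tree.n_nodes, 2)).astype(np.int8)
        data = MethylationData(
            np.concatenate([states0, states1], axis=1), [0, 3, 5]
        )
        full = tree_log_likelihood(data, [cfg0, cfg1], tree, theta)
        parts = [
            tree_log_likelihood(data, [cfg0, cfg1], tree, theta, islands=[i])
            for i in range(2)
        ]
        assert full == pytest.approx(sum(parts), abs=1e-9)
        assert parts[0] == pytest.approx(
            island_log_likelihood(states0, cfg0, tree, theta)
        )


class TestInvariances:
    def test_site_and_island_order_invariance(self, rng):
        tree, cfg, theta, states = random_instance(rng, n_sites=5)
        perm = rng.permutation(5)
        assert island_log_likelihood(states, cfg, tree, theta) == pytest.approx(
            island_log_likelihood(states[:, perm], cfg, tree, theta), abs=1e-10
        )

    def test_tip_relabel_invariance_with_identical_data(self, rng):
        tree = Tree.from_newick("(tipA:0.7,tipB:0.7)root;")
        cfg = IslandConfig(rng.dirichlet(np.ones(3)))
        theta = GlobalParams(r=0.3, alpha=1.0, mu=0.0)
        states = np.array([[3, 3], [0, 1], [2, 0]], dtype=np.int8)
        swapped = states[[0, 2, 1], :]
        assert island_log_likelihood(states, cfg, tree, theta) == pytest.approx(
            island_log_likelihood(swapped, cfg, tree, theta), abs=1e-10
        )

    def test_likelihood_increases_in_length_for_small_l(self):
        cfg = IslandConfig(np.array([0.2, 0.3, 0.5]))
        theta = GlobalParams(r=0.0, alpha=1e6, mu=0.0)
        lls = []
        for l in (0.01, 0.05, 0.2):
            tree = Tree.from_newick(f"(tipA:{l})root;")
            lls.append(site_log_likelihood([0, 2], cfg, tree, theta))
        assert lls[0] < lls[1] < lls[2]

    def test_no_underflow_on_deep_chain(self):
        # 321 branches in a path with alternating states: the naive product of
        # per-branch probabilities is ~1e-650 and would underflow without the
        # log-scale bookkeeping
        n_branches = 321
        newick = "tip:0.01;"
        for i in range(n_branches - 1):
            newick = f"({newick[:-1]})n{i}:0.01;"
        newick = f"({newick[:-1]})root;"
        tree = Tree.from_newick(newick)
        pi = np.array([0.3, 0.2, 0.5])
        cfg = IslandConfig(pi)
        theta = GlobalParams(r=0.0, alpha=1e9, mu=0.0)
        states = np.zeros((tree.n_nodes, 1), dtype=np.int8)
        # preorder is root->tip on a path; alternate u and m down the path
        for depth, node in enumerate(tree.preorder):
            states[node, 0] = 0 if depth % 2 == 0 else 2
        ll = island_log_likelihood(states, cfg, tree, theta)
        e = np.exp(-0.01)
        half = n_branches // 2
        expected = (
            np.log(pi[0])
            + (half + 1) * np.log((1 - e) * pi[2])
            + half * np.log((1 - e) * pi[0])
        )
        # the discretized rates at alpha=1e9 are 1 +- ~1e-5, which accumulates
        # over 321 branches to ~1e-4 in the log-likelihood
        assert ll == pytest.approx(expected, abs=1e-2)
        assert ll < -700  # beyond the double-precision underflow threshold


class TestKernelAgreement:
    @pytest.mark.parametrize("observe", ["all", "tips", "mixed"])
    def test_kernel_matches_numpy_reference(self, rng, observe):
        for _ in range(15):
            tree, cfg, theta, states = random_instance(rng, n_sites=4, observe=observe)
            data = MethylationData(states, [0, states.shape[1]])
            state = MCMCState(tree=tree, data=data, theta=theta, configs=[cfg])
            (co, cf, ifast, ps, po, pm, ec, ep, et, rt) = _kernel_arrays(state, 8)
            rates = np.concatenate([[0.0], discretize_gamma(theta.alpha)])
            weights = np.concatenate([[theta.r], np.full(3, (1 - theta.r) / 3)])
            got = _kernel.island_loglik(
                0, tree.preorder, tree.parent, tree.root, co, cf, tree.lengths,
                ps, po, ifast, pm, rt, ec, ep, et, rates, weights,
            )
            want = island_log_likelihood(states, cfg, tree, theta)
            assert got == pytest.approx(want, abs=1e-9)


def test_composed_branch_matrix_is_stochastic_and_ordered(rng):
    pi0 = rng.dirichlet(np.ones(3))
    evs = [IWEvent(0.2, rng.dirichlet(np.ones(3))), IWEvent(0.7, rng.dirichlet(np.ones(3)))]
    C = composed_branch_matrix(pi0, evs, 1.3, 1.0)
    np.testing.assert_allclose(C.sum(axis=1), 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        composed_branch_matrix(pi0, list(reversed(evs)), 1.3, 1.0)
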