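"""Reversible-jump sampler: acceptance ratios, proposals, engines, traces."""

import math

import numpy as np
import pytest
from scipy import stats

from iwesse.likelihood import IslandConfig, MethylationData
from iwesse.mcmc import (
    MCMCState,
    Priors,
    ProposalConfig,
    branch_length_acceptance,
    credibility_interval,
    iwe_birth_acceptance,
    iwe_birth_death_move,
    iwe_birth_log_ratio,
    iwe_death_log_ratio,
    null_branch_length_acceptance,
    propose_iwe_birth,
    run_mcmc,
    update_island_frequencies,
)
from iwesse.model_core import GlobalParams
from iwesse.simulator import SimulationDesign, simulate_dataset
from iwesse.tree import Tree


def empty_data(n_islands):
    return MethylationData(
        np.zeros((7, 0), dtype=np.int8), np.zeros(n_islands + 1, dtype=np.int64)
    )


class TestAcceptanceFormulas:
    def test_birth_formula_substitution(self):
        assert iwe_birth_acceptance(0.0, 0.0, mu=1.0, l=0.5, n=0) == pytest.approx(0.5)
        assert iwe_birth_acceptance(0.0, 0.0, mu=2.0, l=1.0, n=0) == 1.0
        assert iwe_birth_acceptance(0.0, 0.0, mu=0.0, l=1.0, n=0) == 0.0

    def test_birth_death_reciprocity(self, rng):
        for _ in range(100):
            dll = float(rng.normal(0, 3))
            mu, l = float(rng.uniform(0.1, 5)), float(rng.uniform(0.1, 5))
            n = int(rng.integers(0, 10))
            birth = iwe_birth_log_ratio(dll, 0.0, mu, l, n)
            death = iwe_death_log_ratio(-dll, 0.0, mu, l, n + 1)
            assert birth + death == pytest.approx(0.0, abs=1e-12)

    def test_branch_length_formula(self):
        flat = Priors(log_length=(0.0, 1e9))
        # l' = l: all length terms cancel
        assert branch_length_acceptance(-1.0, -2.0, 0.7, 0.7, 3, 1.2, 10, flat) == 1.0
        assert branch_length_acceptance(-3.0, -2.0, 0.7, 0.7, 3, 1.2, 10, flat) == (
            pytest.approx(math.exp(-1.0))
        )
        # equal likelihoods, flat prior, n=0, mu*N*(l'-l) = log 2 -> 0.5
        l_old = 1.0
        l_new = 1.0 + math.log(2.0)
        assert branch_length_acceptance(
            0.0, 0.0, l_new, l_old, 0, 1.0, 1, flat
        ) == pytest.approx(0.5, rel=1e-9)

    def test_null_acceptance_degenerates_from_full(self):
        pri = Priors(log_length=(-1.0, 0.5))
        lp_new = pri.log_length_logpdf(math.log(0.8))
        lp_old = pri.log_length_logpdf(math.log(0.5))
        a = null_branch_length_acceptance(-4.0, -3.5, lp_new, lp_old)
        b = branch_length_acceptance(-4.0, -3.5, 0.8, 0.5, 0, 0.0, 7, pri)
        assert a == pytest.approx(b, rel=1e-12)


class TestCredibilityInterval:
    def test_constant_trace_degenerates(self):
        assert credibility_interval([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_normal_quantiles(self, rng):
        x = rng.normal(size=200_000)
        lo, hi = credibility_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_level_one_gives_range(self):
        assert credibility_interval([1.0, 5.0, 2.0], 1.0) == (1.0, 5.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            credibility_interval([])
        with pytest.raises(ValueError):
            credibility_interval([1.0])
        with pytest.raises(ValueError):
            credibility_interval([1.0, 2.0], level=0.0)


class TestProposals:
    @pytest.fixture
    def prior_state(self):
        tree = Tree.balanced_quartet().with_lengths(np.full(6, 0.8))
        data = empty_data(3)
        configs = [IslandConfig(np.ones(3) / 3, {}) for _ in range(3)]
        return MCMCState(
            tree=tree, data=data, theta=GlobalParams(0.5, 1.0, 1.0),
            configs=configs, likelihood_on=False,
        )

    def test_birth_position_uniform_and_triple_dirichlet(self, prior_state, rng):
        positions, triples = [], []
        for _ in range(4000):
            cfg, b = propose_iwe_birth(prior_state, 0, rng)
            ev = next(e for evs in cfg.events.values() for e in evs)
            assert 0.0 < ev.position < 0.8
            positions.append(ev.position)
            triples.append(ev.triple)
        assert stats.kstest(positions, stats.uniform(0, 0.8).cdf).pvalue > 0.001
        triples = np.asarray(triples)
        np.testing.assert_allclose(triples.mean(axis=0), 1 / 3, atol=0.02)
        # Dirichlet(1,1,1) marginal variance is 2/36
        np.testing.assert_allclose(triples.var(axis=0), 2 / 36, atol=0.01)

    def test_frequency_update_samples_prior_without_data(self, prior_state, rng):
        roots = []
        for _ in range(4000):
            accepted = update_island_frequencies(prior_state, 0, rng)
            assert accepted  # likelihood ratio is 1 without data
            roots.append(prior_state.configs[0].root_triple.copy())
        roots = np.asarray(roots)
        np.testing.assert_allclose(roots.mean(axis=0), 1 / 3, atol=0.02)
        np.testing.assert_allclose(roots.var(axis=0), 2 / 36, atol=0.01)

    def test_birth_death_move_bookkeeping(self, prior_state, rng):
        for _ in range(300):
            iwe_birth_death_move(prior_state, 0, rng)
        prior_state.configs[0].validate(prior_state.tree)


class TestRunMCMC:
    def test_null_mode_never_produces_iwes(self, rng):
        design = SimulationDesign(
            n_islands=4, site_range=(5, 10),
            theta=GlobalParams(0.3, 1.0, 0.0),
        )
        ds = simulate_dataset(design, rng)
        trace = run_mcmc(
            ds.tree, ds.data, n_sweeps=300, burn_in=100, thin=5, mode="null", seed=2
        )
        assert np.all(trace.iwe_counts == 0)
        assert np.all(trace.mu == 0.0)

    def test_same_seed_bitwise_reproducible(self, rng):
        ds = simulate_dataset(SimulationDesign(n_islands=3, site_range=(5, 10)), rng)
        t1 = run_mcmc(ds.tree, ds.data, n_sweeps=400, burn_in=100, thin=5, seed=9)
        t2 = run_mcmc(ds.tree, ds.data, n_sweeps=400, burn_in=100, thin=5, seed=9)
        np.testing.assert_array_equal(t1.loglik, t2.loglik)
        np.testing.assert_array_equal(t1.branch_lengths, t2.branch_lengths)
        np.testing.assert_array_equal(t1.iwe_counts, t2.iwe_counts)

    def test_python_engine_cache_contract_and_agreement(self, rng):
        ds = simulate_dataset(
            SimulationDesign(
                n_islands=3, site_range=(25, 35),
                theta=GlobalParams(0.2, 1.5, 2.0),
                branch_lengths=tuple([0.4] * 6),
            ),
            rng,
        )
        # python engine checks its cached likelihoods against full recomputation
        tp = run_mcmc(
            ds.tree, ds.data, n_sweeps=1500, burn_in=500, thin=5, seed=4, engine="python"
        )
        tn = run_mcmc(
            ds.tree, ds.data, n_sweeps=15000, burn_in=5000, thin=25, seed=4, engine="numba"
        )
        # the two engines sample the same posterior (well-identified summaries)
        assert abs(tp.loglik.mean() - tn.loglik.mean()) < 6.0
        np.testing.assert_allclose(
            np.log(tp.branch_lengths).mean(axis=0),
            np.log(tn.branch_lengths).mean(axis=0),
            atol=0.6,
        )

    def test_kernel_final_cache_matches_full_recomputation(self, rng):
        """After thousands of incremental cache updates, the kernel's per-island
        log-likelihoods must equal a from-scratch recomputation."""
        from iwesse.likelihood import island_log_likelihood

        ds = simulate_dataset(
            SimulationDesign(n_islands=4, site_range=(5, 12),
                             theta=GlobalParams(0.3, 1.0, 3.0)),
            rng,
        )
        trace = run_mcmc(ds.tree, ds.data, n_sweeps=3000, burn_in=1500, thin=10, seed=6)
        final = trace.meta["final"]
        theta = GlobalParams(final["r"], final["alpha"], max(final["mu"], 1e-300))
        final_tree = ds.tree.with_lengths(final["branch_lengths"])
        for i in range(4):
            fresh = island_log_likelihood(
                ds.data.island_states(i), final["configs"][i], final_tree, theta
            )
            assert final["island_ll"][i] == pytest.approx(fresh, abs=1e-9)
        assert np.all(np.isfinite(trace.loglik))

    def test_nonfinite_initial_likelihood_names_island(self, rng):
        tree = Tree.from_newick("(tipA:1.0)root;")
        # invariant-only model cannot explain a state change along the branch
        states = np.array([[0], [2]], dtype=np.int8)
        data = MethylationData(states, [0, 1], island_names=["cpg7"])
        init = MCMCState(
            tree=tree,
            data=data,
            theta=GlobalParams(1.0, 1.0, 0.5),
            configs=[IslandConfig(np.ones(3) / 3, {})],
        )
        with pytest.raises(ValueError, match="cpg7"), pytest.warns(RuntimeWarning):
            run_mcmc(tree, data, n_sweeps=10, burn_in=5, seed=0, init=init)

    def test_event_capacity_resize_mid_run(self, rng):
        # a high-rate island forces event counts past the initial capacity;
        # the sampler must grow storage and continue deterministically
        ds = simulate_dataset(
            SimulationDesign(
                n_islands=2, site_range=(4, 6),
                theta=GlobalParams(0.2, 1.0, 60.0),
                branch_lengths=tuple([0.5] * 6),
            ),
            rng,
        )
        t1 = run_mcmc(ds.tree, ds.data, n_sweeps=1200, burn_in=600, thin=10, seed=3)
        assert t1.total_iwe_counts.max() > 64  # beyond one initial capacity block
        t2 = run_mcmc(ds.tree, ds.data, n_sweeps=1200, burn_in=600, thin=10, seed=3)
        np.testing.assert_array_equal(t1.iwe_counts, t2.iwe_counts)


class TestPosteriorCorrectness:
    def test_single_branch_length_posterior_matches_quadrature(self, rng):
        """Null-model posterior of one branch length vs 1-D numerical integration."""
        from iwesse.likelihood import island_log_likelihood

        pi = np.array([0.25, 0.35, 0.40])
        theta = GlobalParams(0.0, 1e9, 0.0)
        n_sites = 40
        tree0 = Tree.from_newick("(tipA:0.4)root;")
        cfg = IslandConfig(pi)
        states = np.stack(
            [rng.choice(3, size=n_sites, p=pi), rng.choice(3, size=n_sites, p=pi)]
        ).astype(np.int8)
        data = MethylationData(states, [0, n_sites])
        pri = Priors(log_length=(-1.0, 1.0))
        pc = ProposalConfig(update_r=False, update_alpha=False, update_mu=False,
                            update_frequencies=False, update_iwe=False)
        init = MCMCState(tree=tree0, data=data, theta=theta, configs=[cfg],
                         priors=pri, proposals=pc, mode="null")
        trace = run_mcmc(
            tree0, data, n_sweeps=400_000, burn_in=20_000, thin=100, seed=12,
            mode="null", priors=pri, proposals=pc, init=init,
        )
        ells = np.linspace(-5, 3, 400)
        logpost = np.array(
            [
                island_log_likelihood(states, cfg, tree0.with_lengths([math.exp(e)]), theta)
                - 0.5 * (e + 1.0) ** 2
                for e in ells
            ]
        )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_ref = float((ells * w).sum())
        sd_ref = float(np.sqrt(((ells - mean_ref) ** 2 * w).sum()))
        samp = np.log(trace.branch_lengths[:, 0])
        assert samp.mean() == pytest.approx(mean_ref, abs=0.05)
        assert samp.std() == pytest.approx(sd_ref, rel=0.15)

    def test_mu_posterior_without_data_matches_quadrature(self):
        """mu's conditional is prior x exp(-mu N L_tot) when no IWEs are present."""
        tree = Tree.balanced_quartet().with_lengths(np.full(6, 0.5))
        data = empty_data(10)
        pri = Priors(log_mu=(0.0, 1.0))
        pc = ProposalConfig(update_lengths=False, update_r=False, update_alpha=False,
                            update_frequencies=False, update_iwe=False)
        init = MCMCState(
            tree=tree, data=data, theta=GlobalParams(0.5, 1.0, 1.0),
            configs=[IslandConfig(np.ones(3) / 3, {}) for _ in range(10)],
            priors=pri, proposals=pc, likelihood_on=False,
        )
        trace = run_mcmc(
            tree, data, n_sweeps=400_000, burn_in=10_000, thin=100, seed=13,
            priors=pri, proposals=pc, likelihood_on=False, init=init,
        )
        NL = 10 * 3.0
        lms = np.linspace(-6, 3, 600)
        logpost = -0.5 * lms**2 - NL * np.exp(lms)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_ref = float((lms * w).sum())
        samp = np.log(trace.mu)
        assert samp.mean() == pytest.approx(mean_ref, abs=0.05)
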