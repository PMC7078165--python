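"""Synthetic-data generators: birth-death trees, clock processes,
substitution data, calibrations, and episodic trees."""

import numpy as np
import pytest
from scipy import stats

import chronodiv as cd
from chronodiv.simulate import (anchor_calibrations_to_tree,
                                cir_stationary_sample, cir_transition_sample)


class TestBDTree:
    def test_pure_birth_tip_count_forced(self):
        tt = cd.simulate_bd_tree(cd.BDParams(lam=0.2, mu=0.0, n=8), seed=1)
        assert tt.tree.n_leaves == 8
        assert len(tt.tree.internal_ids()) == 7

    def test_deterministic_under_seed(self):
        a = cd.simulate_bd_tree(cd.BDParams(lam=0.2, mu=0.1, n=15), seed=5)
        b = cd.simulate_bd_tree(cd.BDParams(lam=0.2, mu=0.1, n=15), seed=5)
        assert a.to_newick() == b.to_newick()

    def test_pure_birth_expected_tip_count(self):
        """E[N] = exp(lam*T) for a pure-birth process from one lineage."""
        counts = [cd.simulate_bd_tree(cd.BDParams(lam=0.1, mu=0.0, T=30.0),
                                      seed=5000 + i, min_tips=1).tree.n_leaves
                  for i in range(2000)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - np.exp(3.0)) < 3 * se + 0.3

    def test_conditioned_node_age_distribution(self):
        """Non-root node ages given the root age follow F'(t)/F(t1)."""
        lam, mu, t1 = 0.2, 0.1, 40.0
        ages = []
        for i in range(300):
            tt = cd.simulate_bd_tree(cd.BDParams(lam=lam, mu=mu, n=50),
                                     seed=i, root_age=t1)
            ages.extend(tt.ages[j] for j in tt.tree.internal_ids() if j != 0)
        cdf = lambda t: (cd.bd_depth_cdf(t, lam, mu, 1.0)
                         / cd.bd_depth_cdf(t1, lam, mu, 1.0))
        assert stats.kstest(np.array(ages), cdf).pvalue > 0.01

    def test_yule_conditioned_order_statistics(self):
        """Pure-birth node ages: truncated-exponential order statistics."""
        lam, t1 = 0.15, 30.0
        ages = []
        for i in range(400):
            tt = cd.simulate_bd_tree(cd.BDParams(lam=lam, mu=0.0, n=20),
                                     seed=i, root_age=t1)
            ages.extend(tt.ages[j] for j in tt.tree.internal_ids() if j != 0)
        z = 1 - np.exp(-lam * t1)
        cdf = lambda t: (1 - np.exp(-lam * np.asarray(t))) / z
        assert stats.kstest(np.array(ages), cdf).pvalue > 0.01

    def test_rho_subsampling_reduces_tips(self):
        full = cd.simulate_bd_tree(cd.BDParams(lam=0.3, mu=0.0, T=25.0),
                                   seed=3)
        sub = cd.simulate_bd_tree(cd.BDParams(lam=0.3, mu=0.0, T=25.0,
                                              rho=0.3), seed=3)
        assert sub.tree.n_leaves < full.tree.n_leaves

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            cd.BDParams(lam=0.0, mu=0.1, n=5)
        with pytest.raises(ValueError):
            cd.BDParams(lam=0.1, mu=0.0)          # neither n nor T
        with pytest.raises(ValueError):
            cd.BDParams(lam=0.1, mu=0.2, n=10)    # subcritical n-mode


class TestClockProcesses:
    def test_strict_clock_constant(self, bd_timetree):
        r = cd.simulate_rates(bd_timetree,
                              cd.ClockParams(model="strict", mean_rate=0.002),
                              seed=0)
        assert np.allclose(r.rates[1:], 0.002)

    def test_ugam_moments(self):
        """Gamma multiplier: mean m, variance v (about 1e5 branches)."""
        tt = cd.simulate_bd_tree(cd.BDParams(lam=5.0, mu=0.0, n=50001),
                                 seed=7)
        r = cd.simulate_rates(
            tt, cd.ClockParams(model="ugam", mean_rate=1.0, v=0.25), seed=1)
        x = r.rates[1:]
        n = x.size
        assert abs(x.mean() - 1.0) < 3 * np.sqrt(0.25 / n)
        assert abs(x.var() - 0.25) < 3 * 0.25 * np.sqrt(2.0 / n) * 3

    def test_ugam_exchangeable(self, bd_timetree):
        """Permuting branch ids leaves marginal statistics unchanged."""
        p = cd.ClockParams(model="ugam", mean_rate=0.01, v=0.5)
        draws = np.array([cd.simulate_rates(bd_timetree, p, seed=s).rates[1:]
                          for s in range(400)])
        means = draws.mean(axis=0)
        assert means.std() / means.mean() < 0.1

    def test_cir_stationary_convergence(self):
        """Long transition converges to the stationary gamma (mean m, var v)."""
        m, v, theta = 0.002, 1e-6, 0.05
        vals = []
        for i in range(2000):
            g = np.random.default_rng(i)
            r0 = cir_stationary_sample(m, v, g)
            vals.append(cir_transition_sample(r0, 500.0, m, v, theta, g))
        sh, sc = m * m / v, v / m
        assert stats.kstest(vals, "gamma", args=(sh, 0, sc)).pvalue > 0.01

    def test_cir_autocorrelation_structure(self):
        """Parent and child branch rates correlate under CIR, not UGAM."""
        tt = cd.simulate_bd_tree(cd.BDParams(lam=0.3, mu=0.0, n=200), seed=9)
        m = 0.002
        cir = cd.simulate_rates(tt, cd.ClockParams(
            model="cir", mean_rate=m, v=4 * m * m, theta=0.05), seed=10)
        ugam = cd.simulate_rates(tt, cd.ClockParams(
            model="ugam", mean_rate=m, v=4.0), seed=10)
        pairs_c, pairs_u = [], []
        for i in range(1, tt.tree.n_nodes):
            p = tt.tree.parent[i]
            if p != 0:
                pairs_c.append((cir.rates[p], cir.rates[i]))
                pairs_u.append((ugam.rates[p], ugam.rates[i]))
        rc = np.corrcoef(np.array(pairs_c).T)[0, 1]
        ru = np.corrcoef(np.array(pairs_u).T)[0, 1]
        assert rc > 0.3
        assert abs(ru) < 0.2

    def test_invalid_clock_params(self):
        with pytest.raises(ValueError):
            cd.ClockParams(model="cir", mean_rate=-1.0)
        with pytest.raises(ValueError):
            cd.ClockParams(model="ugam", mean_rate=0.1, v=0.0)


class TestSubstData:
    def test_poisson_mean_oracle(self):
        """rate 0.001 x duration 50 x L=1e4: mean length 0.05 over reps."""
        tt = cd.timetree_from_newick("((A:50,B:50):10,C:60);")
        r = cd.simulate_rates(tt, cd.ClockParams(model="strict",
                                                 mean_rate=0.001), seed=0)
        L = 10 ** 4
        a_id = tt.tree.id_of("A")
        obs = [cd.simulate_subst_data(tt, r, L=L, mode="lengths",
                                      seed=i).lengths[a_id]
               for i in range(1000)]
        se = np.sqrt(0.05 / L / len(obs))
        assert abs(np.mean(obs) - 0.05) < 3 * se

    def test_near_zero_duration_branch(self):
        tt = cd.timetree_from_newick("((A:1e-12,B:1e-12):10,C:10);")
        r = cd.simulate_rates(tt, cd.ClockParams(model="strict",
                                                 mean_rate=0.001), seed=0)
        d = cd.simulate_subst_data(tt, r, L=1000, mode="lengths", seed=1)
        assert d.lengths[tt.tree.id_of("A")] == 0.0

    def test_alignment_identical_at_zero_distance(self):
        tt = cd.timetree_from_newick("((A:1e-12,B:1e-12):10,C:10);")
        r = cd.simulate_rates(tt, cd.ClockParams(model="strict",
                                                 mean_rate=0.002), seed=0)
        d = cd.simulate_subst_data(tt, r, L=500, mode="alignment", seed=2)
        assert d.sequences["A"] == d.sequences["B"]
        assert d.sequences["A"] != d.sequences["C"]

    def test_se_matches_poisson(self, bd_timetree):
        r = cd.simulate_rates(bd_timetree,
                              cd.ClockParams(model="strict", mean_rate=0.01),
                              seed=0)
        d = cd.simulate_subst_data(bd_timetree, r, L=1000, seed=3)
        i = 1
        assert d.se[i] == pytest.approx(np.sqrt(d.lengths[i] / 1000))


class TestMakeCalibrations:
    def test_zero_slack_pins_truth(self, bd_timetree):
        cals = cd.make_calibrations(bd_timetree, [0], style="interval",
                                    slack=0.0, seed=0)
        assert cals[0].min_age == cals[0].max_age == bd_timetree.root_age

    def test_bounds_bracket_truth(self, bd_timetree):
        """slack=0.2: min in [0.8a, a], max in [a, 1.2a], always."""
        internal = bd_timetree.tree.internal_ids()
        for s in range(50):
            cals = cd.make_calibrations(bd_timetree, internal,
                                        style="interval", slack=0.2, seed=s)
            for cal, node in zip(cals, internal):
                a = bd_timetree.ages[node]
                assert 0.8 * a <= cal.min_age <= a <= cal.max_age <= 1.2 * a

    def test_min_only_style(self, bd_timetree):
        cals = cd.make_calibrations(bd_timetree, bd_timetree.tree.internal_ids(),
                                    style="min-only", slack=0.1, seed=1)
        assert all(c.max_age is None for c in cals)

    def test_leaf_node_rejected(self, bd_timetree):
        leaf = bd_timetree.tree.leaf_ids()[0]
        with pytest.raises(ValueError, match="leaf"):
            cd.make_calibrations(bd_timetree, [leaf])

    def test_mrca_anchors_resolve_to_node(self, bd_timetree):
        internal = bd_timetree.tree.internal_ids()
        cals = cd.make_calibrations(bd_timetree, internal, seed=2)
        for cal, node in zip(cals, internal):
            assert bd_timetree.tree.mrca(cal.leaf_a, cal.leaf_b) == node

    def test_anchor_fixture_to_synthetic_tree(self):
        tt = cd.simulate_bd_tree(cd.BDParams(lam=0.02, mu=0.005, n=89),
                                 seed=13)
        cals = anchor_calibrations_to_tree(tt, cd.load_default_calibrations())
        nodes = {tt.tree.mrca(c.leaf_a, c.leaf_b) for c in cals}
        assert len(nodes) == len(cals) == 28


class TestEpisodicTree:
    def test_single_bin_equals_constant_rate(self):
        er = cd.EpisodicRates.equal_bins(30.0, [0.12], [0.04])
        a = cd.simulate_episodic_tree(er, rho=1.0, seed=77)
        b = cd.simulate_bd_tree(cd.BDParams(lam=0.12, mu=0.04, T=30.0),
                                seed=77)
        assert a.to_newick() == b.to_newick()

    def test_equal_bins_match_constant_tip_counts(self):
        """Chi-square: tip counts indistinguishable from constant rates."""
        er = cd.EpisodicRates.equal_bins(25.0, [0.1] * 5, [0.03] * 5)
        epi = [cd.simulate_episodic_tree(er, seed=3000 + i,
                                         retry_cap=50).tree.n_leaves
               for i in range(2000)]
        const = [cd.simulate_bd_tree(
            cd.BDParams(lam=0.1, mu=0.03, T=25.0),
            seed=9000 + i).tree.n_leaves for i in range(2000)]
        bins = [2, 3, 4, 6, 8, 12, 20, 10 ** 6]
        o1, _ = np.histogram(epi, bins)
        o2, _ = np.histogram(const, bins)
        assert stats.chi2_contingency(np.vstack([o1, o2])).pvalue > 0.01

    def test_doubled_young_speciation_increases_tips(self):
        base = cd.EpisodicRates.equal_bins(25.0, [0.1] * 5, [1e-9] * 5)
        boosted = cd.EpisodicRates(
            base.edges, np.array([0.2, 0.1, 0.1, 0.1, 0.1]),
            base.mu.copy())
        n_base = np.mean([cd.simulate_episodic_tree(
            base, seed=100 + i).tree.n_leaves for i in range(400)])
        n_boost = np.mean([cd.simulate_episodic_tree(
            boosted, seed=100 + i).tree.n_leaves for i in range(400)])
        assert n_boost > n_base

    def test_extinction_retry_cap(self):
        hopeless = cd.EpisodicRates.equal_bins(50.0, [1e-6], [5.0])
        with pytest.raises(RuntimeError, match="attempts"):
            cd.simulate_episodic_tree(hopeless, seed=0, retry_cap=5)
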