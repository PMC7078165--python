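"""Calibration densities, birth-death age prior, clock likelihoods,
dating MCMC, and clock-model cross-validation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import chronodiv as cd
from chronodiv.dating import _bd_logf, cir_transition_logpdf


def quad_mass(dens, a, b):
    return integrate.quad(lambda x: float(dens.pdf(x)), a, b, limit=300)[0]


class TestCalibrationDensity:
    def test_interval_five_percent_outside(self):
        """min 432.6, max 509 with default soft mass: 5% outside by quadrature."""
        d = cd.calibration_density(cd.Calibration("x", "a", "b", 432.6, 509))
        outside = quad_mass(d, 0, 432.6) + quad_mass(d, 509, np.inf)
        assert outside == pytest.approx(0.05, abs=1e-6)
        total = outside + quad_mass(d, 432.6, 509)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_hard_bounds_limit(self):
        d = cd.calibration_density(
            cd.Calibration("x", "a", "b", 100.0, 200.0, soft_mass=0.0))
        assert float(d.pdf(np.array(99.0))) == 0.0
        assert float(d.pdf(np.array(201.0))) == 0.0
        assert float(d.pdf(np.array(150.0))) == pytest.approx(0.01)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_calibrations_integrate_to_one(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            mn = float(rng.uniform(10, 500))
            style = rng.integers(3)
            if style == 0:
                cal = cd.Calibration("c", "a", "b", mn,
                                     mn * float(rng.uniform(1.05, 2.0)),
                                     soft_mass=float(rng.uniform(0.01, 0.3)))
            elif style == 1:
                cal = cd.Calibration("c", "a", "b", mn, None,
                                     soft_mass=float(rng.uniform(0.01, 0.3)))
            else:
                cal = cd.Calibration("c", "a", "b", None, mn,
                                     soft_mass=float(rng.uniform(0.01, 0.3)))
            d = cd.calibration_density(cal)
            u = np.linspace(1e-6, 1 - 1e-6, 101)
            assert np.allclose(d.cdf(d.ppf(u)), u, atol=1e-9)
            assert d.mass_outside() == pytest.approx(cal.soft_mass, abs=1e-9)

    def test_one_sided_tail_masses(self):
        d_min = cd.calibration_density(cd.Calibration("m", "a", "b", 500.5, None))
        assert float(d_min.cdf(np.array(500.5))) == pytest.approx(0.05, abs=1e-9)
        d_max = cd.calibration_density(cd.Calibration("M", "a", "b", None, 538.8))
        assert 1 - float(d_max.cdf(np.array(538.8))) == pytest.approx(0.05, abs=1e-9)

    def test_sampling_matches_cdf(self):
        d = cd.calibration_density(cd.Calibration("x", "a", "b", 40.0, 60.0))
        s = d.rvs(np.random.default_rng(1), 20000)
        assert stats.kstest(s, lambda x: d.cdf(x)).pvalue > 0.01

    def test_soft_mass_one_rejected(self):
        with pytest.raises(cd.CalibrationError):
            cd.Calibration("x", "a", "b", 10.0, 20.0, soft_mass=1.0)


class TestBDNodeAgePrior:
    def test_yule_closed_form(self):
        """mu=0: truncated-exponential order-statistics density."""
        tt = cd.simulate_bd_tree(cd.BDParams(lam=0.3, mu=0.0, n=10), seed=3)
        lam, t1 = 0.3, tt.root_age
        hand = sum(
            math.log(lam * math.exp(-lam * tt.ages[i])
                     / (1 - math.exp(-lam * t1)))
            for i in tt.tree.internal_ids() if i != 0)
        assert cd.bd_node_age_logprior(tt, lam, 0.0) == pytest.approx(hand)

    def test_critical_limit_continuous(self, bd_timetree):
        vals = [cd.bd_node_age_logprior(bd_timetree, 0.1 + eps, 0.1)
                for eps in (1e-3, 1e-6, 0.0)]
        assert all(np.isfinite(vals))
        assert abs(vals[1] - vals[2]) < 1e-3

    def test_monte_carlo_matches_simulator(self):
        """Histogram of simulated conditioned ages matches exp(log prior)."""
        lam, mu, t1 = 0.2, 0.1, 40.0
        ages = []
        for i in range(200):
            tt = cd.simulate_bd_tree(cd.BDParams(lam=lam, mu=mu, n=40),
                                     seed=i, root_age=t1)
            ages.extend(tt.ages[j] for j in tt.tree.internal_ids() if j != 0)
        from scipy.integrate import cumulative_trapezoid
        grid = np.linspace(0.0, t1, 8001)
        dens = np.exp([_bd_logf(t, lam, mu, 1.0) for t in grid])
        cdf_grid = cumulative_trapezoid(dens, grid, initial=0.0)
        cdf_grid /= cdf_grid[-1]
        interp = lambda x: np.interp(x, grid, cdf_grid)
        assert stats.kstest(np.array(ages), interp).pvalue > 0.01

    def test_violated_ordering_minus_inf(self):
        tree = cd.read_newick("((A,B),C);")
        tt = cd.TimeTree(tree, np.array([10.0, 4.0, 0, 0, 0]))
        tt.ages[1] = 12.0  # corrupt after validation
        with pytest.warns(UserWarning):
            assert cd.bd_node_age_logprior(tt, 0.2, 0.1) == -np.inf


class TestClockLoglik:
    def test_gaussian_mode_attains_maximum(self):
        t2 = cd.timetree_from_newick("(A:10,B:10);")
        d = cd.SubstData(mode="lengths", L=100,
                         lengths=np.array([np.nan, 0.1, 0.2]),
                         se=np.array([np.nan, 0.03, 0.04]))
        exact = cd.BranchRates(np.array([np.nan, 0.01, 0.02]))
        best = cd.clock_loglik(d, t2, exact, mode="gaussian")
        assert best == pytest.approx(
            -math.log(0.03) - math.log(0.04) - math.log(2 * math.pi))
        worse = cd.BranchRates(np.array([np.nan, 0.012, 0.02]))
        assert cd.clock_loglik(d, t2, worse, mode="gaussian") < best

    def test_two_leaf_enumeration_oracle(self):
        """One variable site: sum over 20 root states of transition products."""
        t2 = cd.timetree_from_newick("(A:10,B:10);")
        rates = cd.BranchRates(np.array([np.nan, 0.01, 0.02]))
        d = cd.SubstData(mode="alignment", L=1, sequences={"A": "A", "B": "R"})
        ll = cd.clock_loglik(d, t2, rates)
        nu = 20 / 19

        def p(b, same):
            e = math.exp(-nu * b)
            return e + (1 - e) / 20 if same else (1 - e) / 20

        s = sum((1 / 20) * p(0.1, r == 0) * p(0.2, r == 1) for r in range(20))
        assert ll == pytest.approx(math.log(s), abs=1e-10)

    def test_zero_branch_length_limit(self):
        """Identical sequences, rates -> 0: L * log(1/20)."""
        t2 = cd.timetree_from_newick("(A:10,B:10);")
        d = cd.SubstData(mode="alignment", L=5,
                         sequences={"A": "ARNDC", "B": "ARNDC"})
        r0 = cd.BranchRates(np.array([np.nan, 1e-12, 1e-12]))
        assert cd.clock_loglik(d, t2, r0) == pytest.approx(
            5 * math.log(1 / 20), abs=1e-6)

    def test_missing_branch_data_named(self, bd_timetree):
        lengths = np.full(bd_timetree.tree.n_nodes, 0.01)
        lengths[3] = np.nan
        d = cd.SubstData(mode="lengths", L=100, lengths=lengths)
        r = cd.simulate_rates(bd_timetree,
                              cd.ClockParams(model="strict", mean_rate=0.001),
                              seed=0)
        with pytest.raises(ValueError, match="node 3"):
            cd.clock_loglik(d, bd_timetree, r)


class TestCIRTransitionDensity:
    def test_integrates_to_one(self):
        m, v, theta = 0.002, 4e-6, 0.1
        f = lambda r1: math.exp(cir_transition_logpdf(r1, 0.003, 5.0,
                                                      m, v, theta))
        total = integrate.quad(f, 0, 0.05, limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_simulated_transitions(self):
        from chronodiv.simulate import cir_transition_sample
        m, v, theta, r0, dt = 0.002, 4e-6, 0.1, 0.003, 5.0
        g = np.random.default_rng(0)
        draws = [cir_transition_sample(r0, dt, m, v, theta, g)
                 for _ in range(4000)]
        grid = np.linspace(1e-5, 0.02, 500)
        pdf = np.exp([cir_transition_logpdf(x, r0, dt, m, v, theta)
                      for x in grid])
        cdfg = np.cumsum(pdf) * (grid[1] - grid[0])
        cdfg /= cdfg[-1]
        interp = lambda x: np.clip(np.interp(x, grid, cdfg), 0, 1)
        assert stats.kstest(draws, interp).pvalue > 0.01


class TestDatingModel:
    def test_duplicate_anchor_rejected(self, bd_timetree):
        cals = cd.make_calibrations(bd_timetree, [0], seed=0)
        model = cd.DatingModel(tree=bd_timetree.tree,
                               calibrations=cals + cals)
        with pytest.raises(ValueError, match="same node"):
            model.resolve_calibrations()

    def test_hard_bound_conflict_preflight(self, bd_timetree):
        tree = bd_timetree.tree
        # root hard max below a child's hard min
        kids = tree.children[0]
        a = tree.names[tree.clade_leaves(kids[0])[0]]
        b = tree.names[tree.clade_leaves(kids[1])[0]]
        child = [i for i in tree.internal_ids() if i != 0][0]
        ck = tree.children[child]
        ca = tree.names[tree.clade_leaves(ck[0])[0]]
        cb = tree.names[tree.clade_leaves(ck[1])[0]]
        cals = [cd.Calibration("root", a, b, None, 10.0, soft_mass=0.0),
                cd.Calibration("child", ca, cb, 20.0, None, soft_mass=0.0)]
        model = cd.DatingModel(tree=tree, calibrations=cals)
        with pytest.raises(ValueError, match="conflict"):
            model.resolve_calibrations()

    def test_zero_iterations_structured_error(self, bd_timetree):
        cals = cd.make_calibrations(bd_timetree, [0], seed=0, slack=0.2)
        model = cd.DatingModel(tree=bd_timetree.tree, calibrations=cals,
                               prior_only=True)
        with pytest.raises(ValueError, match="burn-in"):
            cd.run_dating_mcmc(model, iterations=0, seed=1)


class TestDatingMCMC:
    def test_prior_only_leaf_order_invariance(self):
        """Root-age marginal unchanged under leaf relabeling."""
        tt = cd.simulate_bd_tree(cd.BDParams(lam=0.15, mu=0.0, n=6), seed=2)
        tree = tt.tree
        kids = tree.children[0]
        a = tree.names[tree.clade_leaves(kids[0])[0]]
        b = tree.names[tree.clade_leaves(kids[1])[0]]
        cal = cd.Calibration("root", a, b, 30.0, 50.0)
        m1 = cd.DatingModel(tree=tree, calibrations=[cal], prior_only=True)
        tr1, _ = cd.run_dating_mcmc(m1, chains=1, iterations=4000, seed=3)
        # relabel leaves by swapping two names
        tree2 = tree.copy()
        la, lb = tree2.leaf_ids()[0], tree2.leaf_ids()[-1]
        tree2.names[la], tree2.names[lb] = tree2.names[lb], tree2.names[la]
        tree2._name_to_id = {tree2.names[i]: i for i in tree2.leaf_ids()}
        kids = tree2.children[0]
        a2 = tree2.names[tree2.clade_leaves(kids[0])[0]]
        b2 = tree2.names[tree2.clade_leaves(kids[1])[0]]
        cal2 = cd.Calibration("root", a2, b2, 30.0, 50.0)
        m2 = cd.DatingModel(tree=tree2, calibrations=[cal2], prior_only=True)
        tr2, _ = cd.run_dating_mcmc(m2, chains=1, iterations=4000, seed=3)
        assert stats.ks_2samp(tr1["age_0"][::8], tr2["age_0"][::8]).pvalue > 0.01

    def test_posterior_samples_respect_age_ordering(self, bd_timetree):
        rates = cd.simulate_rates(
            bd_timetree, cd.ClockParams(model="strict", mean_rate=0.002),
            seed=1)
        data = cd.simulate_subst_data(bd_timetree, rates, L=1000, seed=2)
        cals = cd.make_calibrations(bd_timetree, [0], slack=0.2, seed=3)
        model = cd.DatingModel(tree=bd_timetree.tree, data=data,
                               calibrations=cals, clock="strict")
        trace, _ = cd.run_dating_mcmc(model, chains=1, iterations=600, seed=4)
        tree = bd_timetree.tree
        for i in tree.internal_ids():
            p = tree.parent[i]
            if p >= 0:
                assert np.all(trace[f"age_{p}"] > trace[f"age_{i}"])

    def test_fixed_root_noiseless_strict_identifiable(self):
        """Point-calibrated root + noiseless data: ages within 1% of truth."""
        tt = cd.simulate_bd_tree(cd.BDParams(lam=0.2, mu=0.0, n=12), seed=8)
        m = 0.005
        rates = cd.simulate_rates(tt, cd.ClockParams(model="strict",
                                                     mean_rate=m), seed=0)
        dur = tt.durations()
        lengths = rates.rates * dur  # noiseless expectations
        data = cd.SubstData(mode="lengths", L=10 ** 6, lengths=lengths)
        cals = cd.make_calibrations(tt, [0], style="interval", slack=1e-4,
                                    seed=1)
        model = cd.DatingModel(tree=tt.tree, data=data, calibrations=cals,
                               clock="strict")
        trace, _ = cd.run_dating_mcmc(model, chains=1, iterations=3000,
                                      seed=5)
        for i in tt.tree.internal_ids():
            est = trace[f"age_{i}"].mean()
            assert abs(est - tt.ages[i]) <= 0.01 * tt.ages[i] + 0.01

    def test_ugam_clock_runs_and_converges_shape(self, bd_timetree):
        rates = cd.simulate_rates(
            bd_timetree, cd.ClockParams(model="ugam", mean_rate=0.002, v=0.3),
            seed=1)
        data = cd.simulate_subst_data(bd_timetree, rates, L=2000, seed=2)
        cals = cd.make_calibrations(bd_timetree, [0], slack=0.2, seed=3)
        model = cd.DatingModel(tree=bd_timetree.tree, data=data,
                               calibrations=cals, clock="ugam")
        trace, report = cd.run_dating_mcmc(model, chains=2, iterations=500,
                                           seed=6)
        assert "rate_var" in trace.samples
        assert set(report.ess) == set(report.rel_diff)

    def test_summarize_ages_schema(self, bd_timetree):
        cals = cd.make_calibrations(bd_timetree, [0], slack=0.2, seed=0)
        model = cd.DatingModel(tree=bd_timetree.tree, calibrations=cals,
                               prior_only=True)
        trace, _ = cd.run_dating_mcmc(model, chains=1, iterations=500, seed=1)
        table, nexus = cd.summarize_ages(trace, bd_timetree.tree)
        assert list(table.columns) == ["taxon", "mean_age_Ma",
                                       "hpd_lower_Ma", "hpd_upper_Ma"]
        assert nexus.startswith("#NEXUS")

    def test_summarize_constant_trace(self):
        tree = cd.read_newick("((A,B),C);")
        trace = cd.PosteriorTrace({"age_0": np.full(100, 10.0),
                                   "age_1": np.full(100, 4.0)})
        table, _ = cd.summarize_ages(trace, tree)
        assert table.loc[0, "mean_age_Ma"] == 10.0
        assert table.loc[0, "hpd_lower_Ma"] == table.loc[0, "hpd_upper_Ma"]

    def test_summarize_uniform_grid_hpd(self):
        tree = cd.read_newick("((A,B),C);")
        grid = np.arange(475.0, 495.0)  # 20 evenly spaced samples
        trace = cd.PosteriorTrace({"age_0": grid,
                                   "age_1": grid / 2})
        table, _ = cd.summarize_ages(trace, tree)
        lo, hi = table.loc[0, "hpd_lower_Ma"], table.loc[0, "hpd_upper_Ma"]
        assert hi - lo == 18.0  # ceil(0.95*20)=19 samples -> width 18


class TestConvergenceReport:
    def test_verdict_rule(self):
        rep = cd.ConvergenceReport(ess={"a": 100.0}, rel_diff={"a": 0.2})
        assert rep.passed
        assert not cd.ConvergenceReport(ess={"a": 10.0},
                                        rel_diff={"a": 0.2}).passed
        assert not cd.ConvergenceReport(ess={"a": 100.0},
                                        rel_diff={"a": 1.5}).passed


@pytest.fixture(scope="module")
def ugam_data():
    tt = cd.simulate_bd_tree(cd.BDParams(lam=0.15, mu=0.05, n=40), seed=5)
    r = cd.simulate_rates(tt, cd.ClockParams(model="ugam",
                                             mean_rate=0.002, v=1.0),
                          seed=6)
    data = cd.simulate_subst_data(tt, r, L=2000, mode="lengths", seed=7)
    return tt, data


class TestCrossValidation:
    def test_identical_models_zero_difference(self, ugam_data):
        tt, data = ugam_data
        cv = cd.cross_validate("ugam", "ugam", data, tt.tree, replicates=10,
                               seed=9, timetree=tt)
        assert abs(cv.mean) <= 2 * cv.se + 1e-9

    def test_ugam_recovered_over_strict(self, ugam_data):
        tt, data = ugam_data
        cv = cd.cross_validate("ugam", "strict", data, tt.tree,
                               replicates=10, seed=8, timetree=tt)
        assert cv.n_supporting_a >= 9
        assert cv.verdict == "A"

    def test_replicate_minimum(self, ugam_data):
        tt, data = ugam_data
        with pytest.raises(ValueError, match="replicates"):
            cd.cross_validate("ugam", "strict", data, tt.tree, replicates=1,
                              seed=0)

    def test_alignment_data_rejected(self, ugam_data):
        tt, _ = ugam_data
        d = cd.SubstData(mode="alignment", L=3,
                         sequences={nm: "ARN" for nm in tt.tree.leaf_names()})
        with pytest.raises(ValueError, match="branch-length"):
            cd.cross_validate("ugam", "strict", d, tt.tree, seed=0)
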