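"""Two-trait Brownian thermal-tolerance model: covariance, likelihood, MCMC."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import beringia as b
from beringia.thermal import (BMModel, MCMCConfig, ThermalModel, compare_models,
                              loglik, phylo_vcv, transform_vcv)

from conftest import random_trees


SIGMA = np.array([[300.0, 120.0], [120.0, 200.0]])


def gen_model(lam=0.925, beta=(-30.0, -15.0), model="B"):
    return BMModel(model=model, alpha=(-5.0, 15.0),
                   beta=beta if model == "B" else (0.0, 0.0),
                   sigma=SIGMA, lam=lam)


class TestVcv:
    def test_two_tip_star(self):
        t = b.read_newick("(A:1.5,B:2.5);")
        V, labels = phylo_vcv(t)
        i, j = labels.index("A"), labels.index("B")
        assert V[i, i] == pytest.approx(1.5)
        assert V[j, j] == pytest.approx(2.5)
        assert V[i, j] == 0.0

    def test_three_tip_shared_paths(self):
        t = b.read_newick("((A:1,B:1):1,C:2);")
        V, labels = phylo_vcv(t)
        i, j, k = (labels.index(x) for x in "ABC")
        assert V[i, j] == pytest.approx(1.0)
        assert V[i, i] == pytest.approx(2.0)
        assert V[i, k] == 0.0

    def test_matches_path_intersection_oracle(self):
        for tree in random_trees(30, 8, seed=900):
            V, labels = phylo_vcv(tree)
            d = tree.depths()
            idx = tree.tip_index()
            for la in labels:
                for lb in labels:
                    m = b.mrca(tree, {la, lb})
                    assert V[labels.index(la), labels.index(lb)] == pytest.approx(
                        d[m], abs=1e-12)


class TestTransforms:
    def test_identity(self):
        t = b.read_newick("((A:1,B:1):1,C:2);")
        V0, _, _ = transform_vcv(t)
        V1, _, _ = transform_vcv(t, 1.0, 1.0, 1.0)
        np.testing.assert_allclose(V0, V1)

    def test_lambda_zero_gives_star(self):
        t = b.read_newick("((A:1,B:1):1,C:2);")
        V, _, _ = transform_vcv(t, lam=0.0)
        np.testing.assert_allclose(V, np.diag(np.diag(V)))

    def test_kappa_zero_is_speciational(self):
        t = b.read_newick("((A:1,B:0.5):2,C:2);")
        V, depths, labels = transform_vcv(t, kappa=0.0)
        # every positive branch collapses to length 1: depth = #edges on path
        assert depths[labels.index("A")] == pytest.approx(2.0)
        assert depths[labels.index("C")] == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        t = b.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            transform_vcv(t, lam=1.2)
        with pytest.raises(ValueError):
            transform_vcv(t, delta=0.0)
        with pytest.raises(ValueError):
            transform_vcv(t, kappa=-0.5)


class TestLoglik:
    def test_single_trait_one_tip_closed_form(self):
        # one tip at depth t: logL = log N(x | alpha, sigma^2 t) per trait
        t = b.read_newick("(A:2.0,B:2.0);")
        model = BMModel(model="A", alpha=(1.0, 4.0), sigma=np.diag([2.0, 3.0]))
        x = np.array([[0.5, 5.0], [1.5, 3.0]])
        got = loglik(x, t, model)
        want = sum(
            multivariate_normal.logpdf(x[:, k], [model.alpha[k]] * 2,
                                       np.eye(2) * model.sigma[k, k] * 2.0)
            for k in range(2))
        assert got == pytest.approx(want, abs=1e-10)

    def test_model_b_with_zero_trend_equals_model_a(self):
        _, phylo = b.sim_tree(12, seed=2)
        traits, _ = b.sim_bm_traits(phylo, gen_model(), seed=3)
        x = traits.to_numpy()
        la = loglik(x, phylo, gen_model(model="A"))
        lb = loglik(x, phylo, gen_model(beta=(0.0, 0.0)))
        assert la == pytest.approx(lb, abs=1e-12)

    def test_matches_dense_mvn_oracle(self):
        for seed in range(5):
            _, phylo = b.sim_tree(9, seed=40 + seed)
            model = gen_model(lam=[1.0, 0.8, 0.5, 1.0, 0.3][seed])
            traits, _ = b.sim_bm_traits(phylo, model, seed=50 + seed)
            x = traits.to_numpy()
            got = loglik(x, phylo, model)
            V, depths, _ = transform_vcv(phylo, model.lam, 1.0, 1.0)
            mean = np.concatenate([model.alpha[0] + model.beta[0] * depths,
                                   model.alpha[1] + model.beta[1] * depths])
            cov = np.kron(model.sigma, V)
            y = np.concatenate([x[:, 0], x[:, 1]])
            want = multivariate_normal.logpdf(y, mean, cov)
            assert got == pytest.approx(want, abs=1e-8)

    def test_tip_permutation_invariance(self):
        _, phylo = b.sim_tree(10, seed=7)
        model = gen_model(lam=0.7)
        traits, _ = b.sim_bm_traits(phylo, model, seed=8)
        tm1 = ThermalModel(phylo, b.TaxonTable(traits), model="B")
        shuffled = traits.sample(frac=1.0, random_state=1)
        tm2 = ThermalModel(phylo, b.TaxonTable(shuffled), model="B")
        assert tm1.loglik(model) == pytest.approx(tm2.loglik(model), abs=1e-10)

    def test_generating_parameters_beat_perturbed(self):
        """logL(truth) > logL(perturbed) in >= 95 % of seeds."""
        wins = 0
        n_seeds = 100
        model = gen_model(lam=0.9)
        worse = BMModel(model="B", alpha=(-5.0, 15.0), beta=(-30.0, -15.0),
                        sigma=SIGMA * 3.0, lam=0.4)
        for seed in range(n_seeds):
            _, phylo = b.sim_tree(12, seed=seed)
            traits, _ = b.sim_bm_traits(phylo, model, seed=1000 + seed)
            x = traits.to_numpy()
            if loglik(x, phylo, model) > loglik(x, phylo, worse):
                wins += 1
        assert wins >= 95


class TestMCMC:
    def test_same_seed_same_stream(self):
        _, phylo = b.sim_tree(8, seed=21)
        traits, _ = b.sim_bm_traits(phylo, gen_model(), seed=22)
        tm = ThermalModel(phylo, traits.to_numpy(), model="B")
        cfg = MCMCConfig(iterations=3000, burn_in=500, sample_period=10, seed=5)
        r1 = tm.fit_mcmc(cfg)
        r2 = tm.fit_mcmc(cfg)
        assert r1.samples.equals(r2.samples)

    def test_star_tree_alpha_matches_gls(self):
        """Posterior mean of alpha within 3 MC-SEs of the GLS estimate.

        On a star tree with lambda fixed by the data structure (V diagonal),
        the GLS mean is the inverse-variance weighted tip mean per trait.
        """
        newick = "(" + ",".join(f"t{i}:{0.5 + 0.25 * i}" for i in range(8)) + ");"
        star = b.read_newick(newick, unit="subs/site")
        model = BMModel(model="A", alpha=(3.0, 9.0), sigma=np.diag([4.0, 2.0]))
        traits, _ = b.sim_bm_traits(star, model, seed=33)
        tm = ThermalModel(star, traits.to_numpy(), model="A")
        res = tm.fit_mcmc(MCMCConfig(iterations=60_000, burn_in=5_000,
                                     sample_period=20, seed=4))
        V, _, _ = transform_vcv(star)
        w = 1.0 / np.diag(V)
        x = traits.to_numpy()
        for k, name in enumerate(["alpha_cold", "alpha_warm"]):
            gls = float(np.sum(w * x[:, k]) / np.sum(w))
            col = res.samples[name].to_numpy()
            ess = max(len(col) / 10.0, 4.0)  # conservative autocorrelation haircut
            mcse = col.std() / math.sqrt(ess)
            assert abs(col.mean() - gls) < 3 * mcse + 0.05 * col.std()

    def test_parameter_recovery_within_3_sd(self):
        """lambda, beta_cold, sigma11 within 3 posterior SDs in >= 90 % of seeds."""
        hits = {"lambda": 0, "beta_cold": 0, "sigma11": 0}
        n_seeds = 10
        truth = {"lambda": 0.925, "beta_cold": -30.0, "sigma11": 300.0}
        for seed in range(n_seeds):
            _, phylo = b.sim_tree(25, seed=700 + seed)
            traits, _ = b.sim_bm_traits(phylo, gen_model(), seed=800 + seed)
            tm = ThermalModel(phylo, traits.to_numpy(), model="B")
            res = tm.fit_mcmc(MCMCConfig(iterations=40_000, burn_in=4_000,
                                         sample_period=40, seed=900 + seed))
            for name, true_val in truth.items():
                col = res.samples[name]
                if abs(col.mean() - true_val) <= 3 * col.std():
                    hits[name] += 1
        for name, k in hits.items():
            assert k >= 0.9 * n_seeds, f"{name}: {k}/{n_seeds}"

    def test_ultrametric_warning_for_model_b(self):
        chrono, _ = b.sim_tree(6, seed=1)
        traits, _ = b.sim_bm_traits(chrono, gen_model(model="A"), seed=2)
        with pytest.warns(UserWarning, match="ultrametric"):
            ThermalModel(chrono, traits.to_numpy(), model="B")


class TestModelComparison:
    def run_sims(self, gen, n_seeds=50):
        # 40 tips: large enough for the chi-square null of the LRT to hold
        choices = []
        for seed in range(n_seeds):
            _, phylo = b.sim_tree(40, seed=3000 + seed)
            traits, _ = b.sim_bm_traits(phylo, gen, seed=4000 + seed)
            x = traits.to_numpy()
            fa = ThermalModel(phylo, x, model="A").fit(starts=1)
            fb = ThermalModel(phylo, x, model="B").fit(starts=1)
            choices.append(compare_models(fa, fb).best)
        return choices

    def test_type_i_error_controlled(self):
        """Trendless data: model A chosen in >= 90 % of 50 seeds."""
        choices = self.run_sims(gen_model(model="A"))
        assert choices.count("A") >= 45

    def test_power_against_strong_trend(self):
        """Strong directional data: model B chosen in >= 90 % of 50 seeds."""
        choices = self.run_sims(gen_model(beta=(-300.0, -250.0)))
        assert choices.count("B") >= 45

    def test_identical_likelihoods_give_p_one(self):
        from beringia.thermal import ThermalMLFit
        fa = ThermalMLFit(gen_model(model="A"), loglik=-100.0, n_params=6,
                          converged=True)
        fb = ThermalMLFit(gen_model(beta=(0.0, 0.0)), loglik=-100.0,
                          n_params=8, converged=True)
        cmp = compare_models(fa, fb)
        assert cmp.lrt_stat == 0.0
        assert cmp.lrt_p == 1.0
        assert cmp.best == "A"


class TestAncestralStates:
    def test_constant_tips_recover_constant(self):
        t = b.read_newick("((A:0.9,B:1.1):1,(C:0.8,D:1.3):1.2);", unit="subs/site")
        x = np.full((4, 2), [5.0, 12.0])
        tm = ThermalModel(t, x, model="A")
        res = tm.fit_mcmc(MCMCConfig(iterations=20_000, burn_in=2_000,
                                     sample_period=20, seed=9))
        internal = [n for n in range(t.n_nodes)
                    if not t.is_tip(n) and n != t.root]
        states = res.ancestral_states(internal)
        for s in states:
            assert s.mean_cold == pytest.approx(5.0, abs=0.6)
            assert s.mean_warm == pytest.approx(12.0, abs=0.6)

    def test_tip_request_rejected(self):
        _, phylo = b.sim_tree(6, seed=10)
        traits, _ = b.sim_bm_traits(phylo, gen_model(), seed=11)
        tm = ThermalModel(phylo, traits.to_numpy(), model="B")
        res = tm.fit_mcmc(MCMCConfig(iterations=6000, burn_in=1000,
                                     sample_period=20, seed=12))
        with pytest.raises(ValueError, match="tip"):
            res.ancestral_states([int(phylo.tips[0])])

    def test_coverage_of_true_node_states(self):
        """95 % intervals cover the truth for >= 85 % of interior nodes."""
        covered = total = 0
        for seed in range(20):
            _, phylo = b.sim_tree(15, seed=1500 + seed)
            traits, states = b.sim_bm_traits(phylo, gen_model(), seed=1600 + seed)
            tm = ThermalModel(phylo, traits.to_numpy(), model="B")
            res = tm.fit_mcmc(MCMCConfig(iterations=15_000, burn_in=2_000,
                                         sample_period=25, seed=1700 + seed))
            internal = [n for n in range(phylo.n_nodes) if not phylo.is_tip(n)]
            for s in res.ancestral_states(internal, max_draws=200):
                lo, hi = s.ci_cold
                covered += int(lo <= states[s.node, 0] <= hi)
                lo, hi = s.ci_warm
                covered += int(lo <= states[s.node, 1] <= hi)
                total += 2
        assert covered / total >= 0.85

    def test_covariation_sign_preserved(self):
        """Positive generating trait covariance -> positively covarying
        ancestral reconstructions across nodes."""
        _, phylo = b.sim_tree(20, seed=61)
        traits, _ = b.sim_bm_traits(phylo, gen_model(), seed=62)
        tm = ThermalModel(phylo, traits.to_numpy(), model="B")
        res = tm.fit_mcmc(MCMCConfig(iterations=20_000, burn_in=2_000,
                                     sample_period=20, seed=63))
        assert res.posterior_mean("sigma12") > 0


class TestSteppingStone:
    def test_log_marginal_likelihood_properties_and_wiring(self):
        """The stepping-stone estimate is finite, bounded above by the ML
        log-likelihood (a marginal likelihood averages the likelihood over
        the prior), and feeds compare_models as a log Bayes factor."""
        _, phylo = b.sim_tree(10, seed=81)
        gen = gen_model(beta=(-300.0, -250.0))
        traits, _ = b.sim_bm_traits(phylo, gen, seed=82)
        x = traits.to_numpy()
        cfg = MCMCConfig(iterations=8_000, burn_in=1_000, sample_period=20,
                         seed=83)
        logml_a = ThermalModel(phylo, x, model="A").stepping_stone_logml(
            cfg, n_rungs=4)
        logml_b = ThermalModel(phylo, x, model="B").stepping_stone_logml(
            cfg, n_rungs=4)
        fa = ThermalModel(phylo, x, model="A").fit(starts=1)
        fb = ThermalModel(phylo, x, model="B").fit(starts=1)
        assert np.isfinite(logml_a) and np.isfinite(logml_b)
        assert logml_a <= fa.loglik + 1.0
        assert logml_b <= fb.loglik + 1.0
        cmp = compare_models(fa, fb, logml_a=logml_a, logml_b=logml_b)
        assert cmp.log_bayes_factor == pytest.approx(logml_b - logml_a)
        assert "Bayes factor" in cmp.summary()
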