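"""REML, mixed-model equations, prediction, and variance ratios."""

import warnings

import numpy as np
import pytest

import clonalmate as cm
from clonalmate.containers import DegenerateInputError
from clonalmate.models import VarianceComponents, solve_mme


def random_pd_grm(n, rng, n_ref=None):
    a = rng.normal(size=(n, n_ref or 2 * n))
    return a @ a.T / (n_ref or 2 * n)


class TestFitREML:
    def test_one_way_anova_closed_form(self):
        """With a block-of-ones GRM the model is a balanced one-way
        random-effects ANOVA, whose REML solution is closed-form:
        sigma2_e = MSW, sigma2_g = (MSB - MSW) / k."""
        rng = np.random.default_rng(71)
        groups, k = 30, 5
        n = groups * k
        g_eff = rng.normal(0, 2.0, size=groups)
        y = np.repeat(g_eff, k) + rng.normal(0, 1.0, size=n)
        grm = np.kron(np.eye(groups), np.ones((k, k)))
        vc, _ = cm.fit_reml(y, None, [grm], names=["group"])
        means = y.reshape(groups, k).mean(axis=1)
        msw = float(np.sum((y.reshape(groups, k) - means[:, None]) ** 2)
                    / (n - groups))
        msb = float(k * np.sum((means - means.mean()) ** 2) / (groups - 1))
        assert vc.residual == pytest.approx(msw, rel=1e-4)
        assert vc.components["group"] == pytest.approx((msb - msw) / k,
                                                       rel=1e-3)

    def test_zero_variance_phenotype_rejected(self):
        with pytest.raises(DegenerateInputError):
            cm.fit_reml(np.ones(10), None, [np.eye(10)])

    def test_nested_model_likelihood_ordering(self, mvn_fit_pair):
        vc1, _ = mvn_fit_pair["gblup"]
        vc3, _ = mvn_fit_pair["egblup"]
        assert vc3.log_likelihood >= vc1.log_likelihood - 1e-6

    def test_residual_absorption_by_nonadditive_terms(self, mvn_fit_pair):
        """Data carry real dominance/epistatic variance, so the extended
        model's residual cannot exceed the additive model's."""
        vc1, _ = mvn_fit_pair["gblup"]
        vc3, _ = mvn_fit_pair["egblup"]
        assert vc3.residual <= vc1.residual * (1 + 1e-6)


class TestSolveMME:
    def test_gls_route_matches_direct_inversion_oracle(self):
        rng = np.random.default_rng(73)
        n = 60
        g = random_pd_grm(n, rng)
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        vc = VarianceComponents(components={"additive": 1.7}, residual=0.8)
        fit = solve_mme(y, x, [g], vc)
        v = 1.7 * g + 0.8 * np.eye(n)
        vinv = np.linalg.inv(v)
        beta = np.linalg.inv(x.T @ vinv @ x) @ x.T @ vinv @ y
        u = 1.7 * g @ vinv @ (y - x @ beta)
        assert np.allclose(fit.beta_hat, beta, atol=1e-8)
        assert np.allclose(fit.u_hat, u, atol=1e-8)

    def test_explicit_mme_system_agrees_with_gls(self):
        """Dual route: the assembled coefficient system and the V-route
        give the same solutions on PD relationship matrices."""
        rng = np.random.default_rng(79)
        n = 50
        grms = [random_pd_grm(n, rng) for _ in range(3)]
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        vc = VarianceComponents(
            components={"additive": 1.2, "dominance": 0.5,
                        "epistatic": 0.3},
            residual=0.9)
        f_gls = solve_mme(y, x, grms, vc)
        f_mme = solve_mme(y, x, grms, vc, method="mme")
        assert np.allclose(f_gls.beta_hat, f_mme.beta_hat, atol=1e-7)
        for name in ("additive", "dominance", "epistatic"):
            assert np.allclose(f_gls.solutions[name],
                               f_mme.solutions[name], atol=1e-6)
        assert f_mme.mme_residual < 1e-8

    def test_vanishing_shrinkage_interpolates_residuals(self):
        """As sigma2_A -> infinity the BLUP interpolates y - X beta."""
        rng = np.random.default_rng(83)
        n = 5
        g = random_pd_grm(n, rng) + 0.5 * np.eye(n)
        y = rng.normal(size=n)
        vc = VarianceComponents(components={"additive": 1e9}, residual=1.0)
        fit = solve_mme(y, None, [g], vc)
        assert np.allclose(fit.u_hat, y - fit.beta_hat[0], atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(89)
        n = 30
        g = random_pd_grm(n, rng)
        y = rng.normal(size=n)
        vc = VarianceComponents(components={"additive": 1.0}, residual=1.0)
        fit = solve_mme(y, None, [g], vc)
        perm = rng.permutation(n)
        fit_p = solve_mme(y[perm], None, [g[np.ix_(perm, perm)]], vc)
        assert np.allclose(fit_p.u_hat, fit.u_hat[perm], atol=1e-9)


class TestPredictProgeny:
    def test_duplicate_of_training_clone_reproduces_fit(
            self, balanced_p_half_pop):
        pop = balanced_p_half_pop
        freqs = cm.allele_frequencies(pop)
        grms = cm.GRMSet.from_genotypes(pop, freqs)
        het = cm.genomewide_heterozygosity(pop, freqs)
        rng = np.random.default_rng(97)
        y = rng.normal(size=pop.n_clones)
        x = np.column_stack([np.ones(len(y)), het - het.mean()])
        vc = VarianceComponents(
            components={"additive": 1.0, "dominance": 0.5,
                        "epistatic": 0.4},
            residual=1.0)
        fit = solve_mme(y, x, [grms.g_additive, grms.g_dominance,
                               grms.g_epistatic], vc)
        fit.het_center = float(het.mean())
        j = 7
        blocks = cm.cross_block_grms(pop, pop.subset_clones([j]),
                                     train_grms=grms)
        pred = cm.predict_progeny(fit, blocks)
        assert pred["u_hat"][0] == pytest.approx(fit.u_hat[j], abs=1e-8)
        assert pred["d_hat"][0] == pytest.approx(fit.d_hat[j], abs=1e-8)
        assert pred["g_hat"][0] == pytest.approx(
            fit.u_hat[j] + fit.d_hat[j] + fit.t_hat[j]
            + fit.b_hat * (het[j] - het.mean()), abs=1e-7)

    def test_zero_training_solutions_leave_only_het_term(
            self, balanced_p_half_pop):
        pop = balanced_p_half_pop
        freqs = cm.allele_frequencies(pop)
        grms = cm.GRMSet.from_genotypes(pop, freqs)
        n = pop.n_clones
        fit = cm.MMEFit(model="e-GBLUP", beta_hat=np.array([0.0, 2.5]),
                        solutions={"additive": np.zeros(n),
                                   "dominance": np.zeros(n),
                                   "epistatic": np.zeros(n)},
                        b_hat=2.5, log_likelihood=0.0,
                        varcomps=VarianceComponents(
                            components={}, residual=1.0),
                        het_center=0.0,
                        component_weights={"additive": np.zeros(n),
                                           "dominance": np.zeros(n),
                                           "epistatic": np.zeros(n)})
        prog = pop.subset_clones([0, 1, 2])
        blocks = cm.cross_block_grms(pop, prog, train_grms=grms)
        pred = cm.predict_progeny(fit, blocks)
        assert np.allclose(pred["g_hat"], 2.5 * blocks.progeny_het)

    def test_matches_masked_mme_oracle(self, related_pop):
        """Prediction through cross blocks equals the joint BLUP with
        progeny phenotypes masked (direct V-inverse computation)."""
        pop, _ = related_pop
        train = pop.subset_clones(np.arange(60))
        prog = pop.subset_clones(np.arange(60, 80))
        keep = ~cm.allele_frequencies(train).monomorphic
        train = cm.GenotypeMatrix(train.clone_id, train.marker_id[keep],
                                  train.codes[:, keep])
        prog = cm.GenotypeMatrix(prog.clone_id, prog.marker_id[keep],
                                 prog.codes[:, keep])
        freqs = cm.allele_frequencies(train)
        grms = cm.GRMSet.from_genotypes(train, freqs)
        rng = np.random.default_rng(101)
        y = rng.normal(size=60)
        vc = VarianceComponents(components={"additive": 2.0},
                                residual=1.0)
        fit = solve_mme(y, None, [grms.g_additive], vc)
        blocks = cm.cross_block_grms(train, prog, train_grms=grms)
        pred = cm.predict_progeny(fit, blocks)
        # oracle: u_prog = s2 * G_pt * V_tt^-1 * (y - X beta)
        v = 2.0 * grms.g_additive + np.eye(60)
        vinv = np.linalg.inv(v)
        x = np.ones((60, 1))
        beta = np.linalg.inv(x.T @ vinv @ x) @ x.T @ vinv @ y
        oracle = 2.0 * blocks.a_block @ vinv @ (y - x @ beta).ravel()
        assert np.allclose(pred["u_hat"], oracle, atol=1e-6)


class TestHeritabilityReport:
    def test_additive_only_printed_components(self):
        vc = VarianceComponents.from_values(sigma2_A=24.91,
                                            sigma2_eps=68.51)
        rep = cm.heritability_report(vc)
        assert round(rep.h2, 2) == 0.27

    def test_extended_printed_components(self):
        vc = VarianceComponents.from_values(sigma2_A=15.82,
                                            sigma2_eps=46.10,
                                            sigma2_D=3.08,
                                            sigma2_AA=22.94)
        rep = cm.heritability_report(vc)
        assert round(rep.h2, 2) == 0.18
        assert round(rep.dominance_to_additive, 2) == 0.19
        assert round(rep.genetic_shares[2] * 100) == 55

    def test_pure_additive_shares(self):
        vc = VarianceComponents.from_values(sigma2_A=5.0, sigma2_eps=5.0)
        rep = cm.heritability_report(vc)
        assert rep.genetic_shares == (1.0, 0.0, 0.0)

    def test_zero_phenotypic_variance_rejected(self):
        vc = VarianceComponents.from_values(sigma2_A=0.0, sigma2_eps=0.0)
        with pytest.raises(DegenerateInputError):
            cm.heritability_report(vc)


class TestLikelihoodRatioTest:
    def test_equal_likelihoods(self):
        res = cm.likelihood_ratio_test(-100.0, -100.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_survival(self):
        res = cm.likelihood_ratio_test(-98.0, -100.0, df=1)
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.0455, abs=1e-4)
        assert res.significant

    def test_negative_difference_floored(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = cm.likelihood_ratio_test(-101.0, -100.0)
        assert res.statistic == 0.0
        assert any("floored" in str(w.message) for w in caught)


class TestBroadSenseH2:
    def test_limits_and_midpoint(self):
        assert cm.broad_sense_h2(3.0, 0.0, 2) == 1.0
        assert cm.broad_sense_h2(2.0, 2.0, 1) == 0.5

    def test_monotone_in_replicates(self):
        vals = [cm.broad_sense_h2(1.0, 2.0, r) for r in (1, 2, 5, 50)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.95
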