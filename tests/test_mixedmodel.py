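"""REML variance components, LRT and BLUP prediction."""

import numpy as np
import pytest
from scipy import linalg

import selblup as sb
from selblup.kinship import KinshipMatrix, build_grm
from selblup.mixedmodel import fit_reml, lrt, lrt_pvalue, predict_gebv


def grid_search_reml_oracle(y, g, n_grid=2000):
    """Independent restricted-likelihood grid over the heritability ratio.

    Dense textbook formulae only: V = s_p^2 (h2 G + (1-h2) I), sigma
    profiled as y'P y/(n-1); returns the h2 grid argmax.
    """
    n = len(y)
    x = np.ones((n, 1))
    best, best_ll = None, -np.inf
    for h2 in np.linspace(0.0, 0.999999, n_grid):
        v0 = h2 * g + (1 - h2) * np.eye(n)
        v0_inv = np.linalg.inv(v0)
        xtvx = (x.T @ v0_inv @ x).item()
        p0 = v0_inv - (v0_inv @ x @ x.T @ v0_inv) / xtvx
        quad = float(y @ p0 @ y)
        sp2 = quad / (n - 1)
        sign, logdet_v0 = np.linalg.slogdet(v0)
        ll = -0.5 * (
            n * np.log(sp2) + logdet_v0
            + np.log(xtvx) - np.log(sp2)
            + quad / sp2
        )
        if ll > best_ll:
            best, best_ll = h2, ll
    return best


def subset_kinship(g: KinshipMatrix, idx) -> KinshipMatrix:
    return KinshipMatrix(
        values=g.values[np.ix_(idx, idx)],
        individuals=[g.individuals[i] for i in idx],
        s_value=g.s_value,
        snp_ids=g.snp_ids,
        denominator=g.denominator,
    )


@pytest.fixture(scope="module")
def panel():
    p = sb.generate_panel(
        sb.SyntheticPanelConfig(n_individuals=300, n_snps=1200, seed=33)
    )
    return sb.apply_qc(p)[0]


class TestFitREML:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle_n50(self, panel, seed):
        rng = np.random.default_rng(seed)
        idx = rng.choice(panel.n_individuals, size=50, replace=False)
        g = subset_kinship(build_grm(panel, -0.5), idx)
        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=200, s_true=-0.5, h2=0.5, seed=seed)
        )
        y = trait.phenotypes[idx]
        fit = fit_reml(y, [g])
        oracle_h2 = grid_search_reml_oracle(y, g.values)
        assert fit.h2_total == pytest.approx(oracle_h2, abs=1e-3)

    def test_noiseless_limit_h2_one(self, panel):
        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=150, s_true=0.0, h2=0.5, seed=7)
        )
        g = build_grm(panel, 0.0, snp_subset=trait.cv_indices)
        fit = fit_reml(trait.tbv, [g])
        assert fit.h2_total > 0.98

    def test_pure_noise_estimates_near_boundary(self, panel):
        g = build_grm(panel, 0.0)
        h2s = []
        for seed in range(10):
            y = np.random.default_rng(seed).standard_normal(panel.n_individuals)
            h2s.append(fit_reml(y, [g]).h2_total)
        assert np.median(h2s) < 0.05

    def test_multi_path_with_one_grm_matches_single_path(self, panel):
        from selblup.mixedmodel import _fit_multi

        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=150, s_true=-1.0, h2=0.4, seed=11)
        )
        g = build_grm(panel, -1.0)
        single = fit_reml(trait.phenotypes, [g])
        multi = _fit_multi(trait.phenotypes, [g.values], 200, 1e-8)
        assert abs(single.h2_total - multi.h2_total) < 1e-6

    def test_scale_equivariance(self, panel):
        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=150, s_true=0.0, h2=0.4, seed=13)
        )
        g = build_grm(panel, 0.0)
        c = 5.0
        f1 = fit_reml(trait.phenotypes, [g])
        f2 = fit_reml(c * trait.phenotypes, [g])
        assert f2.sigma_a2[0] == pytest.approx(c**2 * f1.sigma_a2[0], rel=1e-4)
        assert f2.sigma_e2 == pytest.approx(c**2 * f1.sigma_e2, rel=1e-4)
        assert f2.h2_total == pytest.approx(f1.h2_total, abs=1e-6)

    def test_nonnegative_components_and_bounded_h2(self, panel):
        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=150, s_true=0.5, h2=0.3, seed=17)
        )
        grms = sb.build_stratified_grms(panel, 0.5)
        fit = fit_reml(trait.phenotypes, grms)
        assert np.all(fit.sigma_a2 >= 0)
        assert 0.0 <= fit.h2_total <= 1.0
        assert np.isfinite(fit.loglik)

    def test_too_few_individuals_rejected(self, panel):
        g = subset_kinship(build_grm(panel, 0.0), np.arange(5))
        with pytest.raises(ValueError, match="at least 10"):
            fit_reml(np.zeros(5), [g])

    def test_non_psd_grm_rejected(self):
        with pytest.raises(ValueError):
            fit_reml(np.zeros(12), [KinshipMatrix(
                values=np.diag([1.0] * 11 + [-1.0]),
                individuals=[("f", str(i)) for i in range(12)],
                s_value=0.0, snp_ids=[], denominator=1.0,
            )])


class TestLRT:
    def test_identical_fits_give_zero(self, panel):
        y = np.random.default_rng(0).standard_normal(panel.n_individuals)
        null = fit_reml(y, [])
        assert lrt(null, null) == 0.0

    def test_boundary_fit_gives_zero(self, panel):
        """When sigma_a2 lands on the 0 boundary the nested optima coincide."""
        g = build_grm(panel, 0.0)
        y = np.random.default_rng(3).standard_normal(panel.n_individuals)
        full = fit_reml(y, [g])
        null = fit_reml(y, [])
        if full.h2_total == 0.0:
            assert lrt(full, null) == pytest.approx(0.0, abs=1e-6)

    def test_statistic_grows_with_sample_size(self):
        stats_by_n = []
        for n in (250, 500, 1000):
            p = sb.generate_panel(
                sb.SyntheticPanelConfig(n_individuals=n, n_snps=1500, seed=41)
            )
            p, _ = sb.apply_qc(p)
            trait = sb.simulate_trait(
                p, sb.SimulationConfig(n_cv=300, s_true=0.0, h2=0.5, seed=41)
            )
            g = build_grm(p, 0.0)
            full = fit_reml(trait.phenotypes, [g])
            null = fit_reml(trait.phenotypes, [])
            stats_by_n.append(lrt(full, null))
        assert stats_by_n[0] < stats_by_n[1] < stats_by_n[2]

    def test_mismatched_phenotypes_rejected(self, panel):
        y1 = np.random.default_rng(1).standard_normal(panel.n_individuals)
        y2 = np.random.default_rng(2).standard_normal(panel.n_individuals)
        full = fit_reml(y1, [build_grm(panel, 0.0)])
        null = fit_reml(y2, [])
        with pytest.raises(ValueError, match="different phenotype"):
            lrt(full, null)

    def test_boundary_mixture_pvalue(self):
        assert lrt_pvalue(0.0) == 1.0
        assert 0.0 < lrt_pvalue(3.84) < 0.05


class TestPredictGEBV:
    def test_unrelated_candidate_gets_zero(self, panel):
        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=100, s_true=0.0, h2=0.4, seed=19)
        )
        g = build_grm(panel, 0.0)
        g2 = KinshipMatrix(
            values=g.values.copy(), individuals=g.individuals,
            s_value=0.0, snp_ids=g.snp_ids, denominator=g.denominator,
        )
        train = np.arange(0, 200)
        cand = np.array([250])
        g2.values[cand[0], :] = 0.0
        g2.values[:, cand[0]] = 0.0
        g2.values[cand[0], cand[0]] = 1.0
        fit = fit_reml(trait.phenotypes[train], [subset_kinship(g2, train)])
        pred = predict_gebv(fit, [g2], trait.phenotypes[train], train, cand)
        assert pred.gebv[0] == pytest.approx(0.0, abs=1e-12)

    def test_clone_recovers_phenotype_as_noise_vanishes(self, panel):
        """A candidate identical to a training individual, sigma_e2 -> 0."""
        trait = sb.simulate_trait(
            panel, sb.SimulationConfig(n_cv=100, s_true=0.0, h2=0.4, seed=23)
        )
        g = build_grm(panel, 0.0)
        train = np.arange(0, 200)
        clone_of = 10
        cand = np.array([299])
        gv = g.values.copy()
        gv[cand[0], :] = gv[clone_of, :]
        gv[:, cand[0]] = gv[:, clone_of]
        gv[cand[0], cand[0]] = gv[clone_of, clone_of]
        g_clone = KinshipMatrix(
            values=gv, individuals=g.individuals, s_value=0.0,
            snp_ids=g.snp_ids, denominator=g.denominator,
        )
        fit = fit_reml(trait.phenotypes[train], [subset_kinship(g_clone, train)])
        fit.sigma_e2 = 1e-8
        fit.sigma_a2 = np.array([1.0])
        y_train = trait.phenotypes[train]
        pred = predict_gebv(fit, [g_clone], y_train, train, cand)
        mu = pred.gebv[0] + 0.0
        # GEBV is centered; compare against the clone's centered phenotype
        beta_ref = y_train.mean()
        assert pred.gebv[0] == pytest.approx(
            y_train[clone_of] - beta_ref, abs=0.05 * np.std(y_train)
        )

    def test_matches_mixed_model_equations_oracle(self):
        """Direct dense MME solve on a 30-individual toy with a ridge-regularized
        kinship so the inverse relationship matrix exists."""
        rng = np.random.default_rng(55)
        n = 30
        z = rng.standard_normal((n, 40))
        k = z @ z.T / 40
        k = 0.9 * k + 0.1 * np.eye(n)  # invertible kinship
        kin = KinshipMatrix(
            values=k, individuals=[("f", str(i)) for i in range(n)],
            s_value=0.0, snp_ids=[], denominator=1.0,
        )
        y_all = rng.standard_normal(n)
        train = np.arange(20)
        cand = np.arange(20, 30)
        fit = fit_reml(y_all[train], [subset_kinship(kin, train)])
        if fit.sigma_a2[0] <= 0:
            fit.sigma_a2 = np.array([0.5])
            fit.sigma_e2 = 0.5
        pred = predict_gebv(fit, [kin], y_all[train], train, cand)

        # MME over ALL individuals, Z selecting the phenotyped (training) rows
        lam = fit.sigma_e2 / fit.sigma_a2[0]
        zmat = np.zeros((len(train), n))
        zmat[np.arange(len(train)), train] = 1.0
        x = np.ones((len(train), 1))
        kinv = np.linalg.inv(k)
        top = np.hstack([x.T @ x, x.T @ zmat])
        bottom = np.hstack([zmat.T @ x, zmat.T @ zmat + lam * kinv])
        lhs = np.vstack([top, bottom])
        rhs = np.concatenate([x.T @ y_all[train], zmat.T @ y_all[train]])
        sol = np.linalg.solve(lhs, rhs)
        a_hat = sol[1:]
        np.testing.assert_allclose(pred.gebv, a_hat[cand], atol=1e-8)

    def test_all_zero_variances_rejected(self, panel):
        from selblup.mixedmodel import FitResult

        g = build_grm(panel, 0.0)
        fit = FitResult(sigma_a2=np.array([0.0]), sigma_e2=0.0, loglik=0.0,
                        converged=True, n_iter=0, n_obs=10)
        with pytest.raises(ValueError, match="singular"):
            predict_gebv(fit, [g], np.zeros(10), np.arange(10), np.arange(10, 12))
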