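import numpy as np
import pytest
from scipy import stats

from oracles import (
    acdc_vcv_bruteforce,
    brute_force_vcv,
    direct_mvn_loglik,
    grafen_vcv_via_tree_rebuild,
)
from nichelimits.backbone_tree import parse_newick, vcv_from_tree
from nichelimits.errors import SingularCovarianceError
from nichelimits.pgls_core import (
    FAMILY_ORDER,
    CorrelationModel,
    Family,
    TreeData,
    build_design,
    estimated_means,
    fit_pgls,
    gls_fit,
    model_suite,
    transform_vcv,
)
from nichelimits.synthetic_data import (
    assign_states_by_clades,
    simulate_tip_values,
    simulate_yule_tree,
)


def _sim(tree, seed, beta1=1.0, family=Family.BROWNIAN, theta=None, sigma2=1.0):
    td = TreeData(tree)
    states, _ = assign_states_by_clades(tree, 3, seed=seed)
    labels, y = simulate_tip_values(
        td, states, family, theta, 10.0, beta1, sigma2, seed=seed + 1
    )
    X = build_design([states[l] for l in labels])
    return td, y, X, states


class TestBuildDesign:
    def test_indicator_in_input_order(self):
        X = build_design(["C3", "C4", "C4", "C3"])
        np.testing.assert_array_equal(X[:, 0], 1.0)
        np.testing.assert_array_equal(X[:, 1], [0, 1, 1, 0])

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="both states"):
            build_design(["C3", "C3"])

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="CAM"):
            build_design(["C3", "CAM"])


class TestTransformVCV:
    tree = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")

    def test_independent_is_identity(self):
        C = transform_vcv(None, self.tree, CorrelationModel(Family.INDEPENDENT))
        np.testing.assert_allclose(C, np.eye(4))

    def test_brownian_matches_tree_vcv(self):
        td = TreeData(self.tree)
        C = transform_vcv(td.V, td, CorrelationModel(Family.BROWNIAN))
        expected = vcv_from_tree(self.tree).loc[td.labels, td.labels].values
        np.testing.assert_allclose(C, expected)

    @pytest.mark.parametrize("lam", [0.0, 0.3, 1.0])
    def test_pagel_scales_offdiagonals_only(self, lam):
        td = TreeData(self.tree)
        C = transform_vcv(td.V, td, CorrelationModel(Family.PAGEL_LAMBDA, lam))
        np.testing.assert_allclose(np.diag(C), np.diag(td.V))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(C[off], lam * td.V[off])

    def test_grafen_hand_case(self):
        # 4-tip balanced tree: cherry MRCAs have 2 descendants, h = 1/3.
        td = TreeData(self.tree)
        C1 = transform_vcv(None, td, CorrelationModel(Family.GRAFEN_RHO, 1.0))
        i, j = td.labels.index("A"), td.labels.index("B")
        assert C1[i, j] == pytest.approx(1 - 1 / 3)
        assert C1[i, i] == 1.0
        C2 = transform_vcv(None, td, CorrelationModel(Family.GRAFEN_RHO, 2.0))
        assert C2[i, j] == pytest.approx(1 - (1 / 3) ** 2)

    @pytest.mark.parametrize("rho", [0.5, 1.0, 2.0, 7.3])
    def test_grafen_matches_tree_rebuild_oracle(self, random_trees, rho):
        for tree in random_trees(2, 18, seed=31):
            labels, expected = grafen_vcv_via_tree_rebuild(tree, rho)
            td = TreeData(tree)
            C = transform_vcv(None, td, CorrelationModel(Family.GRAFEN_RHO, rho))
            order = [td.labels.index(l) for l in labels]
            np.testing.assert_allclose(C[np.ix_(order, order)], expected, atol=1e-10)

    @pytest.mark.parametrize("g", [0.05, 0.5, 2.0, 50.0])
    def test_acdc_matches_bruteforce_oracle(self, random_trees, g):
        for tree in random_trees(2, 15, seed=37):
            labels, expected = acdc_vcv_bruteforce(tree, g)
            td = TreeData(tree)
            C = transform_vcv(None, td, CorrelationModel(Family.ACDC_G, g))
            order = [td.labels.index(l) for l in labels]
            np.testing.assert_allclose(C[np.ix_(order, order)], expected, atol=1e-9)

    def test_acdc_g_one_is_brownian(self, random_trees):
        tree = random_trees(1, 12, seed=41)[0]
        td = TreeData(tree)
        C = transform_vcv(None, td, CorrelationModel(Family.ACDC_G, 1.0))
        np.testing.assert_allclose(C, td.V)

    @pytest.mark.parametrize(
        "family,theta",
        [(Family.PAGEL_LAMBDA, 1.2), (Family.PAGEL_LAMBDA, -0.1),
         (Family.GRAFEN_RHO, 0.0), (Family.ACDC_G, 0.0),
         (Family.BROWNIAN, 0.5)],
    )
    def test_out_of_range_parameters_rejected(self, family, theta):
        with pytest.raises(ValueError):
            CorrelationModel(family, theta)


class TestGLSFit:
    def test_identity_v_reproduces_ols(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 2.0 + 0.5 * X[:, 1] + rng.normal(size=n)
        res = gls_fit(y, X, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta, beta_ols, atol=1e-10)

    def test_intercept_only_gives_gls_mean(self, rng):
        y = rng.normal(size=10)
        res = gls_fit(y, np.ones((10, 1)), np.eye(10))
        assert res.beta[0] == pytest.approx(y.mean())

    def test_ml_loglik_matches_direct_density(self, random_trees, rng):
        # the profiled ML loglik evaluated at (beta_hat, sigma2_hat) must
        # equal the plain multivariate-normal density at those values
        for tree in random_trees(3, 20, seed=43):
            td = TreeData(tree)
            states, _ = assign_states_by_clades(tree, 3, seed=7)
            labels, y = simulate_tip_values(
                td, states, Family.BROWNIAN, None, 5.0, 1.0, 2.0, seed=8
            )
            X = build_design([states[l] for l in labels])
            res = gls_fit(y, X, td.V, method="ML")
            direct = direct_mvn_loglik(y, X @ res.beta, res.sigma2 * td.V)
            assert res.log_likelihood == pytest.approx(direct, abs=1e-8)

    def test_reml_penalises_relative_to_ml(self, random_trees):
        tree = random_trees(1, 20, seed=47)[0]
        td, y, X, _ = _sim(tree, 3)
        ml = gls_fit(y, X, td.V, "ML")
        reml = gls_fit(y, X, td.V, "REML")
        assert ml.log_likelihood != pytest.approx(reml.log_likelihood)
        # both give identical point estimates
        np.testing.assert_allclose(ml.beta, reml.beta)

    def test_singular_covariance_raises(self):
        V = np.ones((3, 3))
        with pytest.raises(SingularCovarianceError):
            gls_fit(np.arange(3.0), np.column_stack([np.ones(3), [0, 1, 1.0]]), V)

    def test_p_value_from_t_distribution(self, random_trees):
        tree = random_trees(1, 25, seed=53)[0]
        td, y, X, states = _sim(tree, 5)
        fit = fit_pgls(y, X, td, Family.BROWNIAN)
        res = gls_fit(y, X, td.V)
        t = res.beta[1] / np.sqrt(res.cov_beta[1, 1])
        assert fit.p_value == pytest.approx(2 * stats.t.sf(abs(t), td.n - 2))


class TestFitPGLS:
    def test_lambda_profile_beats_dense_grid(self, random_trees):
        tree = random_trees(1, 40, seed=59)[0]
        td, y, X, _ = _sim(tree, 11, family=Family.PAGEL_LAMBDA, theta=0.6)
        fit = fit_pgls(y, X, td, Family.PAGEL_LAMBDA)
        grid_ll = max(
            gls_fit(
                y, X, transform_vcv(td.V, td, CorrelationModel(Family.PAGEL_LAMBDA, lam))
            ).log_likelihood
            for lam in np.linspace(0, 1, 101)
        )
        assert fit.log_likelihood >= grid_ll - 1e-6

    @pytest.mark.parametrize("family", [Family.GRAFEN_RHO, Family.ACDC_G])
    def test_profiled_families_beat_coarse_grid(self, random_trees, family):
        tree = random_trees(1, 30, seed=61)[0]
        td, y, X, _ = _sim(tree, 13)
        fit = fit_pgls(y, X, td, family)
        lo, hi = {Family.GRAFEN_RHO: (1e-3, 10.0), Family.ACDC_G: (0.01, 100.0)}[family]
        for theta in np.geomspace(lo, hi, 41):
            ll = gls_fit(
                y, X, transform_vcv(td.V, td, CorrelationModel(family, theta))
            ).log_likelihood
            assert fit.log_likelihood >= ll - 1e-6

    def test_scale_equivariance_of_estimates(self, random_trees):
        # multiplying every branch length by c rescales sigma2 but leaves
        # beta, se and p unchanged for BROWNIAN and PAGEL
        from nichelimits.backbone_tree import write_newick

        tree = random_trees(1, 25, seed=67)[0]
        td, y, X, _ = _sim(tree, 17)
        scaled = parse_newick(write_newick(tree))
        for node in scaled.preorder_node_iter():
            if node is not scaled.seed_node:
                node.edge.length *= 3.7
        td2 = TreeData(scaled)
        order = [td2.labels.index(l) for l in td.labels]
        y2, X2 = np.empty_like(y), np.empty_like(X)
        for i, j in enumerate(order):
            y2[j], X2[j] = y[i], X[i]
        for family in (Family.BROWNIAN, Family.PAGEL_LAMBDA):
            f1 = fit_pgls(y, X, td, family)
            f2 = fit_pgls(y2, X2, td2, family)
            assert f2.beta1 == pytest.approx(f1.beta1, rel=1e-5)
            assert f2.se_beta1 == pytest.approx(f1.se_beta1, rel=1e-5)
            assert f2.sigma2 == pytest.approx(f1.sigma2 / 3.7, rel=1e-5)

    def test_lambda_zero_equals_independent_on_ultrametric_tree(self, random_trees):
        tree = random_trees(1, 20, seed=71)[0]  # Yule trees are ultrametric
        td, y, X, _ = _sim(tree, 19)
        ind = gls_fit(y, X, np.eye(td.n))
        lam0 = gls_fit(y, X, transform_vcv(td.V, td, CorrelationModel(Family.PAGEL_LAMBDA, 0.0)))
        np.testing.assert_allclose(ind.beta, lam0.beta, atol=1e-10)
        # identical up to the diagonal scale T: t statistics match exactly
        t_i = ind.beta[1] / np.sqrt(ind.cov_beta[1, 1])
        t_l = lam0.beta[1] / np.sqrt(lam0.cov_beta[1, 1])
        assert t_i == pytest.approx(t_l)

    def test_lambda_one_equals_brownian(self, random_trees):
        tree = random_trees(1, 20, seed=73)[0]
        td, y, X, _ = _sim(tree, 23)
        br = gls_fit(y, X, td.V)
        lam1 = gls_fit(y, X, transform_vcv(td.V, td, CorrelationModel(Family.PAGEL_LAMBDA, 1.0)))
        np.testing.assert_allclose(br.beta, lam1.beta)
        assert br.log_likelihood == pytest.approx(lam1.log_likelihood)

    def test_star_tree_collapses_all_families_to_ols(self, rng):
        tree = parse_newick("(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        td = TreeData(tree)
        states = {f"t{i}": ("C4" if i < 8 else "C3") for i in range(20)}
        labels, y = simulate_tip_values(
            td, states, Family.INDEPENDENT, None, 0.0, 1.0, 1.0, seed=4
        )
        X = build_design([states[l] for l in labels])
        betas = [fit_pgls(y, X, td, f).beta1 for f in FAMILY_ORDER]
        np.testing.assert_allclose(betas, betas[0], atol=1e-6)


class TestModelSuite:
    def test_selection_and_aic_bookkeeping(self, random_trees):
        tree = random_trees(1, 40, seed=79)[0]
        td, y, X, _ = _sim(tree, 29)
        sel = model_suite(y, X, td)
        assert len(sel.fits) == 5 and not sel.failures
        assert sel.best.aic == min(f.aic for f in sel.fits.values())
        for fit in sel.fits.values():
            k_expected = 4 if fit.model.family in (
                Family.PAGEL_LAMBDA, Family.GRAFEN_RHO, Family.ACDC_G
            ) else 3
            assert fit.k == k_expected
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood)
        assert sel.ranked[0] is sel.best
        aics = [f.aic for f in sel.ranked]
        assert aics == sorted(aics)

    def test_strong_brownian_signal_selects_tree_aware_model(self, random_trees):
        tree = random_trees(1, 80, seed=83)[0]
        td, y, X, _ = _sim(tree, 31, sigma2=4.0)
        sel = model_suite(y, X, td)
        assert sel.best.model.family is not Family.INDEPENDENT

    def test_agreement_flag_consistency(self, random_trees):
        # recompute the flag from the reported fits
        tree = random_trees(1, 30, seed=89)[0]
        td, y, X, _ = _sim(tree, 37)
        sel = model_suite(y, X, td, alpha=0.05)
        expected = all(
            ((f.p_value <= 0.05) == (sel.best.p_value <= 0.05))
            and (np.sign(f.beta1) == np.sign(sel.best.beta1))
            for f in sel.fits.values()
            if f.aic - sel.best.aic <= 10.0
        )
        assert sel.agreement is expected

    def test_estimated_means_arithmetic(self, random_trees):
        tree = random_trees(1, 25, seed=97)[0]
        td = TreeData(tree)
        states, _ = assign_states_by_clades(tree, 3, seed=41)
        labels, y = simulate_tip_values(
            td, states, Family.BROWNIAN, None, 26.56, 1.61, 0.0, seed=0
        )
        X = build_design([states[l] for l in labels])
        fit = fit_pgls(y, X, td, Family.BROWNIAN)
        m3, m4, diff, _ = estimated_means(fit)
        assert m3 == pytest.approx(26.56, abs=1e-8)
        assert m4 == pytest.approx(28.17, abs=1e-8)
        assert diff == pytest.approx(1.61, abs=1e-8)
        assert fit.mean_c3 == m3 and fit.mean_c4 == m4


class TestTreeData:
    def test_vcv_matches_oracle(self, random_trees):
        for tree in random_trees(3, 22, seed=101):
            labels, expected = brute_force_vcv(tree)
            td = TreeData(tree)
            order = [td.labels.index(l) for l in labels]
            np.testing.assert_allclose(td.V[np.ix_(order, order)], expected, atol=1e-12)

    def test_mrca_nleaves_hand_case(self):
        td = TreeData(parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"))
        i = {l: k for k, l in enumerate(td.labels)}
        assert td.mrca_nleaves[i["A"], i["B"]] == 2
        assert td.mrca_nleaves[i["A"], i["C"]] == 4
        assert td.mrca_nleaves[i["A"], i["A"]] == 1

    def test_ensure_is_idempotent(self, random_trees):
        td = TreeData(random_trees(1, 10, seed=103)[0])
        assert TreeData.ensure(td) is td
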