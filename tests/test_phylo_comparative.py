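"""GLS machinery, signal statistics, contrasts, PGLS and ASR."""

import numpy as np
import pandas as pd
import pytest

from gcpanorama.phylo_comparative import (
    asr_bm,
    blomberg_k,
    bm_fit,
    fit_delta,
    fit_kappa,
    fit_lambda,
    parse_newick,
    pgls,
    pic,
    vcv,
)
from gcpanorama.synthetic_data import sim_bm_trait, sim_yule_tree
from gcpanorama.tree import transform_vcv
from oracles import (
    dense_asr,
    dense_bm_fit,
    dense_gls_beta,
    enumerate_rooted_topologies,
    topology_to_newick,
)


def _star(n, v=1.0):
    labels = [f"t{i}" for i in range(n)]
    return parse_newick(
        "(" + ",".join(f"{l}:{v}" for l in labels) + ");",
        require_bifurcating_root=False), labels


class TestBmFit:
    def test_star_tree_root_is_arithmetic_mean(self, rng):
        star, labels = _star(12)
        x = rng.normal(size=12)
        fit = bm_fit(dict(zip(labels, x)), vcv(star), labels)
        assert fit.root_mean == pytest.approx(x.mean(), abs=1e-12)

    def test_two_tip_inverse_variance_weighting(self):
        tree = parse_newick("(A:1,B:3);", require_bifurcating_root=False)
        fit = bm_fit({"A": 0.0, "B": 4.0}, vcv(tree), ["A", "B"])
        # weights 1/1 and 1/3: (0*1 + 4/3) / (1 + 1/3) = 1
        assert fit.root_mean == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_dense_gaussian_oracle(self, rng):
        for seed in range(10):
            tree = sim_yule_tree(6, 1.0, seed=seed)
            C = vcv(tree)
            x = rng.normal(size=6) * 3 + 1
            fit = bm_fit(x, C)
            a, s2, logL = dense_bm_fit(x, C)
            assert fit.root_mean == pytest.approx(a, abs=1e-10)
            assert fit.sigma2 == pytest.approx(s2, rel=1e-10)
            assert fit.log_likelihood == pytest.approx(logL, abs=1e-8)

    def test_singular_covariance_rejected(self):
        C = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="zero"):
            bm_fit(np.array([1.0, 2.0, 3.0]), C)


class TestSignalFits:
    def test_lambda_zero_loglik_equals_iid_normal_fit(self, rng):
        tree = sim_yule_tree(30, 1.0, seed=2)
        x = rng.normal(size=30)
        trait = dict(zip(tree.tip_labels, x))
        res = fit_lambda(trait, tree)
        # iid ML normal fit on a star tree with the same tip variances
        C0 = transform_vcv(vcv(tree), "lambda", 0.0)
        iid = bm_fit(x, C0)
        assert res.null_log_likelihood == pytest.approx(iid.log_likelihood,
                                                        abs=1e-8)

    def test_bm_trait_recovers_lambda_near_one(self):
        errs = []
        for rep in range(5):
            tree = sim_yule_tree(150, 1.0, seed=20 + rep)
            trait = sim_bm_trait(tree, 1.0, 0.0, seed=30 + rep)
            errs.append(abs(fit_lambda(trait, tree).estimate - 1.0))
        assert np.mean(errs) <= 0.1

    def test_permuted_trait_loses_lambda_signal(self, rng):
        tree = sim_yule_tree(150, 1.0, seed=3)
        trait = sim_bm_trait(tree, 1.0, 0.0, seed=4)
        shuffled = dict(zip(trait, rng.permutation(list(trait.values()))))
        assert fit_lambda(shuffled, tree).estimate < 0.2

    def test_neutral_parameters_not_rejected_by_lrt(self):
        # data simulated at the null transform should rarely reject
        rejections = 0
        for rep in range(10):
            tree = sim_yule_tree(100, 1.0, seed=50 + rep)
            trait = sim_bm_trait(tree, 1.0, 0.0, transform="delta",
                                 param=1.0, seed=60 + rep)
            if fit_delta(trait, tree).p_value < 0.05:
                rejections += 1
        assert rejections <= 2

    def test_kappa_recovery(self):
        for truth in (0.5, 1.0):
            errs = []
            for rep in range(3):
                tree = sim_yule_tree(150, 1.0, seed=70 + rep)
                trait = sim_bm_trait(tree, 1.0, 0.0, transform="kappa",
                                     param=truth, seed=80 + rep)
                errs.append(abs(fit_kappa(trait, tree).estimate - truth))
            assert np.mean(errs) <= 0.3


class TestBlombergK:
    def test_star_tree_k_is_exactly_one(self, rng):
        for n in (5, 9, 17):
            star, labels = _star(n, v=2.5)
            x = rng.normal(size=n) * 7 + 3
            res = blomberg_k(dict(zip(labels, x)), star, n_perm=0)
            assert res.estimate == pytest.approx(1.0, abs=1e-10)

    def test_bm_traits_center_near_one(self):
        ks = []
        for rep in range(10):
            tree = sim_yule_tree(150, 1.0, seed=100 + rep)
            trait = sim_bm_trait(tree, 1.0, 0.0, seed=110 + rep)
            ks.append(blomberg_k(trait, tree, n_perm=0).estimate)
        assert 0.7 < np.mean(ks) < 1.3

    def test_clade_indicator_strong_conservatism(self):
        tree = sim_yule_tree(60, 1.0, seed=5)
        left = tree.root.children[0]
        stack, members = [left], set()
        while stack:
            node = stack.pop()
            if node.is_tip:
                members.add(node.name)
            stack.extend(node.children)
        trait = {l: (1.0 if l in members else 0.0) + 1e-6 * i
                 for i, l in enumerate(tree.tip_labels)}
        res = blomberg_k(trait, tree, n_perm=199, seed=9)
        assert res.estimate > 1.0
        assert res.p_value <= 0.01

    def test_permutation_p_invariant_to_affine_transform(self):
        tree = sim_yule_tree(40, 1.0, seed=6)
        trait = sim_bm_trait(tree, 1.0, 0.0, seed=7)
        res1 = blomberg_k(trait, tree, n_perm=199, seed=11)
        scaled = {k: 100.0 - 7.0 * v for k, v in trait.items()}
        res2 = blomberg_k(scaled, tree, n_perm=199, seed=11)
        assert res1.estimate == pytest.approx(res2.estimate, rel=1e-9)
        assert res1.p_value == res2.p_value

    def test_constant_trait_rejected(self, yule_tree_50):
        with pytest.raises(ValueError):
            blomberg_k({l: 1.0 for l in yule_tree_50.tip_labels},
                       yule_tree_50, n_perm=0)


class TestPic:
    def test_two_tip_worked_example(self):
        tree = parse_newick("(A:1,B:1);", require_bifurcating_root=False)
        contrasts = pic({"A": 3.0, "B": 1.0}, tree)
        assert contrasts == pytest.approx([np.sqrt(2)])

    def test_identical_values_give_zero_contrasts(self, yule_tree_50):
        trait = {l: 4.2 for l in yule_tree_50.tip_labels}
        np.testing.assert_allclose(pic(trait, yule_tree_50), 0.0, atol=1e-12)

    def test_returns_n_minus_one_contrasts(self, yule_tree_50):
        trait = sim_bm_trait(yule_tree_50, 1.0, 0.0, seed=1)
        assert len(pic(trait, yule_tree_50)) == 49

    def test_polytomies_resolved_with_warning(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);",
                            require_bifurcating_root=False)
        with pytest.warns(UserWarning, match="polytom"):
            contrasts = pic({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}, tree)
        assert len(contrasts) == 3

    def test_standardized_variance_estimates_rate(self):
        # Var of standardized contrasts is a consistent sigma2 estimator
        tree = sim_yule_tree(500, 1.0, seed=8)
        sigma2 = 3.7
        trait = sim_bm_trait(tree, sigma2, 0.0, seed=9)
        c = pic(trait, tree)
        assert np.mean(c ** 2) == pytest.approx(sigma2, rel=0.15)

    def test_contrasts_uncorrelated_with_node_height(self):
        tree = sim_yule_tree(300, 1.0, seed=10)
        trait = sim_bm_trait(tree, 1.0, 0.0, seed=11)
        c = np.abs(pic(trait, tree))
        heights = np.arange(len(c))  # postorder proxy for node age ordering
        r = np.corrcoef(c, heights)[0, 1]
        assert abs(r) < 0.15


class TestPgls:
    def test_star_tree_equals_ols(self, rng):
        star, labels = _star(25)
        X = rng.normal(size=(25, 2))
        y = 1.0 + X @ np.array([0.5, -1.2]) + rng.normal(scale=0.3, size=25)
        fit = pgls(dict(zip(labels, y)), X, star)
        beta_ols = np.linalg.lstsq(np.column_stack([np.ones(25), X]), y,
                                   rcond=None)[0]
        np.testing.assert_allclose(fit.coef, beta_ols, atol=1e-10)

    def test_exact_linear_function_r2_one(self, rng):
        tree = sim_yule_tree(20, 1.0, seed=12)
        X = rng.normal(size=(20, 2))
        y = 2.0 + X @ np.array([1.0, 2.0])
        fit = pgls(dict(zip(tree.tip_labels, y)), X, tree)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_slope_recovery_under_bm_noise(self):
        tree = sim_yule_tree(200, 1.0, seed=13)
        x1 = np.array(list(sim_bm_trait(tree, 1.0, 0.0, seed=14).values()))
        noise = sim_bm_trait(tree, 0.5, 0.0, seed=15)
        labels = tree.tip_labels
        y = {l: 2.0 + 0.5 * x1[i] + noise[l] for i, l in enumerate(labels)}
        fit = pgls(y, x1[:, None], tree)
        assert abs(fit.coef[1] - 0.5) < 3 * fit.se[1]

    def test_matches_dense_oracle_on_small_trees(self, rng):
        for seed in range(5):
            tree = sim_yule_tree(6, 1.0, seed=seed)
            C = vcv(tree)
            X = rng.normal(size=(6, 2))
            y = rng.normal(size=6)
            fit = pgls(dict(zip(tree.tip_labels, y)), X, tree)
            oracle = dense_gls_beta(np.column_stack([np.ones(6), X]), y, C)
            np.testing.assert_allclose(fit.coef, oracle, atol=1e-8)

    def test_rank_deficient_design_names_columns(self, rng):
        tree = sim_yule_tree(10, 1.0, seed=16)
        x = rng.normal(size=10)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=tree.tip_labels)
        y = dict(zip(tree.tip_labels, rng.normal(size=10)))
        with pytest.raises(ValueError, match="collinear"):
            pgls(y, X, tree)

    def test_ml_lambda_structure_estimates_lambda(self):
        tree = sim_yule_tree(100, 1.0, seed=17)
        x = np.array(list(sim_bm_trait(tree, 1.0, 0.0, seed=18).values()))
        noise = sim_bm_trait(tree, 0.3, 0.0, seed=19)
        y = {l: 0.4 * x[i] + noise[l]
             for i, l in enumerate(tree.tip_labels)}
        fit = pgls(y, x[:, None], tree, structure="ML-lambda")
        assert fit.lambda_hat is not None
        assert 0.5 <= fit.lambda_hat <= 1.0


class TestAsr:
    def test_two_tip_inverse_variance_root(self):
        tree = parse_newick("(A:1,B:3);", require_bifurcating_root=False)
        states = asr_bm({"A": 0.0, "B": 4.0}, tree)
        assert states.root_mean == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_cherries_shrink_toward_root(self):
        # conditional-expectation ASR pulls each cherry toward the root
        # mean; values cross-checked against phytools::fastAnc
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = asr_bm({"A": 0.0, "B": 2.0, "C": 10.0, "D": 12.0}, tree)
        assert states.root_mean == pytest.approx(6.0, abs=1e-10)
        assert states.estimates["node1"] == pytest.approx(8 / 3, abs=1e-9)
        assert states.estimates["node2"] == pytest.approx(28 / 3, abs=1e-9)

    def test_matches_dense_conditional_gaussian_oracle(self, rng):
        for seed in range(6):
            tree = sim_yule_tree(6, 1.0, seed=seed)
            work = tree.copy()
            work.label_internal_nodes()
            x = rng.normal(size=6)
            states = asr_bm(dict(zip(work.tip_labels, x)), work)
            C = vcv(work)
            depths = work.depths()
            internals = work.internal_nodes()
            tips = work.tips()
            cross = np.zeros((len(internals), 6))
            dn = np.zeros(len(internals))
            for u, node in enumerate(internals):
                dn[u] = depths[node]
                for b, tip in enumerate(tips):
                    # MRCA depth by brute-force ancestor-set intersection
                    anc_u, p = [], node
                    while p is not None:
                        anc_u.append(p)
                        p = p.parent
                    p = tip
                    while p not in anc_u:
                        p = p.parent
                    cross[u, b] = depths[p]
            est, var, a, s2 = dense_asr(x, C, cross, dn)
            for u, node in enumerate(internals):
                assert states.estimates[node.name] == pytest.approx(
                    est[u], abs=1e-8)
                assert states.standard_errors[node.name] == pytest.approx(
                    np.sqrt(var[u]), abs=1e-8)

    def test_zero_length_terminal_branch_warns(self):
        tree = parse_newick("((A:0,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="zero-length"):
            asr_bm({"A": 1.0, "B": 2.0, "C": 3.0}, tree)


class TestSmallTreeOracleSweep:
    def test_all_four_tip_topologies_match_oracle(self, rng):
        for topo in enumerate_rooted_topologies(["A", "B", "C", "D"]):
            tree = parse_newick(topology_to_newick(topo, rng))
            C = vcv(tree)
            for _ in range(3):
                x = rng.normal(size=4)
                fit = bm_fit(x, C)
                a, s2, logL = dense_bm_fit(x, C)
                assert fit.root_mean == pytest.approx(a, abs=1e-9)
                assert fit.log_likelihood == pytest.approx(logL, abs=1e-8)
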