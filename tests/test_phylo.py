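"""Unit tests for the phylogenetic covariance machinery and model fits."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

from winggrad import synthetic as syn
from winggrad.phylo import (ContinuousTraitEvolution, Phylogeny, _eb_structure,
                            _ou_structure, _profile_ml, aicc, blomberg_k,
                            fit_model, lambda_transform, loglik, model_select,
                            pagel_lambda, phylo_cov, sigma2_profile)

THREE_TAXON = "((A:1,B:1):1,C:2);"


class TestTreeHandling:
    def test_prune_preserves_path_lengths(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        pruned = tree.prune(["A", "C"])
        d = pruned.distance_matrix()
        assert pruned.tip_labels == ["A", "C"] or pruned.tip_labels == ["C", "A"]
        assert d[0, 1] == pytest.approx(4.0)
        assert np.allclose(np.diag(pruned.vcv()[0]), 2.0)

    def test_prune_all_tips_is_identity(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        same = tree.prune(tree.tip_labels)
        assert np.allclose(same.distance_matrix(), tree.distance_matrix())

    def test_prune_random_half_keeps_distances(self):
        tree = syn.simulate_tree(100, seed=5)
        rng = np.random.default_rng(5)
        keep = sorted(rng.choice(tree.tip_labels, size=50, replace=False))
        sub = tree.prune(keep)
        D_full = tree.distance_matrix()
        pos = {lab: i for i, lab in enumerate(tree.tip_labels)}
        D_sub = sub.distance_matrix()
        for i, a in enumerate(sub.tip_labels):
            for j, b in enumerate(sub.tip_labels):
                assert D_sub[i, j] == pytest.approx(D_full[pos[a], pos[b]], abs=1e-10)

    def test_prune_unknown_labels_error(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        with pytest.raises(ValueError, match="absent"):
            tree.prune(["A", "Z"])

    def test_vcv_three_taxon(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        C = tree.vcv_for(["A", "B", "C"])
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_two_unrelated_tips_identity_cov(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        C = tree.vcv_for(["A", "B"])
        assert np.allclose(C, np.eye(2))


class TestCovarianceModels:
    def test_ou_limit_reduces_to_bm(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        C, _ = tree.vcv()
        V = _ou_structure(C, 1e-9)
        assert np.abs(V - C).max() < 1e-6 * C.max()

    def test_eb_limit_reduces_to_bm(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        C, _ = tree.vcv()
        V = _eb_structure(C, -1e-9)
        assert np.abs(V - C).max() < 1e-6 * C.max()

    def test_eb_matches_quadrature(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        r = -0.5
        V = phylo_cov(tree, "EB", r=r).C
        C, _ = tree.vcv()
        Vq = np.vectorize(lambda s: quad(lambda t: math.exp(r * t), 0.0, s)[0])(C)
        assert np.abs(V - Vq).max() < 1e-10

    def test_invalid_params_raise(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        with pytest.raises(ValueError):
            phylo_cov(tree, "OU", alpha=-1.0)
        with pytest.raises(ValueError):
            phylo_cov(tree, "EB", r=0.5)


class TestLikelihood:
    def test_single_standard_normal(self):
        ll = loglik(np.array([0.3]), np.array([[1.0]]), 0.3)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_zero_quadratic_form(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        C, _ = tree.vcv()
        ll = loglik(np.full(3, 1.7), C, 1.7)
        expect = -1.5 * math.log(2 * math.pi) - 0.5 * math.log(np.linalg.det(C))
        assert ll == pytest.approx(expect)

    def test_matches_direct_density(self):
        tree = Phylogeny.from_newick(THREE_TAXON)
        C, order = tree.vcv()
        x = np.array([0.0, 1.0, 4.0])
        ll = loglik(x, C, 1.0)
        assert ll == pytest.approx(
            multivariate_normal.logpdf(x, mean=np.ones(3), cov=C), abs=1e-10)

    def test_non_pd_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            loglik(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 0.0)


class TestFitting:
    def test_two_tip_gls_closed_form(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        C, _ = tree.vcv()
        z0, s2, _, degen = _profile_ml(np.array([1.0, -1.0]), C)
        assert z0 == pytest.approx(0.0)
        assert s2 == pytest.approx(1.0)
        assert not degen

    def test_constant_data_degenerate_floor(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fit = fit_model(np.full(4, 2.0), tree, "BM")
        assert fit.degenerate
        assert np.isfinite(fit.loglik)

    def test_gls_mean_equals_arithmetic_mean_on_star(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        x = np.array([0.0, 1.0, 2.0, 7.0])
        fit = fit_model(x, star, "BM")
        assert fit.z0 == pytest.approx(x.mean())

    def test_sigma2_scale_equivariance(self, tree24):
        rng = np.random.default_rng(1)
        x = np.linalg.cholesky(tree24.vcv()[0]) @ rng.standard_normal(24)
        for model in ("BM", "OU", "EB"):
            f1 = fit_model(x, tree24, model)
            f2 = fit_model(2.0 * x, tree24, model)
            assert f2.sigma2 == pytest.approx(4.0 * f1.sigma2, rel=1e-4)

    def test_loglik_invariant_to_tip_order(self, tree24):
        rng = np.random.default_rng(2)
        _, order = tree24.vcv()
        x = rng.standard_normal(24)
        f1 = fit_model(dict(zip(order, x)), tree24, "BM")
        shuffled = list(zip(order, x))
        rng.shuffle(shuffled)
        f2 = fit_model(dict(shuffled), tree24, "BM")
        assert f1.loglik == pytest.approx(f2.loglik)
        assert f1.sigma2 == pytest.approx(f2.sigma2)


class TestModelSelection:
    def test_aicc_arithmetic(self):
        assert aicc(-10.0, 2, 178) == pytest.approx(24 + 12 / 175)

    def test_aicc_undefined(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 2, 3)

    def test_parsimony_tie_break(self):
        from winggrad.phylo import EvolFitResults

        # identical AICc: the 2-parameter model must win
        ll_bm, ll_ou = -10.0, None
        a_bm = aicc(ll_bm, 2, 100)
        # choose OU loglik so its AICc equals BM's exactly
        ll_ou = -(a_bm - 2 * 3 - 2 * 3 * 4 / 96) / 2
        fits = [
            EvolFitResults("OU", 1.0, 0.0, ll_ou, aicc(ll_ou, 3, 100), 3, 100),
            EvolFitResults("BM", 1.0, 0.0, ll_bm, a_bm, 2, 100),
        ]
        best, table = model_select(fits)
        assert best.model == "BM"


class TestSignalStatistics:
    def test_k_is_one_on_star_tree(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert blomberg_k(rng.standard_normal(5), star) == pytest.approx(1.0)

    def test_k_constant_data_nan(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        with pytest.warns(UserWarning):
            assert math.isnan(blomberg_k(np.ones(4), star))

    def test_lambda_zero_transform_is_diagonal(self, tree24):
        C, _ = tree24.vcv()
        assert np.allclose(lambda_transform(C, 0.0), np.diag(np.diag(C)))

    def test_lambda_estimate_in_bounds(self, tree24):
        rng = np.random.default_rng(4)
        for _ in range(5):
            fit = pagel_lambda(rng.standard_normal(24), tree24)
            assert 0.0 <= fit.lam <= fit.lam_max


class TestSigma2Profile:
    def test_identical_slices_give_flat_profile(self, tree24):
        import pandas as pd

        rng = np.random.default_rng(3)
        _, order = tree24.vcv()
        x = np.linalg.cholesky(tree24.vcv()[0]) @ rng.standard_normal(24)
        vals = pd.DataFrame({f"s{i:02d}": x for i in range(1, 6)}, index=order)
        prof = sigma2_profile(vals, tree24, model_policy="BM")
        assert prof["sigma2"].nunique() == 1

    def test_doubling_values_quadruples_rates(self, tree24):
        import pandas as pd

        rng = np.random.default_rng(7)
        _, order = tree24.vcv()
        L = np.linalg.cholesky(tree24.vcv()[0])
        vals = pd.DataFrame({f"s{i:02d}": L @ rng.standard_normal(24)
                             for i in range(1, 6)}, index=order)
        p1 = sigma2_profile(vals, tree24, model_policy="BM")
        p2 = sigma2_profile(2.0 * vals, tree24, model_policy="BM")
        assert np.allclose(p2["sigma2"], 4.0 * p1["sigma2"])
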