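import numpy as np
import pandas as pd
import pytest

from conftest import random_binary_tree
from paleorates.bm import phylo_covariance
from paleorates.pgls import lambda_transform, pgls_ancova, reclassify_and_refit
from paleorates.synthetic import make_scenario
from paleorates.tree import PhylogenyError


@pytest.fixture(scope="module")
def allo71():
    return make_scenario("study71", seed=101, trait_model="allometry")


class TestLambdaTransform:
    def test_identity_at_one(self, rng):
        t = random_binary_tree(rng, 8)
        V = phylo_covariance(t)
        np.testing.assert_array_equal(lambda_transform(V, 1.0), V)

    def test_diagonal_at_zero(self, rng):
        t = random_binary_tree(rng, 8)
        V = phylo_covariance(t)
        np.testing.assert_array_equal(lambda_transform(V, 0.0), np.diag(np.diag(V)))

    def test_psd_preserved(self, rng):
        for _ in range(10):
            t = random_binary_tree(rng, int(rng.integers(5, 15)))
            V = phylo_covariance(t)
            lam = float(rng.uniform())
            eig = np.linalg.eigvalsh(lambda_transform(V, lam))
            assert eig.min() > -1e-10

    def test_out_of_range_refused(self, rng):
        V = phylo_covariance(random_binary_tree(rng, 5))
        with pytest.raises(ValueError):
            lambda_transform(V, 1.5)


class TestANCOVA:
    def test_zero_noise_exact_recovery(self):
        sc = make_scenario("study71", seed=9, trait_model="allometry",
                           allometry={"resid_sigma2": 0.0})
        fit = pgls_ancova(sc.tree, sc.traits, sc.groups, variant="three_level",
                          lam=0.0)
        truth = sc.truth["allometry"]
        est = fit.coef["estimate"]
        assert est["Femur: Aves"] == pytest.approx(truth["slopes"]["Aves"], abs=1e-8)
        assert est["Femur: Paraves"] == pytest.approx(
            truth["slopes"]["Paraves"] - truth["slopes"]["Aves"], abs=1e-8)
        assert est["Int. Aves"] == pytest.approx(truth["intercepts"]["Aves"], abs=1e-8)

    def test_single_group_lambda_zero_is_ols(self):
        # lambda = 0 leaves a diagonal covariance of tip depths; with tips
        # at equal depth that is exactly ordinary least squares
        from paleorates.tree import read_newick

        t = read_newick(
            "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,(E:2,F:2):1);", root_age=10.0)
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 0.3, 6)
        y = 1.2 * x + 0.1 + rng.normal(0, 0.05, 6)
        traits = pd.DataFrame({"femur_mm": x, "forelimb_mm": y},
                              index=t.tip_label_list)
        groups = pd.Series("all", index=traits.index)
        fit = pgls_ancova(t, traits, groups, variant="single", lam=0.0)
        b = np.polyfit(x, y, 1)
        assert fit.coef["estimate"]["Femur: all"] == pytest.approx(b[0], abs=1e-8)
        assert fit.coef["estimate"]["Int. all"] == pytest.approx(b[1], abs=1e-8)

    def test_single_group_lambda_zero_is_wls(self, allo71):
        # on a non-ultrametric tree lambda = 0 is weighted least squares
        # with weights 1/depth
        sc = allo71
        fit = pgls_ancova(sc.tree, sc.traits, sc.groups, variant="single", lam=0.0)
        labels = sc.tree.tip_label_list
        x = sc.traits.iloc[:, 0].loc[labels].to_numpy()
        y = sc.traits.iloc[:, 1].loc[labels].to_numpy()
        w = 1.0 / sc.tree.node_depths()[sc.tree.tips]
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert fit.coef["estimate"]["Int. all"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.coef["estimate"]["Femur: all"] == pytest.approx(beta[1], abs=1e-8)

    def test_lambda_one_matches_bm_gls(self, allo71):
        # cross-module oracle: with lambda fixed at 1 the PGLS mean model
        # on an intercept-only design must reproduce the BM-engine GLS fit
        sc = allo71
        y = sc.traits.iloc[:, [1]]
        fit = pgls_ancova(sc.tree, sc.traits, sc.groups, variant="single", lam=1.0)
        # same covariance scaling: compare regression lnL computed by the
        # bm engine on the residual-free single-trait model is not directly
        # the ANCOVA lnL; instead verify via the shared GLS machinery below
        V = phylo_covariance(sc.tree)
        L = np.linalg.cholesky(V)
        x = sc.traits.iloc[:, 0].loc[sc.tree.tip_label_list].to_numpy()
        yy = sc.traits.iloc[:, 1].loc[sc.tree.tip_label_list].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        from scipy.linalg import solve_triangular

        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, yy, lower=True)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        e = yw - Xw @ beta
        n = len(yy)
        s = float(e @ e) / n
        ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s)
                     + 2 * np.sum(np.log(np.diag(L))) + n)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_lambda_recovery_under_bm(self):
        # residuals simulated at lambda = 1 should give high lambda-hats
        lams = []
        for seed in range(12):
            sc = make_scenario("study71", seed=200 + seed, trait_model="allometry",
                               allometry={"lambda": 1.0})
            fit = pgls_ancova(sc.tree, sc.traits, sc.groups, variant="three_level")
            lams.append(fit.lam)
        assert np.median(lams) >= 0.9

    def test_taxon_order_invariance(self, allo71):
        sc = allo71
        fit1 = pgls_ancova(sc.tree, sc.traits, sc.groups)
        fit2 = pgls_ancova(sc.tree, sc.traits.sample(frac=1, random_state=1),
                           sc.groups.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(fit1.coef, fit2.coef)

    def test_three_vs_two_level_designs(self, allo71):
        sc = allo71
        f3 = pgls_ancova(sc.tree, sc.traits, sc.groups, variant="three_level")
        f2 = pgls_ancova(sc.tree, sc.traits, sc.groups, variant="aves_only")
        assert len(f3.coef) == 6
        assert len(f2.coef) == 4
        assert f3.reference == "Aves" and f2.reference == "Aves"

    def test_missing_groups_refused(self, allo71):
        sc = allo71
        g = sc.groups.drop(sc.groups.index[0])
        with pytest.raises(PhylogenyError):
            pgls_ancova(sc.tree, sc.traits, g)


class TestReclassify:
    def test_empty_moves_identity(self, allo71):
        sc = allo71
        base, moved = reclassify_and_refit(sc.tree, sc.traits, sc.groups, {})
        pd.testing.assert_frame_equal(base.coef, moved.coef)

    def test_moves_change_only_group_columns(self, allo71):
        sc = allo71
        movers = list(sc.groups[sc.groups == "Paraves"].index[:2])
        base, moved = reclassify_and_refit(
            sc.tree, sc.traits, sc.groups, {t: "Aves" for t in movers})
        assert base.design_info["n_per_level"]["Aves"] + 2 == \
            moved.design_info["n_per_level"]["Aves"]

    def test_unknown_taxon_refused(self, allo71):
        sc = allo71
        with pytest.raises(PhylogenyError):
            reclassify_and_refit(sc.tree, sc.traits, sc.groups, {"nope": "Aves"})

    def test_common_slope_robust_to_reclassification(self):
        # when the true slope is shared, moving two taxa between adjacent
        # levels should barely move the estimated slopes
        sc = make_scenario("study71", seed=77, trait_model="allometry",
                           allometry={"slopes": {"Aves": 1.0, "Paraves": 1.0,
                                                 "other": 1.0}})
        movers = list(sc.groups[sc.groups == "Paraves"].index[:2])
        base, moved = reclassify_and_refit(
            sc.tree, sc.traits, sc.groups, {t: "Aves" for t in movers})
        b0 = base.coef["estimate"]["Femur: Aves"]
        b1 = moved.coef["estimate"]["Femur: Aves"]
        se = base.coef["se"]["Femur: Aves"]
        assert abs(b1 - b0) < 2 * se
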