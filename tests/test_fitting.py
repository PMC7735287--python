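import numpy as np
import pytest

from phylocomp import (
    ModelParams,
    ModelSpec,
    TraitVector,
    aicc,
    compare_models,
    comparison_table,
    fit_all_models,
    fit_model,
    loglik,
    moments,
    pgls_residuals,
    read_tree,
    simulate_traits,
    simulate_tree,
    standardize_depth,
)
from phylocomp.fitting import FitResult
from phylocomp.likelihoods import CovarianceWorkspace


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-10.0, 2, 20) == pytest.approx(24 + 12 / 17)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestFitModel:
    def test_bm_matches_closed_form_gls_estimator(self, bd_tree_25):
        x = simulate_traits(bd_tree_25, ModelSpec("BM", ModelParams(sig2=0.1)), 1, seed=8)[0]
        f = fit_model(bd_tree_25, x, "BM")
        C = bd_tree_25.shared_time_matrix()
        Ci = np.linalg.inv(C)
        ones = np.ones(len(x))
        z0 = (ones @ Ci @ x) / (ones @ Ci @ ones)
        sig2 = (x - z0) @ Ci @ (x - z0) / len(x)
        assert f.spec.params.sig2 == pytest.approx(sig2, rel=1e-6)
        assert f.spec.params.z0 == pytest.approx(z0, rel=1e-6)
        assert f.k == 2

    def test_bm_sig2_recovery_100_tips(self, bd_tree_100):
        X = simulate_traits(bd_tree_100, ModelSpec("BM", ModelParams(sig2=0.1)), 100, seed=1)
        ws = CovarianceWorkspace(bd_tree_100)
        est = [fit_model(bd_tree_100, x, "BM", workspace=ws).spec.params.sig2 for x in X]
        assert np.median(est) == pytest.approx(0.1, rel=0.10)

    def test_ml_dominance_over_truth(self, bd_tree_25):
        """Fitted likelihood always >= likelihood at the generating parameters."""
        gen = ModelSpec("OU", ModelParams(sig2=0.1, alpha=1.0))
        X = simulate_traits(bd_tree_25, gen, 10, seed=5)
        m_true = moments(bd_tree_25, gen)
        for x in X:
            f = fit_model(bd_tree_25, x, "OU")
            assert f.loglik >= loglik(x, m_true) - 1e-6

    def test_mc_on_s0_data_nesting(self, bd_tree_25):
        """On BM data, MC finds S near 0 and never beats BM by > 2 AICc (95%)."""
        X = simulate_traits(bd_tree_25, ModelSpec("BM", ModelParams(sig2=0.1)), 40, seed=2)
        ws = CovarianceWorkspace(bd_tree_25)
        wins = 0
        for x in X:
            fb = fit_model(bd_tree_25, x, "BM", workspace=ws)
            fm = fit_model(bd_tree_25, x, "MC", workspace=ws)
            assert fm.loglik >= fb.loglik - 1e-6  # nested model dominance
            if fm.aicc < fb.aicc - 2:
                wins += 1
        assert wins <= 2  # <= 5% of 40

    def test_too_few_tips(self):
        t = read_tree("(A:1,B:1);")
        with pytest.raises(ValueError):
            fit_model(t, np.array([0.0, 1.0]), "BM")

    def test_per_map_aggregation(self, bd_tree_25):
        from phylocomp.synthdata import simulate_mk_history

        maps = [
            simulate_mk_history(bd_tree_25, ["g1", "g2"], 0.5, seed=s) for s in (1, 2, 3)
        ]
        x = simulate_traits(bd_tree_25, ModelSpec("BM", ModelParams(sig2=0.1)), 1, seed=3)[0]
        f = fit_model(bd_tree_25, x, "DDexp", regimes=maps)
        assert len(f.per_map) == 3
        assert f.aicc == pytest.approx(np.mean([p.aicc for p in f.per_map]))
        assert f.map_id == "mean-of-3"


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "spec,getter,truth",
        [
            (ModelSpec("OU", ModelParams(sig2=0.1, alpha=1.0)), lambda f: f.spec.params.alpha, 1.0),
            (ModelSpec("DDexp", ModelParams(sig2=0.05, rate_n=0.03)), lambda f: f.spec.params.rate_n, 0.03),
            (ModelSpec("MC", ModelParams(sig2=0.1, S=-2.0)), lambda f: f.spec.params.S, -2.0),
        ],
        ids=["OU-alpha", "DDexp-rate", "MC-S"],
    )
    def test_median_within_25pct_at_100_tips(self, bd_tree_100, spec, getter, truth):
        X = simulate_traits(bd_tree_100, spec, 100, seed=2)
        ws = CovarianceWorkspace(bd_tree_100)
        est = [getter(fit_model(bd_tree_100, x, spec.name, workspace=ws)) for x in X]
        assert abs(np.median(est) - truth) <= 0.25 * abs(truth)


def _mk_fit(model, aicc_val, n=20, clade="c1", trait="pc1"):
    k = 2 if model == "BM" else 3
    return FitResult(
        spec=ModelSpec(model, ModelParams(sig2=1.0)),
        loglik=0.0, k=k, n=n, aicc=aicc_val, clade=clade, trait=trait,
    )


class TestCompareModels:
    def test_flag_fires_above_threshold(self):
        comp = compare_models(
            [_mk_fit("BM", 100.0), _mk_fit("OU", 99.0), _mk_fit("DDexp", 96.5)]
        )
        assert comp.best_model == "DDexp"
        assert comp.competition_flag is True

    def test_flag_respects_threshold(self):
        comp = compare_models([_mk_fit("BM", 100.0), _mk_fit("DDexp", 98.5)])
        assert comp.best_model == "DDexp"
        assert comp.competition_flag is False

    def test_order_invariance(self):
        fits = [_mk_fit("BM", 100.0), _mk_fit("OU", 99.0), _mk_fit("MC", 96.0)]
        a = compare_models(fits)
        b = compare_models(fits[::-1])
        assert a.best_model == b.best_model and a.delta_aicc == b.delta_aicc

    def test_tie_prefers_fewer_parameters(self):
        comp = compare_models([_mk_fit("OU", 50.0), _mk_fit("BM", 50.0)])
        assert comp.best_model == "BM"

    def test_empty_input(self):
        with pytest.raises(ValueError):
            compare_models([])

    def test_any_trait_flag(self):
        comps = []
        for trait, fits in [
            ("shape_pc2", [_mk_fit("BM", 100, trait="shape_pc2"), _mk_fit("DDexp", 95, trait="shape_pc2")]),
            ("size", [_mk_fit("BM", 100, trait="size"), _mk_fit("DDexp", 99.5, trait="size")]),
            ("mass", [_mk_fit("BM", 90, trait="mass"), _mk_fit("DDexp", 95, trait="mass")]),
        ]:
            comps.append(compare_models(fits))
        table = comparison_table(comps)
        assert table.flags[("c1", "shape_pc2")] is True
        assert table.flags[("c1", "size")] is False
        assert table.any_trait_flag["c1"] is True


class TestPgls:
    def test_star_phylogeny_equals_ols(self):
        t = read_tree("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        xv, yv = rng.normal(size=5), rng.normal(size=5)
        r = pgls_residuals(t, TraitVector(yv), TraitVector(xv))
        X = np.column_stack([np.ones(5), xv])
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        assert np.allclose(r.values, yv - X @ beta, atol=1e-10)

    def test_perfect_fit_zero_residuals(self, bd_tree_25):
        xv = np.linspace(-1, 1, 25)
        r = pgls_residuals(bd_tree_25, TraitVector(2 * xv + 1), TraitVector(xv))
        assert np.abs(r.values).max() < 1e-10

    def test_matches_dense_matrix_gls(self):
        tree = simulate_tree(5, seed=1)
        rng = np.random.default_rng(3)
        yv, xv = rng.normal(size=5), rng.normal(size=5)
        C = tree.shared_time_matrix()
        X = np.column_stack([np.ones(5), xv])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
        r = pgls_residuals(tree, TraitVector(yv), TraitVector(xv))
        assert np.allclose(r.values, yv - X @ beta, atol=1e-10)

    def test_constant_predictor_rejected(self, bd_tree_25):
        with pytest.raises(ValueError, match="singular"):
            pgls_residuals(
                bd_tree_25, TraitVector(np.arange(25.0)), TraitVector(np.ones(25))
            )
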