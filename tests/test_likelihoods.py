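import numpy as np
import pytest
from scipy.integrate import solve_ivp

from phylocomp import (
    ModelParams,
    ModelSpec,
    loglik,
    moments,
    moments_diversity,
    moments_independent,
    moments_mc,
    read_tree,
    simulate_traits,
)
from phylocomp.likelihoods import CovarianceWorkspace, TipMoments
from phylocomp.models import ParameterDomainError
from phylocomp.treeio import TreeValidationError

from conftest import single_guild_map


class TestIndependentMoments:
    def test_bm_closed_form(self, three_tip_tree):
        m = moments_independent(three_tip_tree, ModelSpec("BM", ModelParams(sig2=0.5)))
        lab = three_tip_tree.tip_labels
        a, b, c = lab.index("A"), lab.index("B"), lab.index("C")
        assert m.cov[a, a] == pytest.approx(1.0)
        assert m.cov[a, b] == pytest.approx(0.5)
        assert m.cov[a, c] == pytest.approx(0.0)

    def test_ou_closed_form(self, three_tip_tree):
        m = moments_independent(
            three_tip_tree, ModelSpec("OU", ModelParams(sig2=2.0, alpha=1.0))
        )
        lab = three_tip_tree.tip_labels
        a, b = lab.index("A"), lab.index("B")
        assert m.cov[a, b] == pytest.approx((1 - np.exp(-2)) * np.exp(-2), abs=1e-10)
        assert m.cov[a, a] == pytest.approx(1 - np.exp(-4), abs=1e-10)

    def test_ou_matches_branch_ode_integration(self, three_tip_tree):
        """Oracle: integrate dv/dt = sig2 - 2 alpha v down the path to a tip."""
        sig2, alpha = 1.7, 0.9
        m = moments_independent(
            three_tip_tree, ModelSpec("OU", ModelParams(sig2=sig2, alpha=alpha))
        )
        sol = solve_ivp(
            lambda t, v: sig2 - 2 * alpha * v, (0, 2), [0.0], rtol=1e-10, atol=1e-12
        )
        a = three_tip_tree.tip_labels.index("A")
        assert m.cov[a, a] == pytest.approx(sol.y[0, -1], abs=1e-8)
        # shared part: variance accrued to the MRCA, then decayed on both stems
        sol_shared = solve_ivp(
            lambda t, v: sig2 - 2 * alpha * v, (0, 1), [0.0], rtol=1e-10, atol=1e-12
        )
        b = three_tip_tree.tip_labels.index("B")
        assert m.cov[a, b] == pytest.approx(
            sol_shared.y[0, -1] * np.exp(-2 * alpha * 1.0), abs=1e-8
        )

    def test_tdlin_integral(self):
        t2 = read_tree("(A:2,B:2);")
        m = moments_independent(t2, ModelSpec("TDlin", ModelParams(sig2=1.0, slope_t=1.0)))
        assert m.cov[0, 0] == pytest.approx(4.0)
        assert m.cov[0, 1] == pytest.approx(0.0)

    def test_ou_rejects_non_ultrametric(self):
        t = read_tree("((A:1,B:2):1,C:2);")
        with pytest.raises(TreeValidationError):
            moments_independent(t, ModelSpec("OU", ModelParams(sig2=1.0, alpha=1.0)))


class TestDiversityMoments:
    def test_ddlin_piecewise_closed_form(self, balanced_four_tip):
        m = moments_diversity(
            balanced_four_tip, ModelSpec("DDlin", ModelParams(sig2=1.0, slope_n=0.5))
        )
        assert np.allclose(np.diag(m.cov), 5.0)

    def test_ddlin_vs_quadrature_oracle(self, bd_tree_25):
        from phylocomp import lineage_count

        spec = ModelSpec("DDexp", ModelParams(sig2=0.2, rate_n=0.08))
        m = moments_diversity(bd_tree_25, spec)
        lc = lineage_count(bd_tree_25)
        # brute-force quadrature of sig2 e^{r n(u)} for one tip's variance
        us = np.linspace(0, bd_tree_25.depth, 200001)[:-1] + bd_tree_25.depth / 400002
        vals = 0.2 * np.exp(0.08 * np.array([lc.count_at(u) for u in us[::100]]))
        integral = vals.mean() * bd_tree_25.depth
        assert m.cov[0, 0] == pytest.approx(integral, rel=1e-3)

    def test_zero_slope_reduces_to_bm(self, bd_tree_25):
        m = moments_diversity(bd_tree_25, ModelSpec("DDlin", ModelParams(sig2=0.7)))
        b = moments_independent(bd_tree_25, ModelSpec("BM", ModelParams(sig2=0.7)))
        assert np.allclose(m.cov, b.cov, atol=1e-12)

    def test_never_mixing_guilds_decompose_into_subtrees(
        self, balanced_four_tip, clade_guild_map
    ):
        spec = ModelSpec(
            "DDexp", ModelParams(sig2=0.5, rate_n=0.2), interaction_structured=True
        )
        m = moments_diversity(balanced_four_tip, spec, regimes=clade_guild_map)
        # oracle: within-guild block = subtree DDexp with its own n(t), plus
        # the stem integral (single lineage in the guild) shared by the pair
        sub = balanced_four_tip.extract_subtree(
            balanced_four_tip.children[balanced_four_tip.root][0]
        )
        msub = moments_diversity(sub, ModelSpec("DDexp", ModelParams(sig2=0.5, rate_n=0.2)))
        stem = 0.5 * np.exp(0.2 * 1) * 1.0  # one lineage, duration 1
        assert np.allclose(m.cov[:2, :2], msub.cov + stem, atol=1e-10)
        assert np.allclose(m.cov[:2, 2:], 0.0)

    def test_clamped_rate_rejected(self, balanced_four_tip):
        spec = ModelSpec("DDlin", ModelParams(sig2=1.0, slope_n=-0.26))
        with pytest.raises(ParameterDomainError):
            moments_diversity(balanced_four_tip, spec)


class TestMCMoments:
    def test_s0_is_exactly_bm(self, bd_tree_25):
        m = moments_mc(bd_tree_25, ModelSpec("MC", ModelParams(sig2=1.3, S=0.0)))
        b = moments_independent(bd_tree_25, ModelSpec("BM", ModelParams(sig2=1.3)))
        assert np.allclose(m.cov, b.cov, atol=1e-12)
        assert np.allclose(m.mean, b.mean)

    def test_two_tip_closed_form(self, two_tip_depth1):
        m = moments_mc(two_tip_depth1, ModelSpec("MC", ModelParams(sig2=1.0, S=-1.0)))
        var_w, var_s = np.e**2 - 1, 2.0
        assert m.cov[0, 0] == pytest.approx((var_w + var_s) / 4, abs=1e-10)
        assert m.cov[0, 1] == pytest.approx((var_s - var_w) / 4, abs=1e-10)

    def test_different_guilds_give_bm(self, two_tip_depth1):
        from phylocomp.simmap import RegimeMap

        rm = RegimeMap(two_tip_depth1, ["g1", "g2"], {0: [(0, 1.0)], 1: [(1, 1.0)]})
        spec = ModelSpec("MC", ModelParams(sig2=1.0, S=-5.0), interaction_structured=True)
        m = moments_mc(two_tip_depth1, spec, regimes=rm)
        assert np.allclose(m.cov, np.eye(2), atol=1e-12)

    def test_single_guild_equals_unstructured(self, bd_tree_25):
        spec = ModelSpec("MC", ModelParams(sig2=0.8, S=-2.0))
        m0 = moments_mc(bd_tree_25, spec)
        sg = single_guild_map(bd_tree_25)
        spec_s = ModelSpec(
            "MC", ModelParams(sig2=0.8, S=-2.0), interaction_structured=True
        )
        m1 = moments_mc(bd_tree_25, spec_s, regimes=sg)
        assert np.allclose(m0.cov, m1.cov, atol=1e-10)

    def test_positive_s_rejected(self, two_tip_depth1):
        with pytest.raises(ParameterDomainError):
            CovarianceWorkspace(two_tip_depth1).unit_cov("MC", 0.5)


ALL_SPECS = [
    ModelSpec("BM", ModelParams(sig2=0.3)),
    ModelSpec("OU", ModelParams(sig2=0.5, alpha=2.0)),
    ModelSpec("TDlin", ModelParams(sig2=0.5, slope_t=0.4)),
    ModelSpec("TDexp", ModelParams(sig2=0.5, rate_t=1.0)),
    ModelSpec("DDlin", ModelParams(sig2=0.5, slope_n=0.1)),
    ModelSpec("DDexp", ModelParams(sig2=0.2, rate_n=0.15)),
    ModelSpec("MC", ModelParams(sig2=0.5, S=-2.0)),
]


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.name)
def test_simulation_likelihood_consistency(spec):
    """Central oracle: analytic moments match empirical moments of 5000 sims."""
    from phylocomp import simulate_tree, standardize_depth

    tree = standardize_depth(simulate_tree(8, seed=42), 1.0)
    X = simulate_traits(tree, spec, 5000, seed=1)
    m = moments(tree, spec)
    th_var = np.diag(m.cov)
    se = th_var * np.sqrt(2.0 / 5000)
    assert np.all(np.abs(X.var(axis=0, ddof=1) - th_var) < 3.5 * se)
    # covariances: MC Euler paths carry O(h) discretization bias on top of
    # Monte-Carlo error, hence the looser gate for off-diagonals
    emp = np.cov(X.T)
    scale = np.sqrt(np.outer(th_var, th_var))
    tol = (4.0 if spec.name == "MC" else 3.5) * scale * np.sqrt(2.0 / 5000)
    assert np.all(np.abs(emp - m.cov) < tol + 1e-12)


def test_reductions_hold_as_likelihood_equalities(bd_tree_25):
    """TD/DD slope 0, OU alpha 0, MC S=0 all equal BM log-likelihood."""
    x = simulate_traits(bd_tree_25, ModelSpec("BM", ModelParams(sig2=0.1)), 1, seed=3)[0]
    ll_bm = loglik(x, moments(bd_tree_25, ModelSpec("BM", ModelParams(sig2=0.1))))
    for spec in [
        ModelSpec("OU", ModelParams(sig2=0.1, alpha=0.0)),
        ModelSpec("TDlin", ModelParams(sig2=0.1)),
        ModelSpec("TDexp", ModelParams(sig2=0.1)),
        ModelSpec("DDlin", ModelParams(sig2=0.1)),
        ModelSpec("DDexp", ModelParams(sig2=0.1)),
        ModelSpec("MC", ModelParams(sig2=0.1, S=0.0)),
    ]:
        assert loglik(x, moments(bd_tree_25, spec)) == pytest.approx(ll_bm, abs=1e-6)


class TestLoglik:
    def test_standard_normal(self):
        m = TipMoments(np.zeros(1), np.eye(1))
        assert loglik(np.zeros(1), m) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_dense_mvn_oracle(self, three_tip_tree):
        m = moments_independent(three_tip_tree, ModelSpec("BM", ModelParams(sig2=0.5)))
        x = np.array([0.1, -0.2, 0.4])
        V = m.cov
        brute = -0.5 * (
            3 * np.log(2 * np.pi)
            + np.log(np.linalg.det(V))
            + x @ np.linalg.inv(V) @ x
        )
        assert loglik(x, m) == pytest.approx(brute, abs=1e-10)

    def test_translation_invariance(self, three_tip_tree):
        m = moments_independent(three_tip_tree, ModelSpec("BM", ModelParams(sig2=0.5)))
        x = np.array([0.1, -0.2, 0.4])
        m2 = TipMoments(m.mean + 5.0, m.cov)
        assert loglik(x, m) == pytest.approx(loglik(x + 5.0, m2), abs=1e-10)


def test_covariance_invariant_to_tip_reordering(bd_tree_25):
    """Conjugating by a tip permutation leaves the model covariance intact."""
    from phylocomp import Phylogeny

    tree = bd_tree_25
    perm = np.random.default_rng(1).permutation(tree.n_tips)
    # rename tips according to perm; structure unchanged
    relabeled = Phylogeny(
        [tree.tip_labels[i] for i in np.argsort(perm)][: tree.n_tips],
        tree.parent.copy(),
        tree.edge_length.copy(),
    )
    spec = ModelSpec("MC", ModelParams(sig2=0.5, S=-1.0))
    a = moments(tree, spec).cov
    b = moments(relabeled, spec).cov
    assert np.allclose(a, b, atol=1e-10)  # same node indices, labels irrelevant
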