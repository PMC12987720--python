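import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from pleioscan.linemodels import (
    EMConfig,
    LineGroup,
    compare_one_vs_two,
    fit_em,
    gibbs_membership,
    group_covariance,
    mixture_loglik,
    responsibilities,
    scale_init,
    sharing_proportion,
)
from pleioscan.simulate import TraitArchitecture, simulate_effect_pairs


def noisy_pairs(arch, n, se, seed):
    eff, lab = simulate_effect_pairs(n, arch, seed)
    rng = np.random.default_rng(seed + 10_000)
    B = eff + rng.normal(0.0, se, size=eff.shape)
    S = np.full_like(B, se)
    return B, S, lab


class TestGroupCovariance:
    def test_slope_one_anchor(self):
        """At slope 1 the coordinate correlation of the prior equals rho."""
        sigma = group_covariance(LineGroup(slope=1.0, scale=0.1, correlation=0.99))
        assert np.allclose(sigma, 0.01 * np.array([[1, 0.99], [0.99, 1]]))

    def test_slope_zero_trait_only(self):
        sigma = group_covariance(LineGroup(slope=0.0, scale=1.0, correlation=0.99))
        assert np.allclose(sigma, np.diag([1.99, 0.01]))

    def test_isotropic_limit(self):
        for s in (-3.0, 0.0, 0.7):
            sigma = group_covariance(LineGroup(slope=s, scale=0.5, correlation=0.0))
            assert np.allclose(sigma, 0.25 * np.eye(2))

    def test_eigenstructure(self):
        """Eigen-decomposition oracle: eigenvalues tau^2(1 +- rho), principal
        axis along (1, s)."""
        g = LineGroup(slope=0.43, scale=0.2, correlation=0.9)
        w, V = np.linalg.eigh(group_covariance(g))
        assert sorted(w) == pytest.approx(sorted([0.04 * 1.9, 0.04 * 0.1]))
        v_max = V[:, np.argmax(w)]
        assert abs(v_max[1] / v_max[0]) == pytest.approx(0.43, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            LineGroup(slope=0.0, scale=0.0)
        with pytest.raises(ValueError):
            LineGroup(slope=0.0, scale=1.0, correlation=1.0)


class TestMixtureLoglik:
    def test_matches_direct_density_evaluation(self):
        rng = np.random.default_rng(1)
        B = rng.normal(0, 0.1, (20, 2))
        S = np.abs(rng.normal(0.05, 0.01, (20, 2))) + 0.01
        groups = [LineGroup(0.0, 0.1), LineGroup(1.0, 0.1)]
        pi = np.array([0.3, 0.7])
        want = 0.0
        for i in range(20):
            li = 0.0
            for g, p in zip(groups, pi):
                cov = group_covariance(g) + np.diag(S[i] ** 2)
                li += p * multivariate_normal.pdf(B[i], mean=[0, 0], cov=cov)
            want += math.log(li)
        assert mixture_loglik(B, S, groups, pi) == pytest.approx(want, rel=1e-10)

    def test_reflection_invariance(self):
        """Data reflected through the group line leaves the likelihood fixed."""
        rng = np.random.default_rng(2)
        B = rng.normal(0, 0.1, (50, 2))
        S = np.full((50, 2), 0.03)
        groups = [LineGroup(1.0, 0.1, 0.9)]
        # reflection through the slope-1 line swaps coordinates
        ll = mixture_loglik(B, S, groups, np.array([1.0]))
        ll_ref = mixture_loglik(B[:, ::-1], S, groups, np.array([1.0]))
        assert ll_ref == pytest.approx(ll, rel=1e-12)

    def test_degenerate_mixture_equals_single_group(self):
        rng = np.random.default_rng(3)
        B = rng.normal(0, 0.1, (30, 2))
        S = np.full((30, 2), 0.05)
        g1, g2 = LineGroup(0.0, 0.1), LineGroup(1.0, 0.1)
        assert mixture_loglik(B, S, [g1, g2], np.array([1.0, 0.0])) == \
            pytest.approx(mixture_loglik(B, S, [g1], np.array([1.0])), rel=1e-12)

    def test_prior_washed_out_at_huge_se(self):
        B = np.array([[0.01, -0.02]])
        S = np.full((1, 2), 50.0)
        lls = [mixture_loglik(B, S, [LineGroup(0.3, tau)], np.array([1.0]))
               for tau in (0.01, 0.5)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-4)

    def test_invalid_pi(self):
        B = np.zeros((3, 2)); S = np.ones((3, 2))
        with pytest.raises(ValueError):
            mixture_loglik(B, S, [LineGroup(0.0, 1.0)], np.array([0.5]))


class TestScaleInit:
    def test_percentile_rule(self):
        """95% of pooled |effects| lie within twice the initial scale."""
        rng = np.random.default_rng(4)
        B = rng.normal(0, 0.2, (400, 2))
        tau = scale_init(B)
        assert np.mean(np.abs(B) <= 2 * tau) == pytest.approx(0.95, abs=0.01)


class TestFitEM:
    def test_noise_free_line_recovers_slope(self):
        """Zero-noise limit: fitted slope matches regression through origin."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.2, 200)
        B = np.column_stack([x, 0.5 * x])
        S = np.full_like(B, 1e-4)
        groups = [LineGroup(1.0, scale_init(B), 0.999, slope_free=True)]
        fit = fit_em(B, S, groups)
        assert fit.groups[0].slope == pytest.approx(0.5, abs=0.01)

    def test_balanced_two_group_proportions(self):
        arch = TraitArchitecture(
            groups=[LineGroup(0.0, 0.15, 0.99, label="only"),
                    LineGroup(1.0, 0.15, 0.99, label="shared")],
            proportions=(0.5, 0.5))
        B, S, _ = noisy_pairs(arch, 400, se=0.02, seed=6)
        groups = [LineGroup(0.0, 0.15, 0.99), LineGroup(1.0, 0.15, 0.99, slope_free=True)]
        fit = fit_em(B, S, groups)
        assert fit.pi[0] == pytest.approx(0.5, abs=0.05)

    def test_single_fixed_group_is_direct_evaluation(self):
        rng = np.random.default_rng(7)
        B = rng.normal(0, 0.1, (50, 2))
        S = np.full((50, 2), 0.05)
        g = LineGroup(0.3, 0.1)
        fit = fit_em(B, S, [g])
        assert fit.pi == pytest.approx([1.0])
        assert fit.loglik == pytest.approx(
            mixture_loglik(B, S, [g], np.array([1.0])), rel=1e-12)

    def test_loglik_monotone_nondecreasing(self):
        arch = TraitArchitecture()
        B, S, _ = noisy_pairs(arch, 300, se=0.05, seed=8)
        groups = [LineGroup(0.0, 0.15, 0.99),
                  LineGroup(1.0, 0.15, 0.99, slope_free=True)]
        fit = fit_em(B, S, groups)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-7)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((1, 2)), np.ones((1, 2)), [LineGroup(0.0, 1.0)])
        with pytest.raises(ValueError):
            fit_em(np.zeros((5, 3)), np.ones((5, 3)), [LineGroup(0.0, 1.0)])


class TestModelComparison:
    def test_one_group_null_keeps_statistic_small(self):
        stats = []
        for seed in range(8):
            arch = TraitArchitecture(
                groups=[LineGroup(0.43, 0.15, 0.99)], proportions=(1.0,))
            B, S, _ = noisy_pairs(arch, 200, se=0.05, seed=seed)
            stats.append(compare_one_vs_two(B, S, scale=0.15)["stat"])
        assert np.median(stats) < 5.0
        # nesting: non-negative up to the EM convergence tolerance
        assert min(stats) >= -1e-3

    def test_two_group_power(self):
        hits = 0
        for seed in range(8):
            B, S, _ = noisy_pairs(TraitArchitecture(), 400, se=0.05, seed=100 + seed)
            r = compare_one_vs_two(B, S, scale=0.15)
            hits += r["stat"] > 20 and r["strong_evidence"]
        assert hits >= 7


class TestGibbs:
    def test_fixed_pi_matches_closed_form(self):
        B, S, _ = noisy_pairs(TraitArchitecture(), 100, se=0.05, seed=11)
        groups = [LineGroup(0.0, 0.15, 0.99), LineGroup(0.43, 0.15, 0.99)]
        pi = np.array([0.6, 0.4])
        fit = fit_em(B, S, groups, pi_init=pi)
        resp = responsibilities(B, S, groups, fit.pi)
        g = gibbs_membership(B, S, fit, n_iter=4000, burn_in=500, seed=3,
                             pi_fixed=fit.pi)
        kept = 3500
        se = np.maximum(g.mc_se, np.sqrt(resp * (1 - resp) / kept)) + 1.0 / kept
        dev = np.abs(g.membership - resp) / se
        # per-entry 3-se check with the usual multiple-comparison allowance:
        # ~99.7% of 200 entries should sit inside 3 se, none far outside
        assert np.mean(dev <= 3.0) >= 0.99
        assert np.max(dev) <= 6.0

    def test_symmetric_origin_pair(self):
        B = np.array([[0.0, 0.0]])
        S = np.array([[0.05, 0.05]])
        groups = [LineGroup(0.5, 0.1, 0.9), LineGroup(-0.5, 0.1, 0.9)]
        fit = fit_em(np.vstack([B, B]), np.vstack([S, S]), groups)
        g = gibbs_membership(np.vstack([B, B]), np.vstack([S, S]), fit,
                             n_iter=4000, burn_in=500, seed=4,
                             pi_fixed=np.array([0.5, 0.5]))
        assert g.membership[0, 0] == pytest.approx(0.5, abs=0.05)

    def test_extreme_pair_assigned_decisively(self):
        B = np.array([[0.1, 0.001]] * 5)
        S = np.full((5, 2), 0.002)
        groups = [LineGroup(0.0, 0.05, 0.99), LineGroup(1.0, 0.05, 0.99)]
        resp = responsibilities(B, S, groups, np.array([0.5, 0.5]))
        assert resp[0, 0] > 0.99

    def test_iteration_validation(self):
        B = np.zeros((2, 2)); S = np.ones((2, 2))
        fit = fit_em(B, S, [LineGroup(0.0, 1.0)])
        with pytest.raises(ValueError):
            gibbs_membership(B, S, fit, n_iter=100, burn_in=100)


class TestSharingProportion:
    def test_all_shared(self):
        r = sharing_proportion(np.ones(10), np.full(10, 1e-20))
        assert r["fraction_shared"] == 1.0 and r["n_top"] == 10

    def test_direct_count_at_cutoff(self):
        post = np.array([0.9, 0.7, 0.85])
        p1 = np.full(3, 1e-20)
        r = sharing_proportion(post, p1)
        assert r["fraction_shared"] == pytest.approx(2 / 3)

    def test_confidence_tiers(self):
        post = np.array([0.999, 0.96, 0.5, 0.2])
        r = sharing_proportion(post, np.full(4, 1e-20))
        assert r["n_99"] == 1 and r["n_95"] == 2

    def test_empty_after_filter(self):
        with pytest.raises(ValueError):
            sharing_proportion(np.array([0.9]), np.array([0.5]))


def test_parameter_recovery_slope_grid():
    """Generating at several true slopes and refitting recovers each one."""
    for true_slope in (-0.37, 0.13, 0.99):
        arch = TraitArchitecture(
            groups=[LineGroup(0.0, 0.15, 0.99, label="only"),
                    LineGroup(true_slope, 0.15, 0.99, label="shared")],
            proportions=(0.5, 0.5))
        B, S, _ = noisy_pairs(arch, 400, se=0.05, seed=int(abs(true_slope) * 1000))
        groups = [LineGroup(0.0, 0.15, 0.99),
                  LineGroup(1.0, 0.15, 0.99, slope_free=True)]
        fit = fit_em(B, S, groups)
        assert fit.groups[1].slope == pytest.approx(true_slope, abs=0.05)
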