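"""TCC-v likelihood family: probabilities, gradients, fits, comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import colorcat as cc
from colorcat import _kernels
from colorcat.tccv import (
    TccvModel,
    _Objective,
    choice_probability,
    fit,
    fit_free_similarity,
    information_criteria,
    negative_log_likelihood,
    similarity,
    similarity_matrix,
)


def quad_choice_probability(m, delta):
    """Adaptive-quadrature oracle for the max-of-Gaussians race."""
    m = np.asarray(m, float)
    out = []
    for n in range(len(m)):
        others = np.delete(m, n)

        def integrand(x):
            return norm.pdf(x) * np.prod(norm.cdf(x + delta * (m[n] - others)))

        out.append(quad(integrand, -12, 12, epsabs=1e-11, limit=200)[0])
    return np.array(out)


class TestSimilarity:
    def test_match_has_unit_similarity(self, sset):
        for model in (
            TccvModel("null", sigma=20.0, dprime=1.0),
            TccvModel("stimulus_nonuniformity", sigma=20.0, dprime=1.0,
                      distances=np.full(64, 5.625)),
        ):
            assert similarity(model, sset, 10, 10) == pytest.approx(1.0)

    def test_uniform_distances_reduce_to_null(self, sset):
        null = TccvModel("null", sigma=22.0, dprime=1.0)
        warp = TccvModel("stimulus_nonuniformity", sigma=22.0, dprime=1.0,
                         distances=np.full(64, 5.625))
        np.testing.assert_allclose(
            similarity_matrix(null, sset), similarity_matrix(warp, sset), atol=1e-12
        )

    def test_offset_shifts_peak_toward_higher_hue(self, sset):
        offsets = np.full(64, 5.625)
        model = TccvModel("cognitive_bias", sigma=20.0, dprime=1.0, offsets=offsets)
        S = similarity_matrix(model, sset)
        # counterclockwise neighbor now more similar than clockwise one
        assert S[10, 11] > S[10, 9]
        assert S[10, 11] == pytest.approx(1.0)

    def test_parameter_counts(self):
        assert TccvModel("null", sigma=20.0).n_params == 2
        m = TccvModel("cognitive_bias", sigma=20.0, offsets=np.zeros(64))
        assert m.n_params == 66
        m = TccvModel("stimulus_nonuniformity", sigma=20.0,
                      distances=np.full(64, 5.625))
        assert m.n_params == 66
        assert m.effective_n_params == 65
        m = TccvModel("free_similarity", similarity_values=np.eye(64))
        assert m.n_params == 4096

    def test_distances_must_sum_to_circle(self):
        with pytest.raises(ValueError):
            TccvModel("stimulus_nonuniformity", sigma=20.0, distances=np.full(64, 5.0))


class TestChoiceProbability:
    def test_equal_similarities_uniform(self):
        np.testing.assert_allclose(choice_probability([0.4] * 4, 1.3), 0.25, atol=1e-12)

    def test_zero_sensitivity_uniform(self):
        np.testing.assert_allclose(
            choice_probability([0.9, 0.1, 0.5, 0.3], 0.0), 0.25, atol=1e-12
        )

    def test_two_choice_closed_form(self):
        # P(X1 > X2) = Phi((m1 - m2) * delta / sqrt(2))
        p = choice_probability([1.0, 0.0], 1.0)
        assert p[0] == pytest.approx(norm.cdf(1.0 / math.sqrt(2.0)), abs=1e-9)

    def test_against_monte_carlo(self):
        m = np.array([1.0, 0.0, 0.0, 0.0])
        p = choice_probability(m, 1.0)
        rng = np.random.default_rng(2024)
        n = 10_000_000
        x = m[None, :] * 1.0 + rng.standard_normal((n, 4))
        freq = np.bincount(np.argmax(x, axis=1), minlength=4) / n
        se = np.sqrt(freq * (1 - freq) / n)
        assert np.all(np.abs(p - freq) < 3 * se + 1e-7)

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            choice_probability([1, 0, 0, 0], -0.5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        m=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        delta=st.floats(0, 8),
    )
    def test_probabilities_sum_to_one(self, m, delta):
        assert choice_probability(m, delta).sum() == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        m=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        delta=st.floats(0.1, 6),
        perm=st.permutations(range(4)),
    )
    def test_permutation_equivariance(self, m, delta, perm):
        m = np.asarray(m)
        p = choice_probability(m, delta)
        q = choice_probability(m[list(perm)], delta)
        np.testing.assert_allclose(q, p[list(perm)], atol=1e-12)

    def test_monotone_in_own_similarity(self):
        base = np.array([0.5, 0.4, 0.3, 0.2])
        deltas = [0.3, 1.0, 3.0]
        for d in deltas:
            lo = choice_probability(base, d)[0]
            bumped = base.copy()
            bumped[0] += 0.2
            assert choice_probability(bumped, d)[0] > lo


class TestNLL:
    def test_arithmetic_on_uniform_choices(self, sset):
        # two trials whose selected-choice probability is exactly 1/4
        from colorcat.trials import TrialTable

        t = TrialTable(
            cue=[0, 0],
            choices=[[0, 16, 32, 48], [0, 16, 32, 48]],
            selected=[2, 3],
            stimulus_set=sset,
        )
        model = TccvModel("null", sigma=20.0, dprime=0.0)
        assert negative_log_likelihood(model, t) == pytest.approx(2 * math.log(4), abs=1e-9)

    def test_vanishes_for_deterministic_correct_data(self, sset):
        t = cc.generate_trials(cc.GroundTruth("null", sigma=5.0, dprime=40.0), sset,
                               300, seed=3)
        assert t.accuracy() == 1.0
        model = TccvModel("null", sigma=5.0, dprime=40.0)
        assert negative_log_likelihood(model, t) / t.n_trials < 1e-3

    def test_matches_adaptive_quadrature_per_trial(self, sset, null_table):
        model = TccvModel("null", sigma=20.0, dprime=2.0)
        sub = null_table.subset(np.arange(25))
        nll = negative_log_likelihood(model, sub)
        S = similarity_matrix(model, sset)
        total = 0.0
        for i in range(sub.n_trials):
            m = S[sub.cue[i], sub.choices[i]]
            p = quad_choice_probability(m, model.dprime)[sub.selected[i] - 1]
            total -= math.log(p)
        assert nll == pytest.approx(total, abs=1e-7)

    def test_kernel_backends_agree(self):
        rng = np.random.default_rng(5)
        msel = rng.random(200)
        mfoil = rng.random((200, 3))
        nodes, weights = _kernels.gh_nodes(61)
        P1, q1 = _kernels.selected_prob_grad_numpy(msel, mfoil, 1.7, nodes, weights)
        P2, q2 = _kernels.selected_prob_grad(msel, mfoil, 1.7, nodes, weights)
        np.testing.assert_allclose(P1, P2, atol=1e-12)
        np.testing.assert_allclose(q1, q2, atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("variant", ["null", "cognitive_bias", "stimulus_nonuniformity"])
    def test_analytic_gradient_matches_finite_differences(self, sset, variant):
        t = cc.generate_trials(cc.GroundTruth("null", sigma=18.0, dprime=1.2),
                               sset, 300, seed=17)
        obj = _Objective(variant, t)
        rng = np.random.default_rng(0)
        dim = {"null": 2, "cognitive_bias": 66, "stimulus_nonuniformity": 65}[variant]
        x0 = np.concatenate([[math.log(20.0), math.log(1.5)], rng.normal(0, 0.2, dim - 2)])
        _, g = obj(x0)
        for i in rng.choice(dim, size=min(dim, 6), replace=False):
            e = np.zeros(dim)
            e[i] = 1e-6
            num = (obj(x0 + e)[0] - obj(x0 - e)[0]) / 2e-6
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_free_similarity_gradient(self, sset):
        t = cc.generate_trials(cc.GroundTruth("null", sigma=18.0, dprime=1.2),
                               sset, 100, seed=18)
        obj = _Objective("free_similarity", t, dprime_fixed=1.0)
        rng = np.random.default_rng(1)
        x0 = rng.normal(0, 1, 64 * 64)
        _, g = obj(x0)
        cells = [t.cue[0] * 64 + t.choices[0, 0], t.cue[3] * 64 + t.choices[3, 2]]
        for i in cells:
            e = np.zeros(64 * 64)
            e[i] = 1e-6
            num = (obj(x0 + e)[0] - obj(x0 - e)[0]) / 2e-6
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestInformationCriteria:
    def test_worked_example(self):
        aic, bic = information_criteria(nll=50.0, k=2, n=100)
        assert aic == pytest.approx(104.0)
        assert bic == pytest.approx(2 * math.log(100) + 100)

    @settings(derandomize=True, max_examples=30)
    @given(k=st.integers(1, 5000), n=st.integers(1, 10**6),
           nll=st.floats(0, 1e6))
    def test_bic_aic_identity(self, k, n, nll):
        aic, bic = information_criteria(nll, k, n)
        # abs term covers float cancellation when nll dominates the identity
        assert bic - aic == pytest.approx(k * (math.log(n) - 2), rel=1e-9, abs=1e-7)


class TestFitting:
    def test_null_parameter_recovery_small(self, sset):
        truth = cc.GroundTruth("null", sigma=25.0, dprime=2.0)
        t = cc.generate_trials(truth, sset, 8000, seed=55)
        res = fit("null", t, restarts=1, seed=0, n_nodes=31)
        assert res.converged
        assert res.model.sigma == pytest.approx(25.0, rel=0.10)
        assert res.model.dprime == pytest.approx(2.0, rel=0.10)

    def test_nested_models_never_fit_worse(self, sset, scenarios):
        cognitive, _ = scenarios
        t = cc.generate_trials(cognitive, sset, 6000, seed=56)
        kw = dict(restarts=1, seed=0, n_nodes=31, ftol=1e-8)
        nll_null = fit("null", t, **kw).nll
        nll_cog = fit("cognitive_bias", t, **kw).nll
        nll_non = fit("stimulus_nonuniformity", t, **kw).nll
        assert nll_cog <= nll_null + 1e-3
        assert nll_non <= nll_null + 1e-3

    def test_free_similarity_ridge_on_null_data(self, sset, null_table):
        res = fit_free_similarity(null_table, dprime_fixed=1.0, seed=0, n_nodes=31,
                                  maxiter=150)
        S = res.model.similarity_values
        assert res.n_params == 4096
        assert res.uninformed_cells is not None
        informative = ~res.uninformed_cells
        diag = np.diag(S)
        off = S[informative & ~np.eye(64, dtype=bool)]
        assert np.nanmean(diag) > np.nanmean(off) + 0.2  # ridge on the diagonal
        # near mirror symmetry about the diagonal in expectation
        sym = np.nanmean(np.abs(S - S.T))
        assert sym < 0.25

    def test_bootstrap_compare_is_deterministic(self, sset, scenarios):
        _, nonuniform = scenarios
        tables = [cc.generate_trials(nonuniform, sset, 3000, seed=s) for s in (1, 2)]
        kw = dict(B=2, n_draw=1500, seed=9, restarts=1, n_nodes=31, maxiter=60,
                  ftol=1e-6)
        a = cc.bootstrap_compare(tables, **kw)
        b = cc.bootstrap_compare(tables, **kw)
        np.testing.assert_array_equal(a["bic"], b["bic"])
        assert a["wins"] == b["wins"]
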