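import numpy as np
import pytest
from scipy.stats import beta as sp_beta

from phylofunc import (
    AnnotatedTreeSet,
    AnnotationSet,
    MCMCSettings,
    ModelParameters,
    OptimSettings,
    PriorSet,
    gelman_rubin,
    log_posterior,
    map_estimate,
    mcmc,
    mle,
    pooled_loglik,
    simulate_tree,
    summarize,
)
from phylofunc.inference import MCMCTrace, ParameterSpace, _reflect
from phylofunc.model import PARAM_NAMES, BetaPrior
from phylofunc.simulate import observe_states, simulate_states


@pytest.fixture(scope="module")
def small_pooled_data():
    """20 fully annotated 100-leaf trees simulated from known parameters."""
    true = ModelParameters(pi=0.1, mu01_d=0.9, mu10_d=0.5,
                           mu01_s=0.05, mu10_s=0.05, psi01=0.0, psi10=0.0)
    data = AnnotatedTreeSet()
    for i in range(20):
        tree = simulate_tree(100, p_dup=0.2, seed=100 + i)
        states = simulate_states(tree, true, seed=200 + i)
        ann = observe_states(states, tree, true, seed=300 + i)
        data.add(tree, ann, "fn")
    return true, data


class TestLogPosterior:
    def test_uniform_prior_equals_loglik(self, toy_tree):
        params = ModelParameters(0.4, 0.9, 0.5, 0.1, 0.05, 0.1, 0.02)
        data = AnnotatedTreeSet()
        data.add(toy_tree, AnnotationSet({("A", "f"): 1, ("C", "f"): 0}), "f")
        assert log_posterior(params, PriorSet.uniform(), data) == pytest.approx(
            pooled_loglik(data, params), abs=1e-12)

    def test_empty_data_equals_sum_of_beta_logdensities(self):
        params = ModelParameters.from_array(np.linspace(0.1, 0.7, 7))
        priors = PriorSet.constant(2, 9)
        expected = sum(sp_beta.logpdf(v, 2, 9) for v in params.to_array())
        assert log_posterior(params, priors, AnnotatedTreeSet()) == pytest.approx(
            expected, abs=1e-10)


class TestReflection:
    @pytest.mark.parametrize("x,expected", [
        (1.07, 0.93), (-0.2, 0.2), (0.5, 0.5), (0.0, 0.0), (1.0, 1.0),
        (2.3, 0.3), (-1.6, 0.4),
    ])
    def test_folding(self, x, expected):
        assert _reflect(np.array([x]))[0] == pytest.approx(expected)

    def test_result_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, size=1000)
        y = _reflect(x)
        assert np.all((y >= 0) & (y <= 1))


class TestMCMC:
    def test_same_seed_gives_bit_identical_traces(self):
        data = AnnotatedTreeSet()
        s = MCMCSettings(n_iter=1000, n_chains=2)
        t1 = mcmc(data, PriorSet.constant(2, 9), s, seed=5)
        t2 = mcmc(data, PriorSet.constant(2, 9), s, seed=5)
        np.testing.assert_array_equal(t1.draws, t2.draws)

    def test_kept_draw_count_matches_contract(self):
        s = MCMCSettings(n_iter=3000, n_chains=1)
        t = mcmc(AnnotatedTreeSet(), PriorSet.uniform(), s, seed=1)
        assert t.n_kept == int(3000 * 0.5 / 10)

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            mcmc(AnnotatedTreeSet(), settings=MCMCSettings(n_iter=100), seed=0)

    def test_empty_data_recovers_prior_moments(self):
        # prior target Beta(2, 9): mean 2/11, sd ~0.116
        s = MCMCSettings(n_iter=8000, n_chains=2)
        t = mcmc(AnnotatedTreeSet(), PriorSet.constant(2, 9), s, seed=11)
        draws = t.stacked()
        prior_mean, prior_sd = 2 / 11, np.sqrt(2 * 9 / (11**2 * 12))
        assert np.all(np.abs(draws.mean(axis=0) - prior_mean) < 0.03)
        assert np.all(np.abs(draws.std(axis=0) - prior_sd) < 0.03)

    def test_fixed_parameters_are_not_sampled(self):
        s = MCMCSettings(n_iter=1000, n_chains=1, fix={"psi01": 0.0, "psi10": 0.0})
        t = mcmc(AnnotatedTreeSet(), PriorSet.uniform(), s, seed=2)
        assert "psi01" not in t.param_names
        assert summarize(t).point.psi01 == 0.0

    def test_baseline_model_has_five_parameters(self):
        s = MCMCSettings(n_iter=1000, n_chains=1, baseline=True)
        t = mcmc(AnnotatedTreeSet(), PriorSet.uniform(), s, seed=3)
        assert t.param_names == ("pi", "mu01", "mu10", "psi01", "psi10")
        pt = summarize(t).point
        assert pt.mu01_d == pt.mu01_s and pt.mu10_d == pt.mu10_s

    def test_trace_csv_roundtrip(self, tmp_path):
        s = MCMCSettings(n_iter=1000, n_chains=2)
        t = mcmc(AnnotatedTreeSet(), PriorSet.constant(2, 9), s, seed=4)
        path = tmp_path / "trace.csv"
        t.to_csv(path)
        back = MCMCTrace.from_csv(path, meta=t.meta)
        np.testing.assert_allclose(back.draws, t.draws, rtol=1e-12)


class TestGelmanRubin:
    def test_identical_chains_converged(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 0.4, size=(1, 200, 2))
        trace = MCMCTrace(np.concatenate([x, x]), ("a", "b"), {})
        psrf = gelman_rubin(trace)
        assert all(abs(v - 1.0) < 0.01 for v in psrf.values())

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        c1 = rng.normal(0.2, 0.001, size=(1, 100, 1))
        c2 = rng.normal(0.8, 0.001, size=(1, 100, 1))
        trace = MCMCTrace(np.concatenate([c1, c2]), ("a",), {})
        assert gelman_rubin(trace)["a"] > 1.1

    def test_single_chain_is_an_error(self):
        trace = MCMCTrace(np.zeros((1, 100, 1)), ("a",), {})
        with pytest.raises(ValueError):
            gelman_rubin(trace)

    def test_stationary_sampler_passes_threshold(self):
        s = MCMCSettings(n_iter=10_000, n_chains=2)
        t = mcmc(AnnotatedTreeSet(), PriorSet.constant(2, 9), s, seed=8)
        assert all(v < 1.1 for v in gelman_rubin(t).values())


class TestSummarize:
    def test_constant_trace(self):
        trace = MCMCTrace(np.full((2, 50, 7), 0.3), PARAM_NAMES, {})
        pt = summarize(trace).point
        assert all(getattr(pt, n) == pytest.approx(0.3) for n in PARAM_NAMES)

    def test_mean_matches_independent_computation(self):
        rng = np.random.default_rng(3)
        draws = rng.uniform(0, 1, size=(3, 40, 7))
        trace = MCMCTrace(draws, PARAM_NAMES, {})
        np.testing.assert_allclose(summarize(trace).point.to_array(),
                                   draws.reshape(-1, 7).mean(axis=0), rtol=1e-12)


class TestOptimization:
    def test_mle_recovers_generating_parameters(self, small_pooled_data):
        true, data = small_pooled_data
        est = mle(data, OptimSettings(fix={"psi01": 0.0, "psi10": 0.0},
                                      n_starts=4), seed=0)
        assert est.converged
        for name in ("mu01_d", "mu10_d", "mu01_s", "mu10_s"):
            assert getattr(est.point, name) == pytest.approx(
                getattr(true, name), abs=0.1)
        # the maximized likelihood dominates the truth's likelihood
        assert est.loglik >= pooled_loglik(data, true) - 1e-6

    def test_mle_requires_annotations(self):
        with pytest.raises(ValueError):
            mle(AnnotatedTreeSet(), seed=0)

    def test_flat_likelihood_flagged_non_identifiable(self, two_leaf_tree):
        # with mu = 0.5 the likelihood is constant in pi
        data = AnnotatedTreeSet()
        data.add(two_leaf_tree, AnnotationSet({("A", "f"): 1, ("B", "f"): 1}), "f")
        est = mle(data, OptimSettings(
            fix={"mu01_d": 0.5, "mu10_d": 0.5, "mu01_s": 0.5, "mu10_s": 0.5,
                 "psi01": 0.0, "psi10": 0.0}), seed=1)
        assert not est.identifiable

    def test_map_empty_data_finds_prior_mode(self):
        est = map_estimate(AnnotatedTreeSet(), PriorSet.constant(2, 9), seed=0)
        for name in PARAM_NAMES:
            assert getattr(est.point, name) == pytest.approx(1 / 9, abs=1e-4)

    def test_map_with_uniform_prior_matches_mle(self, small_pooled_data):
        _, data = small_pooled_data
        opts = OptimSettings(fix={"psi01": 0.0, "psi10": 0.0}, n_starts=4)
        est_mle = mle(data, opts, seed=0)
        est_map = map_estimate(data, PriorSet.uniform(), opts, seed=0)
        np.testing.assert_allclose(est_map.point.to_array(),
                                   est_mle.point.to_array(), atol=1e-3)

    def test_strong_prior_dominates_single_annotation(self, two_leaf_tree):
        data = AnnotatedTreeSet()
        data.add(two_leaf_tree, AnnotationSet({("A", "f"): 1}), "f")
        est = map_estimate(data, PriorSet.constant(2, 9), seed=0)
        for name in ("mu01_s", "mu10_s", "psi01", "psi10"):
            assert abs(getattr(est.point, name) - 1 / 9) < 0.05


class TestParameterSpace:
    def test_roundtrip_free_vector(self):
        space = ParameterSpace(fix={"psi10": 0.25})
        v = np.linspace(0.1, 0.6, space.dim)
        p = space.to_params(v)
        assert p.psi10 == 0.25
        assert p.pi == pytest.approx(0.1)

    def test_unknown_fixed_name_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace(fix={"nope": 0.1})
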