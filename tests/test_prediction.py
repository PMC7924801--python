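import numpy as np
import pytest

from phylofunc import (
    AnnotationSet,
    ModelParameters,
    brute_force_posteriors,
    credible_intervals,
    high_confidence,
    loo_predictions,
    node_posteriors,
    prune,
    read_tree,
)
from phylofunc.inference import MCMCTrace
from phylofunc.model import PARAM_NAMES

from conftest import random_instance


def post_by_label(table):
    return dict(zip(table["node"], table["posterior_prob"]))


class TestNodePosteriors:
    def test_no_annotations_prior_propagation(self, toy_tree):
        params = ModelParameters(0.3, 0.9, 0.5, 0.1, 0.05, 0.0, 0.0)
        table = node_posteriors(toy_tree, AnnotationSet(), params)
        post = post_by_label(table)
        assert post["r"] == pytest.approx(params.pi, abs=1e-12)
        # chained marginal: root (duplication) -> n1 (speciation) -> A
        pr = np.array([1 - params.pi, params.pi])
        at_n1 = pr @ params.transition_matrix("duplication")
        at_a = at_n1 @ params.transition_matrix("speciation")
        assert post["n1"] == pytest.approx(at_n1[1], abs=1e-12)
        assert post["A"] == pytest.approx(at_a[1], abs=1e-12)

    def test_error_free_observation_pins_the_leaf(self, toy_tree):
        params = ModelParameters(0.3, 0.9, 0.5, 0.1, 0.05, 0.0, 0.0)
        ann = AnnotationSet({("A", "f"): 1, ("B", "f"): 0})
        post = post_by_label(node_posteriors(toy_tree, ann, params))
        assert post["A"] == pytest.approx(1.0, abs=1e-12)
        assert post["B"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle(self, seed):
        tree, ann, params = random_instance(seed)
        mine = node_posteriors(tree, ann, params)
        exact = brute_force_posteriors(tree, ann, params)
        np.testing.assert_allclose(mine["posterior_prob"].to_numpy(),
                                   exact["posterior_prob"].to_numpy(),
                                   atol=1e-10)

    def test_root_posterior_closed_form(self):
        tree, ann, params = random_instance(77)
        if len(ann) == 0:
            pytest.skip("no annotations drawn")
        _, cache = prune(tree, ann, params, reduced=False)
        i = int(np.nonzero(cache.flat.orig_ids == tree.root.id)[0][0])
        l0, l1 = cache.partials[i]
        expected = params.pi * l1 / (params.pi * l1 + (1 - params.pi) * l0)
        post = post_by_label(node_posteriors(tree, ann, params))
        assert post[tree.root.label] == pytest.approx(expected, abs=1e-12)

    def test_posterior_in_unit_interval_everywhere(self):
        tree, ann, params = random_instance(5)
        p = node_posteriors(tree, ann, params)["posterior_prob"].to_numpy()
        assert np.all((p >= 0) & (p <= 1))


class TestLeaveOneOut:
    def test_single_annotation_reduces_to_prior_marginal(self, toy_tree):
        params = ModelParameters(0.3, 0.9, 0.5, 0.1, 0.05, 0.0, 0.0)
        ann = AnnotationSet({("A", "f"): 1})
        loo = loo_predictions(toy_tree, ann, params)
        assert len(loo) == 1
        empty = post_by_label(node_posteriors(toy_tree, AnnotationSet(), params))
        assert loo["posterior_prob"].iloc[0] == pytest.approx(empty["A"], abs=1e-12)
        assert bool(loo["loo"].iloc[0])

    def test_definitional_identity_with_held_out_set(self, toy_tree):
        params = ModelParameters(0.3, 0.9, 0.5, 0.1, 0.05, 0.1, 0.02)
        ann = AnnotationSet({("A", "f"): 1, ("C", "f"): 0, ("D", "f"): 1})
        loo = loo_predictions(toy_tree, ann, params)
        for _, row in loo.iterrows():
            direct = post_by_label(node_posteriors(
                toy_tree, ann.without(row["node"], "f"), params))
            assert row["posterior_prob"] == pytest.approx(
                direct[row["node"]], abs=1e-12)

    def test_annotated_sibling_pulls_prediction_up(self):
        # sibling under a speciation parent annotated 1, small mu, psi=0
        tree = read_tree("((A,B)n1,C)r;",
                         events={"n1": "speciation", "r": "speciation"})
        params = ModelParameters(0.5, 0.05, 0.05, 0.05, 0.05, 0.0, 0.0)
        ann = AnnotationSet({("A", "f"): 1, ("B", "f"): 1})
        loo = loo_predictions(tree, ann, params)
        assert (loo["posterior_prob"] > 0.5).all()

    def test_requires_annotations(self, toy_tree):
        with pytest.raises(ValueError):
            loo_predictions(toy_tree, AnnotationSet(),
                            ModelParameters.baseline(0.5, 0.5, 0.5, 0, 0))


def constant_trace(value=0.3, n=40):
    return MCMCTrace(np.full((2, n, 7), value), PARAM_NAMES, {})


class TestCredibleIntervals:
    def test_degenerate_trace_gives_zero_width(self, toy_tree):
        ann = AnnotationSet({("A", "f"): 1})
        table = credible_intervals(toy_tree, ann, constant_trace(), n_draws=10)
        np.testing.assert_allclose(table["ci_low"], table["posterior_prob"],
                                   atol=1e-12)
        np.testing.assert_allclose(table["ci_high"], table["posterior_prob"],
                                   atol=1e-12)

    def test_bounds_bracket_point_and_respect_level(self, toy_tree):
        rng = np.random.default_rng(0)
        draws = rng.uniform(0.05, 0.95, size=(2, 100, 7))
        trace = MCMCTrace(draws, PARAM_NAMES, {})
        ann = AnnotationSet({("A", "f"): 1, ("C", "f"): 0})
        table = credible_intervals(toy_tree, ann, trace, n_draws=100, seed=1)
        assert (table["ci_low"] <= table["ci_high"]).all()
        assert ((table["ci_low"] >= 0) & (table["ci_high"] <= 1)).all()

    def test_unannotated_clades_have_wider_intervals(self):
        # annotations concentrated in one half of the tree; the bare half
        # should carry more parameter-driven uncertainty
        tree = read_tree("(((A,B)n1,(C,D)n2)n3,((E,F)n4,(G,H)n5)n6)r;")
        ann = AnnotationSet({(l, "f"): 1 for l in "ABCD"})
        rng = np.random.default_rng(2)
        # a concentrated, posterior-like trace: plausible center + jitter
        center = np.array([0.3, 0.9, 0.5, 0.1, 0.05, 0.05, 0.05])
        draws = np.clip(center + rng.normal(0, 0.05, size=(2, 200, 7)),
                        0.01, 0.99)
        trace = MCMCTrace(draws, PARAM_NAMES, {})
        table = credible_intervals(tree, ann, trace, n_draws=150, seed=3)
        width = dict(zip(table["node"], table["ci_high"] - table["ci_low"]))
        annotated = np.median([width[l] for l in "ABCD"])
        bare = np.median([width[l] for l in "EFGH"])
        assert bare > annotated

    def test_input_validation(self, toy_tree):
        ann = AnnotationSet({("A", "f"): 1})
        with pytest.raises(ValueError):
            credible_intervals(toy_tree, ann, constant_trace(), n_draws=1)
        with pytest.raises(ValueError):
            credible_intervals(toy_tree, ann, constant_trace(), level=1.5)


class TestHighConfidence:
    def test_filter_keeps_only_decisive_intervals(self):
        import pandas as pd
        table = pd.DataFrame({
            "tree": "t0", "node": list("abcd"), "function": "f",
            "posterior_prob": [0.05, 0.95, 0.5, 0.92],
            "ci_low": [0.01, 0.91, 0.3, 0.85],
            "ci_high": [0.08, 0.98, 0.7, 0.95],
            "loo": False,
        })
        kept = high_confidence(table)
        assert set(kept["node"]) == {"a", "b"}

    def test_requires_intervals(self):
        import pandas as pd
        table = pd.DataFrame({"ci_low": [np.nan], "ci_high": [0.5]})
        with pytest.raises(ValueError):
            high_confidence(table)
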