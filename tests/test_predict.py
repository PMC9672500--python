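"""Thresholds, bottom-up smoothing, top-down search and Bayesian MAP."""

import itertools
import math

import numpy as np
import pytest

from hiercode.classify import EnsembleModel, NodeClassifier
from hiercode.corpus import NodeTrainingSet
from hiercode.hierarchy import ancestors_of, true_path_closure
from hiercode.predict import (BayesianAggregator, ThresholdTable,
                              bayes_map_aggregate, bottom_up_smooth,
                              fit_bayes_aggregator, hierarchical_search,
                              init_thresholds)

from conftest import build_tree, random_tree


class TestInitThresholds:
    def test_proportion_formula(self):
        sets = {"A": NodeTrainingSet("A", [f"p{i}" for i in range(30)],
                                     [f"n{i}" for i in range(70)])}
        tt = init_thresholds(sets)
        assert tt.get("A") == pytest.approx(0.3)
        assert tt.provenance["A"] == "proportion-init"

    def test_default_for_missing_stats(self):
        tt = init_thresholds({})
        assert tt.get("whatever") == 0.5

    def test_matches_formula_for_random_counts(self, rng):
        sets = {}
        for i in range(50):
            np_, nn = int(rng.integers(1, 40)), int(rng.integers(0, 200))
            sets[f"c{i}"] = NodeTrainingSet(
                f"c{i}", [f"p{j}" for j in range(np_)],
                [f"n{j}" for j in range(nn)])
        tt = init_thresholds(sets)
        for c, s in sets.items():
            assert tt.get(c) == pytest.approx(s.n_pos / (s.n_pos + s.n_neg))


def smooth_fixpoint_oracle(tt, h, stat="mean"):
    """Iterate the parent-replacement rule until nothing changes."""
    vals = {c: tt.get(c) for c in h}
    agg = np.mean if stat == "mean" else np.min
    while True:
        changed = False
        for c in h:
            kids = h.children(c)
            if not kids:
                continue
            cand = float(agg([vals[k] for k in kids]))
            if cand < vals[c] - 1e-15:
                vals[c] = cand
                changed = True
        if not changed:
            return vals


class TestBottomUpSmooth:
    def test_leaf_only_table_unchanged(self):
        h = build_tree([], ["A", "B"])
        tt = ThresholdTable({"A": 0.4, "B": 0.7})
        out = bottom_up_smooth(tt, h)
        assert out.thresholds == tt.thresholds

    def test_parent_replaced_by_smaller_child_mean(self):
        h = build_tree([("A.1", "A"), ("A.2", "A")], ["A"])
        tt = ThresholdTable({"A": 0.8, "A.1": 0.2, "A.2": 0.4})
        out = bottom_up_smooth(tt, h)
        assert out.get("A") == pytest.approx(0.3)
        assert out.provenance["A"] == "smoothed"

    def test_larger_child_mean_keeps_parent(self):
        h = build_tree([("A.1", "A")], ["A"])
        tt = ThresholdTable({"A": 0.1, "A.1": 0.9})
        assert bottom_up_smooth(tt, h).get("A") == pytest.approx(0.1)

    @pytest.mark.parametrize("stat", ["mean", "min"])
    def test_matches_fixpoint_oracle_and_never_increases(self, rng, stat):
        for _ in range(25):
            h = random_tree(rng, int(rng.integers(3, 30)))
            tt = ThresholdTable({c: float(rng.random()) for c in h})
            out = bottom_up_smooth(tt, h, stat=stat)
            oracle = smooth_fixpoint_oracle(tt, h, stat)
            for c in h:
                assert out.get(c) == pytest.approx(oracle[c])
                assert out.get(c) <= tt.get(c) + 1e-15
            again = bottom_up_smooth(out, h, stat=stat)
            for c in h:
                assert again.get(c) == pytest.approx(out.get(c))


class _FixedScore:
    """Deterministic classifier double returning a fixed score."""

    def __init__(self, value):
        self.value = value

    def score(self, X):
        n = X.shape[0] if hasattr(X, "shape") else len(X)
        return np.full(n, self.value)


def oracle_model(h, scores):
    return EnsembleModel(
        "per-node",
        {c: _FixedScore(s) for c, s in scores.items()},
        h)


class TestHierarchicalSearch:
    def test_blocked_at_root_gives_empty_prediction(self, two_level):
        model = oracle_model(two_level, {c: 0.1 for c in two_level})
        res = hierarchical_search(np.zeros(1), model,
                                  ThresholdTable(default_t=0.5),
                                  mode="threshold")
        assert res.codes == frozenset() and res.deepest is None

    def test_argmax_returns_one_code_per_visited_level(self, rng):
        for _ in range(10):
            h = random_tree(rng, 20)
            model = oracle_model(h, {c: float(rng.random()) for c in h})
            res = hierarchical_search(np.zeros(1), model, ThresholdTable())
            for lv, accepted in res.accepted_per_level.items():
                assert len(accepted) == 1

    def test_threshold_mode_equals_exhaustive_oracle(self, rng):
        """Accepted set = every node passing its threshold whose ancestors
        all pass too (brute force over all nodes)."""
        for _ in range(20):
            h = random_tree(rng, int(rng.integers(4, 25)))
            scores = {c: float(rng.random()) for c in h}
            tt = ThresholdTable({c: float(rng.random()) for c in h})
            model = oracle_model(h, scores)
            res = hierarchical_search(np.zeros(1), model, tt,
                                      mode="threshold")
            expected = {c for c in h
                        if scores[c] > tt.get(c)
                        and all(scores[a] > tt.get(a)
                                for a in ancestors_of(h, c))}
            assert set(res.codes) == expected

    def test_result_always_true_path_closed(self, rng):
        for mode in ("argmax", "threshold"):
            h = random_tree(rng, 15)
            model = oracle_model(h, {c: float(rng.random()) for c in h})
            res = hierarchical_search(np.zeros(1), model, ThresholdTable(),
                                      mode=mode)
            assert res.codes == true_path_closure(h, res.codes)

    def test_empty_model_rejected(self, two_level):
        model = EnsembleModel("per-node", {}, two_level)
        with pytest.raises(ValueError):
            hierarchical_search(np.zeros(1), model, ThresholdTable())


def enumerate_map_oracle(h, nodes, observations, agg):
    """Exhaustive argmax of the joint over all 2^n assignments."""
    nodes = sorted(nodes)
    best, best_p = None, -1.0
    for assign in itertools.product([0, 1], repeat=len(nodes)):
        state = dict(zip(nodes, assign))
        p = 1.0
        for c in nodes:
            parent = h.parent(c)
            pc = agg.p_child.get(c, 0.5)
            if parent is None or parent not in state:
                p *= pc if state[c] else 1 - pc
            elif state[parent] == 0:
                if state[c] == 1:
                    p = 0.0
                    break
            else:
                p *= pc if state[c] else 1 - pc
            if c in observations:
                p1, p0 = agg.p_obs[c]
                q = p1 if state[c] else p0
                p *= q if observations[c] == 1 else 1 - q
        if p > best_p:
            best_p, best = p, state
    return frozenset(c for c, s in best.items() if s == 1)


class TestBayesAggregation:
    def test_perfect_classifier_without_smoothing(self, two_level):
        val = []
        for code in two_level:
            val += [(code, 1, 1)] * 5 + [(code, 0, 0)] * 5
        agg = fit_bayes_aggregator(val, two_level, smoothing=0)
        for code in two_level:
            assert agg.p_obs[code] == (1.0, 0.0)

    def test_confusion_rates_recovered_within_sampling_error(self, rng,
                                                             two_level):
        """0.9/0.1 observation rates recovered within ±0.03 at n=2000."""
        val = []
        for _ in range(2000):
            y = int(rng.random() < 0.5)
            p_fire = 0.9 if y else 0.1
            val.append(("A", y, int(rng.random() < p_fire)))
        agg = fit_bayes_aggregator(val, two_level, smoothing=1)
        p1, p0 = agg.p_obs["A"]
        assert p1 == pytest.approx(0.9, abs=0.03)
        assert p0 == pytest.approx(0.1, abs=0.03)

    def test_smoothing_keeps_probabilities_interior(self, two_level):
        val = [("A", 1, 1)] * 10
        agg = fit_bayes_aggregator(val, two_level, smoothing=1)
        p1, p0 = agg.p_obs["A"]
        assert 0.0 < p1 < 1.0 and 0.0 < p0 < 1.0

    def test_consistent_observations_map_to_their_closure(self, chain3):
        agg = BayesianAggregator(
            {c: (0.99, 0.01) for c in chain3},
            {c: 0.5 for c in chain3}, chain3)
        obs = {"A": 1, "A.B": 1, "A.B.C": 0}
        assert bayes_map_aggregate(obs, agg) == {"A", "A.B"}

    def test_strong_child_reopens_weak_parent_not_reverse(self, chain3):
        """A confidently observed positive child can flip a weakly negative
        parent to positive; with the child's evidence gone the parent
        stays negative."""
        agg = BayesianAggregator(
            {"A": (0.6, 0.4), "A.B": (0.99, 0.01), "A.B.C": (0.99, 0.01)},
            {"A": 0.5, "A.B": 0.8, "A.B.C": 0.8}, chain3)
        with_child = bayes_map_aggregate({"A": 0, "A.B": 1, "A.B.C": 1}, agg)
        assert {"A", "A.B", "A.B.C"} <= with_child
        without = bayes_map_aggregate({"A": 0, "A.B": 0, "A.B.C": 0}, agg)
        assert "A" not in without
        # both agree with brute force
        for obs in ({"A": 0, "A.B": 1, "A.B.C": 1},
                    {"A": 0, "A.B": 0, "A.B.C": 0}):
            assert bayes_map_aggregate(obs, agg) == enumerate_map_oracle(
                chain3, set(chain3.nodes), obs, agg)

    def test_unknown_observation_code_rejected(self, chain3):
        agg = BayesianAggregator({c: (0.9, 0.1) for c in chain3},
                                 {c: 0.5 for c in chain3}, chain3)
        with pytest.raises(KeyError):
            bayes_map_aggregate({"zz": 1}, agg)

    @pytest.mark.parametrize("trial_block", range(5))
    def test_map_equals_enumeration_on_random_trees(self, trial_block):
        """Max-product DP equals exhaustive enumeration over all 2^n
        assignments, random trees with n <= 12 and random conditionals."""
        rng = np.random.default_rng(100 + trial_block)
        for _ in range(40):
            n = int(rng.integers(2, 13))
            h = random_tree(rng, n)
            agg = BayesianAggregator(
                {c: (float(rng.uniform(0.5, 0.999)),
                     float(rng.uniform(0.001, 0.5))) for c in h},
                {c: float(rng.uniform(0.05, 0.95)) for c in h}, h)
            obs = {c: int(rng.random() < 0.5) for c in h
                   if rng.random() < 0.8}   # some nodes unobserved
            got = bayes_map_aggregate(obs, agg)
            expected = enumerate_map_oracle(h, set(h.nodes), obs, agg)
            assert got == expected

    def test_map_result_true_path_closed(self, rng):
        for _ in range(20):
            h = random_tree(rng, 10)
            agg = BayesianAggregator(
                {c: (float(rng.uniform(0.5, 0.99)),
                     float(rng.uniform(0.01, 0.5))) for c in h},
                {c: float(rng.uniform(0.1, 0.9)) for c in h}, h)
            obs = {c: int(rng.random() < 0.5) for c in h}
            res = bayes_map_aggregate(obs, agg)
            assert res == true_path_closure(h, res)
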