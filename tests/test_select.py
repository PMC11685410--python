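"""Wrapper searches, the Mahalanobis separability-index filter, named
feature bundles, and the combine/aggregate machinery."""

import itertools

import numpy as np
import pytest

from emgintent.classify import ClassifierSpec
from emgintent.evaluate import CVConfig
from emgintent.features.registry import REGISTRY, get_spec
from emgintent.select import (NAMED_SETS, OptimalSet, SelectionTrace,
                              SeparabilityInput, aggregate_generalized_set,
                              choose_optimal_set, combine_domains,
                              select_optimal_set, separability_index,
                              separability_index_of_matrix,
                              sequential_backward_search,
                              sequential_forward_search)

from conftest import clouds_matrix

# a frozen, deterministic subset-scoring oracle: additive feature worth
# minus fixed pairwise redundancy penalties
_WORTH = {"tmabs": 5.0, "tstd": 3.0, "tvar": 4.0, "twl": 2.0,
          "trms": 1.0, "tzc": 6.0}
_PENALTY = {("tmabs", "tzc"): 4.0, ("tstd", "tvar"): 2.5, ("twl", "trms"): 1.0}


def _frozen_eval(subset):
    s = set(subset)
    total = sum(_WORTH[f] for f in s)
    for (a, b), p in _PENALTY.items():
        if a in s and b in s:
            total -= p
    return total


CANDS = sorted(_WORTH, key=lambda f: get_spec(f).index)


class TestNamedSets:
    def test_three_bundles_of_five_registry_features(self):
        assert set(NAMED_SETS) == {"CFS", "EFS", "HDS"}
        for name, feats in NAMED_SETS.items():
            assert len(feats) == 5 and len(set(feats)) == 5
            assert all(f in REGISTRY for f in feats)

    def test_expected_members(self):
        assert NAMED_SETS["CFS"] == ("tcr", "tmcer", "tlogd", "tHmob", "tiabs")
        assert NAMED_SETS["HDS"] == ("tmabs", "twl", "tslpch", "tzc", "tdam")


class TestForwardSearch:
    def test_every_step_is_the_greedy_argmax(self):
        tr = sequential_forward_search(None, CANDS, eval_fn=_frozen_eval)
        assert sorted(tr.order) == sorted(CANDS)
        chosen = []
        for step, picked in enumerate(tr.order):
            rest = [f for f in CANDS if f not in chosen]
            best = max(_frozen_eval(tuple(chosen + [f])) for f in rest)
            assert tr.accuracy_curve[step] == best
            assert _frozen_eval(tuple(chosen + [picked])) == best
            # tie-break: no unpicked feature with the same score has a
            # lower catalog index
            tied = [f for f in rest
                    if _frozen_eval(tuple(chosen + [f])) == best]
            assert picked == min(tied, key=lambda f: get_spec(f).index)
            chosen.append(picked)
        assert tr.top5 == tuple(tr.order[:5])

    def test_constant_scores_fall_back_to_catalog_order(self):
        tr = sequential_forward_search(None, ["tzc", "tmabs", "twl"],
                                       eval_fn=lambda s: 1.0)
        assert tr.order == ["tmabs", "twl", "tzc"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            sequential_forward_search(None, [], eval_fn=_frozen_eval)


class TestBackwardSearch:
    def test_every_removal_is_the_greedy_argmax(self):
        tr = sequential_backward_search(None, CANDS, eval_fn=_frozen_eval)
        assert sorted(tr.order) == sorted(CANDS)
        active = sorted(CANDS, key=lambda f: get_spec(f).index)
        assert tr.accuracy_curve[0] == _frozen_eval(tuple(active))
        for step, removed in enumerate(tr.order[:-1]):
            best = max(_frozen_eval(tuple(f for f in active if f != g))
                       for g in active)
            assert tr.accuracy_curve[step + 1] == best
            assert _frozen_eval(
                tuple(f for f in active if f != removed)) == best
            active.remove(removed)
        assert tr.top5 == tuple(tr.order[-5:])

    def test_survivors_are_the_strongest_subset_here(self):
        tr = sequential_backward_search(None, CANDS, eval_fn=_frozen_eval)
        # brute force: the best 5-subset under the frozen oracle
        best5 = max(itertools.combinations(CANDS, 5), key=_frozen_eval)
        assert set(tr.top5) == set(best5)


class TestSeparabilityIndex:
    def test_two_class_hand_value(self):
        si_in = SeparabilityInput(
            class_centroids=np.array([[0.0], [4.0]]),
            class_covariances=np.array([[[1.0]], [[1.0]]]))
        # each class: 0.5 * sqrt(16 / 1) = 2; average = 2
        assert separability_index(si_in) == pytest.approx(2.0)

    def test_matches_explicit_inverse_when_well_conditioned(self):
        fm = clouds_matrix(n_classes=3, n_per_class=80, seed=5)
        y, X = fm.labels, fm.values
        total = 0.0
        for c in range(3):
            mu_j = X[y == c].mean(axis=0)
            S_inv = np.linalg.inv(np.cov(X[y == c].T, ddof=1))
            ds = []
            for o in range(3):
                if o == c:
                    continue
                d = mu_j - X[y == o].mean(axis=0)
                ds.append(0.5 * np.sqrt(abs(d @ S_inv @ d)))
            total += min(ds)
        assert separability_index_of_matrix(fm) == pytest.approx(
            total / 3, rel=1e-8)

    def test_singular_covariance_stays_finite(self):
        fm = clouds_matrix(n_classes=2, n_per_class=30, n_features=2, seed=6)
        dup = np.hstack([fm.values, fm.values[:, :1]])  # duplicated column
        fm2 = type(fm)(values=dup,
                       columns=fm.columns + [("fdup", "ch1", 0)],
                       labels=fm.labels)
        si = separability_index_of_matrix(fm2)
        assert np.isfinite(si) and si > 0

    def test_si_grows_with_class_spacing(self):
        lo = separability_index_of_matrix(clouds_matrix(spacing=2.0, seed=7))
        hi = separability_index_of_matrix(clouds_matrix(spacing=10.0, seed=7))
        assert hi > lo

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            separability_index(SeparabilityInput(
                class_centroids=np.array([[0.0]]),
                class_covariances=np.array([[[1.0]]])))


class TestFilterAndCombine:
    def _matrix(self):
        return clouds_matrix(
            n_classes=3, n_per_class=40, n_features=4, seed=8,
            feature_ids=["tmabs", "tstd", "tvar", "twl"])

    def test_filter_keeps_higher_si_set_tie_to_forward(self):
        fm = self._matrix()
        fwd = SelectionTrace("forward", ["tmabs", "tstd"], [1.0, 2.0],
                             top5=("tmabs", "tstd"))
        bwd = SelectionTrace("backward", ["tvar", "twl"], [1.0, 2.0],
                             top5=("tvar", "twl"))
        opt = choose_optimal_set(fwd, bwd, fm)
        si_f = separability_index_of_matrix(fm, ("tmabs", "tstd"))
        si_b = separability_index_of_matrix(fm, ("tvar", "twl"))
        assert opt.winner == ("forward" if si_f >= si_b else "backward")
        assert opt.si == max(si_f, si_b)
        same = choose_optimal_set(fwd, fwd, fm)
        assert same.winner == "forward"        # exact tie

    def test_select_optimal_set_end_to_end(self):
        fm = self._matrix()
        opt = select_optimal_set(fm, ["tmabs", "tstd", "tvar", "twl"],
                                 ClassifierSpec("LDA"),
                                 CVConfig(n_rand=2, seed=0))
        assert isinstance(opt, OptimalSet)
        assert set(opt.features) <= {"tmabs", "tstd", "tvar", "twl"}
        assert opt.si > 0

    def test_combine_domains_unions_the_pools(self):
        fm = clouds_matrix(
            n_classes=3, n_per_class=40, n_features=6, seed=9,
            feature_ids=["tmabs", "tstd", "fmn", "fmd", "tfstd", "tfwl"])
        mk = lambda feats: OptimalSet(features=feats, si_forward=1.0,
                                      si_backward=0.0, winner="forward")
        opt = combine_domains(mk(("tmabs", "tstd")), mk(("fmn", "fmd")),
                              mk(("tfstd", "tfwl")), fm,
                              ClassifierSpec("LDA"), CVConfig(n_rand=2))
        assert set(opt.features) <= {"tmabs", "tstd", "fmn", "fmd",
                                     "tfstd", "tfwl"}
        assert len(opt.features) == 5


class TestGeneralizedSet:
    def test_counts_and_tie_break(self):
        cells = [("tmabs", "twl", "tzc"),
                 ("tmabs", "twl", "tvar"),
                 ("tmabs", "tstd", "tzc")]
        counts, top = aggregate_generalized_set(cells, k=3)
        assert counts == {"tmabs": 3, "twl": 2, "tzc": 2, "tvar": 1,
                          "tstd": 1}
        assert top == ("tmabs", "twl", "tzc")
        _, top2 = aggregate_generalized_set(cells, k=5)
        # last slot tie between tstd(2) and tvar(3) goes to tstd
        assert top2 == ("tmabs", "twl", "tzc", "tstd", "tvar")
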