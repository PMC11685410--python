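"""Wrapper + filter feature selection.

Two wrapper searches order candidate features by cross-validated overall
accuracy: sequential forward search greedily adds the feature that maximizes
accuracy; sequential backward search greedily removes the feature whose
removal maximizes accuracy.  Each yields a five-feature set (first five
added / last five surviving).  A filter — the modified Mahalanobis
separability index (SI) — then picks between the two: the set with the
larger SI wins.

The SI for C classes is

    SI = (1/C) * sum_j min_{i != j} 0.5 * sqrt(|(mu_j - mu_i)' S_j^+ (mu_j - mu_i)|)

with mu_j, S_j the class centroid and covariance and S_j^+ the Moore-Penrose
pseudoinverse (features may be linear combinations of one another or sparse,
making S_j singular); the absolute value of the quadratic form is taken
before the square root since off-range components under the pseudoinverse
can make it slightly negative.

Three named five-feature bundles ship as built-ins: the congenital set CFS
(derived for children with congenital below-elbow deficiency), the efficient
set EFS, and the Hudgins-style set HDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classify import ClassifierSpec
from .evaluate import CVConfig, cross_validate
from .features.matrix import FeatureMatrix
from .features.registry import get_spec

__all__ = [
    "NAMED_SETS",
    "SelectionTrace",
    "SeparabilityInput",
    "OptimalSet",
    "sequential_forward_search",
    "sequential_backward_search",
    "separability_index",
    "separability_index_of_matrix",
    "choose_optimal_set",
    "combine_domains",
    "aggregate_generalized_set",
]

#: Built-in named feature sets (five time-domain-centric features each).
NAMED_SETS: dict[str, tuple[str, ...]] = {
    "CFS": ("tcr", "tmcer", "tlogd", "tHmob", "tiabs"),
    "EFS": ("twl", "tcr", "tvar", "tHmob", "tHcom"),
    "HDS": ("tmabs", "twl", "tslpch", "tzc", "tdam"),
}


@dataclass
class SelectionTrace:
    method: str                      # forward | backward
    order: list[str]                 # selection (fwd) or removal (bwd) order
    accuracy_curve: list[float]      # overall accuracy % at each step
    top5: tuple[str, ...]

    def to_json(self) -> dict:
        return {"method": self.method, "order": list(self.order),
                "accuracy_curve": [round(a, 4) for a in self.accuracy_curve],
                "top5": list(self.top5)}


def _default_eval(fm: FeatureMatrix, spec: ClassifierSpec, cv: CVConfig
                  ) -> Callable[[tuple[str, ...]], float]:
    def ev(subset: tuple[str, ...]) -> float:
        return cross_validate(fm.select_features(list(subset)), spec, cv).overall
    return ev


def _key(fid: str) -> int:
    return get_spec(fid).index


def sequential_forward_search(
    fm: FeatureMatrix | None,
    candidates: Sequence[str],
    spec: ClassifierSpec | None = None,
    cv: CVConfig | None = None,
    eval_fn: Callable[[tuple[str, ...]], float] | None = None,
) -> SelectionTrace:
    """Greedy add-one ordering of all candidates by overall accuracy.

    ``eval_fn(subset) -> accuracy`` may be injected (e.g. a frozen accuracy
    cache); by default subsets are scored by cross-validation of ``spec`` on
    ``fm``.  Ties break to the lowest catalog index.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    if eval_fn is None:
        eval_fn = _default_eval(fm, spec, cv)
    chosen: list[str] = []
    curve: list[float] = []
    remaining = sorted(candidates, key=_key)
    while remaining:
        scores = [(eval_fn(tuple(chosen + [f])), f) for f in remaining]
        best_acc = max(s for s, _ in scores)
        best = min((f for s, f in scores if s == best_acc), key=_key)
        chosen.append(best)
        curve.append(best_acc)
        remaining.remove(best)
    return SelectionTrace(method="forward", order=chosen,
                          accuracy_curve=curve,
                          top5=tuple(chosen[:min(5, len(chosen))]))


def sequential_backward_search(
    fm: FeatureMatrix | None,
    candidates: Sequence[str],
    spec: ClassifierSpec | None = None,
    cv: CVConfig | None = None,
    eval_fn: Callable[[tuple[str, ...]], float] | None = None,
) -> SelectionTrace:
    """Greedy remove-one ordering; ``order`` lists features in removal order
    (the last entries survive longest), ``top5`` is the last five
    surviving."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    if eval_fn is None:
        eval_fn = _default_eval(fm, spec, cv)
    active = sorted(candidates, key=_key)
    removed: list[str] = []
    curve: list[float] = [eval_fn(tuple(active))]
    while len(active) > 1:
        scores = [(eval_fn(tuple(f2 for f2 in active if f2 != f)), f)
                  for f in active]
        best_acc = max(s for s, _ in scores)
        worst = min((f for s, f in scores if s == best_acc), key=_key)
        active.remove(worst)
        removed.append(worst)
        curve.append(best_acc)
    removed.extend(active)  # the lone survivor is removed last, notionally
    survivors = removed[-min(5, len(candidates)):]
    return SelectionTrace(method="backward", order=removed,
                          accuracy_curve=curve, top5=tuple(survivors))


# ------------------------------------------------------------------- filter

@dataclass
class SeparabilityInput:
    class_centroids: np.ndarray      # [n_classes, n_features]
    class_covariances: np.ndarray    # [n_classes, n_features, n_features]

    @classmethod
    def from_matrix(cls, fm: FeatureMatrix) -> "SeparabilityInput":
        y = np.asarray(fm.labels)
        classes = np.unique(y)
        mus, covs = [], []
        for c in classes:
            X = fm.values[y == c]
            mus.append(X.mean(axis=0))
            covs.append(np.atleast_2d(np.cov(X.T, ddof=1)))
        return cls(class_centroids=np.asarray(mus),
                   class_covariances=np.asarray(covs))


def separability_index(si_in: SeparabilityInput) -> float:
    """Average minimum one-half Mahalanobis distance between class
    centroids, with pseudoinverse covariances and the magnitude of the
    quadratic form."""
    mu = np.asarray(si_in.class_centroids, dtype=float)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite class centroids")
    C = mu.shape[0]
    if C < 2:
        raise ValueError("need at least 2 classes")
    covs = np.asarray(si_in.class_covariances, dtype=float)
    total = 0.0
    for j in range(C):
        Sj_pinv = np.linalg.pinv(covs[j])
        dists = []
        for i in range(C):
            if i == j:
                continue
            d = mu[j] - mu[i]
            q = float(d @ Sj_pinv @ d)
            dists.append(0.5 * np.sqrt(abs(q)))
        total += min(dists)
    return total / C


def separability_index_of_matrix(fm: FeatureMatrix,
                                 feature_ids: Sequence[str] | None = None
                                 ) -> float:
    """SI of (a feature subset of) a raw feature matrix."""
    if feature_ids is not None:
        fm = fm.select_features(list(feature_ids))
    return separability_index(SeparabilityInput.from_matrix(fm))


@dataclass
class OptimalSet:
    features: tuple[str, ...]
    si_forward: float
    si_backward: float
    winner: str                      # forward | backward

    @property
    def si(self) -> float:
        return self.si_forward if self.winner == "forward" else self.si_backward

    def to_json(self) -> dict:
        return {"features": list(self.features),
                "si_forward": self.si_forward,
                "si_backward": self.si_backward, "winner": self.winner}


def choose_optimal_set(fwd: SelectionTrace, bwd: SelectionTrace,
                       matrix: FeatureMatrix) -> OptimalSet:
    """Filter step: of the two wrapper top-5 sets, keep the one with the
    larger separability index (exact tie -> forward)."""
    si_f = separability_index_of_matrix(matrix, fwd.top5)
    si_b = separability_index_of_matrix(matrix, bwd.top5)
    winner = "forward" if si_f >= si_b else "backward"
    feats = fwd.top5 if winner == "forward" else bwd.top5
    return OptimalSet(features=tuple(feats), si_forward=si_f,
                      si_backward=si_b, winner=winner)


def select_optimal_set(fm: FeatureMatrix, candidates: Sequence[str],
                       spec: ClassifierSpec, cv: CVConfig) -> OptimalSet:
    """Both wrapper searches plus the SI filter over one candidate pool."""
    fwd = sequential_forward_search(fm, candidates, spec, cv)
    bwd = sequential_backward_search(fm, candidates, spec, cv)
    return choose_optimal_set(fwd, bwd, fm)


def combine_domains(time_opt: OptimalSet, freq_opt: OptimalSet,
                    tf_opt: OptimalSet, fm: FeatureMatrix,
                    spec: ClassifierSpec, cv: CVConfig) -> OptimalSet:
    """Re-run the wrapper + filter machinery on the union of the three
    single-domain optimal sets (the combined-domain, CDS-style set)."""
    pool = sorted(set(time_opt.features) | set(freq_opt.features)
                  | set(tf_opt.features), key=_key)
    return select_optimal_set(fm, pool, spec, cv)


def aggregate_generalized_set(cell_sets: Sequence[Sequence[str]], k: int = 5
                              ) -> tuple[dict[str, int], tuple[str, ...]]:
    """Occurrence counts of features across per-cell combined-domain sets
    and the k most frequent (ties -> lowest catalog index): the generalized
    feature set."""
    counts: dict[str, int] = {}
    for s in cell_sets:
        for fid in s:
            counts[fid] = counts.get(fid, 0) + 1
    top = tuple(sorted(counts, key=lambda f: (-counts[f], _key(f)))[:k])
    return counts, top
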