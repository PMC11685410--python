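"""Accuracy engine: repeated random-split cross-validation with per-movement
accuracy averaging, individual-feature screening and top-5 occurrence
counting.

The protocol: for every randomization, 60% of each class's windows (rounded
up) train and the rest test; normalization is refitted on that
randomization's training rows; per-movement accuracy is the fraction of
that class's test windows labeled correctly; the overall accuracy is the
*unweighted mean of the per-movement accuracies*, averaged over
randomizations (100 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierSpec, train, predict
from .features.matrix import FeatureMatrix
from .features.registry import FeatureSpec, get_spec, specs_for_domain
from .segment import WindowSet

__all__ = ["CVConfig", "AccuracyResult", "Top5Count", "cross_validate",
           "screen_individual_features", "count_top5"]


@dataclass(frozen=True)
class CVConfig:
    """Repeated random-split protocol.

    ``group_by_repetition`` switches the split unit from individual windows
    to whole repetitions, which removes the train/test leakage caused by
    50%-overlapping windows (adjacent windows share half their samples).
    The default (window-level splits) reproduces the conventional offline
    protocol, leakage included.
    """

    train_frac: float = 0.6
    n_rand: int = 100
    seed: int = 0
    stratified: bool = True
    group_by_repetition: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")


@dataclass
class AccuracyResult:
    """Mean per-movement and overall accuracies (percent) over
    randomizations, their spread, and mean train/test wall times (ms)."""

    classes: np.ndarray
    per_movement: np.ndarray      # [n_classes] mean accuracy %, class order
    overall: float                # unweighted mean of per_movement
    spread: float                 # std of overall across randomizations
    per_movement_spread: np.ndarray = field(default=None)
    train_time_ms: float = 0.0
    test_time_ms: float = 0.0
    n_rand: int = 0

    def to_json(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "per_movement": np.round(self.per_movement, 6).tolist(),
            "overall": round(float(self.overall), 6),
            "spread": round(float(self.spread), 6),
            "train_time_ms": round(self.train_time_ms, 3),
            "test_time_ms": round(self.test_time_ms, 3),
            "n_rand": self.n_rand,
        }


def _split_indices(y: np.ndarray, classes: np.ndarray, train_frac: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; ceil(train_frac * n_c) rows train."""
    tr, te = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 rows; cannot split")
        perm = rng.permutation(idx)
        n_tr = math.ceil(train_frac * idx.size)
        if n_tr == idx.size:
            n_tr = idx.size - 1  # keep at least one test row
        tr.append(perm[:n_tr])
        te.append(perm[n_tr:])
    return np.concatenate(tr), np.concatenate(te)


def _split_indices_grouped(y: np.ndarray, groups: np.ndarray,
                           classes: np.ndarray, train_frac: float,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split over whole repetitions instead of windows."""
    tr, te = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        reps = np.unique(groups[idx])
        if reps.size < 2:
            raise ValueError(
                f"class {c} has fewer than 2 repetitions; cannot group-split")
        perm = rng.permutation(reps)
        n_tr = math.ceil(train_frac * reps.size)
        if n_tr == reps.size:
            n_tr = reps.size - 1
        tr_reps = set(perm[:n_tr].tolist())
        in_tr = np.array([groups[i] in tr_reps for i in idx])
        tr.append(idx[in_tr])
        te.append(idx[~in_tr])
    return np.concatenate(tr), np.concatenate(te)


def cross_validate(matrix: FeatureMatrix, spec: ClassifierSpec, cv: CVConfig
                   ) -> AccuracyResult:
    """Repeated stratified random-split evaluation of one configuration."""
    y = np.asarray(matrix.labels)
    classes = np.unique(y)
    rng = np.random.default_rng(cv.seed)
    per_mov = np.zeros((cv.n_rand, classes.size))
    overalls = np.zeros(cv.n_rand)
    t_train = np.zeros(cv.n_rand)
    t_test = np.zeros(cv.n_rand)

    if cv.group_by_repetition and matrix.groups is None:
        raise ValueError("matrix lacks repetition groups for a grouped split")
    for r in range(cv.n_rand):
        if cv.group_by_repetition:
            tr_idx, te_idx = _split_indices_grouped(
                y, matrix.groups, classes, cv.train_frac, rng)
        else:
            tr_idx, te_idx = _split_indices(y, classes, cv.train_frac, rng)
        tr = FeatureMatrix(values=matrix.values[tr_idx],
                           columns=matrix.columns, labels=y[tr_idx])
        te = FeatureMatrix(values=matrix.values[te_idx],
                           columns=matrix.columns, labels=y[te_idx])
        model = train(tr, spec, seed=cv.seed)
        pred, dt = predict(model, te)
        t_train[r] = model.train_time_s
        t_test[r] = dt
        for j, c in enumerate(classes):
            m = te.labels == c
            per_mov[r, j] = 100.0 * np.mean(pred[m] == c)
        overalls[r] = per_mov[r].mean()

    return AccuracyResult(
        classes=classes,
        per_movement=per_mov.mean(axis=0),
        overall=float(overalls.mean()),
        spread=float(overalls.std(ddof=1)) if cv.n_rand > 1 else 0.0,
        per_movement_spread=per_mov.std(axis=0, ddof=1) if cv.n_rand > 1
        else np.zeros(classes.size),
        train_time_ms=1000.0 * t_train.mean(),
        test_time_ms=1000.0 * t_test.mean(),
        n_rand=cv.n_rand,
    )


def screen_individual_features(
    fm_or_results, domain: str, specs_by_kind: list[ClassifierSpec],
    cv: CVConfig, fs: float | None = None, features=None,
) -> dict[str, dict[str, AccuracyResult]]:
    """Evaluate every individual feature of one domain under each classifier.

    Accepts either a FeatureMatrix containing the domain's columns (sliced
    out per feature) or a WindowSet (features are extracted first).
    ``features`` optionally restricts the screen to a subset of the domain's
    ids.  Returns ``{classifier kind: {feature id: AccuracyResult}}``.
    """
    specs = specs_for_domain(domain)
    if features is not None:
        wanted = set(features)
        specs = [s for s in specs if s.id in wanted]
        if not specs:
            raise ValueError(f"no requested features belong to domain {domain!r}")
    if isinstance(fm_or_results, WindowSet):
        from .features.matrix import extract_matrix
        fm = extract_matrix(fm_or_results, specs, fs)
    else:
        fm = fm_or_results
    out: dict[str, dict[str, AccuracyResult]] = {}
    for cspec in specs_by_kind:
        per_feat: dict[str, AccuracyResult] = {}
        for fspec in specs:
            sub = fm.select_features([fspec.id])
            if sub.values.shape[1] == 0:
                raise ValueError(f"matrix lacks columns for {fspec.id!r}")
            per_feat[fspec.id] = cross_validate(sub, cspec, cv)
        out[cspec.kind] = per_feat
    return out


@dataclass
class Top5Count:
    counts: dict[str, int]
    max_possible: int

    def top(self, n: int = 5) -> list[str]:
        """The n most frequent feature ids; ties broken by catalog index."""
        return sorted(self.counts,
                      key=lambda f: (-self.counts[f], get_spec(f).index))[:n]


def _rank_cell(results: dict[str, AccuracyResult]) -> list[str]:
    """Feature ids by descending overall accuracy; ties by catalog index."""
    return sorted(results,
                  key=lambda f: (-results[f].overall, get_spec(f).index))


def count_top5(cells: list[dict[str, AccuracyResult]], k: int = 5) -> Top5Count:
    """Count how often each feature lands in a cell's top-k.

    ``cells`` holds one ranked-results dict per (participant, classifier)
    cell; the max possible count for any feature is the number of cells.
    """
    counts: dict[str, int] = {}
    for cell in cells:
        if len(cell) < k:
            raise ValueError(f"cell has fewer than {k} ranked features")
        for fid in _rank_cell(cell)[:k]:
            counts[fid] = counts.get(fid, 0) + 1
    return Top5Count(counts=counts, max_possible=len(cells))
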