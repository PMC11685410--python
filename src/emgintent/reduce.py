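"""Rest-preserving movement-set reduction.

Starting from all classes, a classifier is cross-validated, the non-rest
movement with the lowest per-movement accuracy is discarded, and the
classifier is retrained on the remainder — repeated until only rest and one
movement are left.  The accuracy trajectory is reported against the 85%
usability threshold, with the five-class state (rest + 4 movements) the
point of practical interest for multi-grasp prosthesis control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierSpec
from .evaluate import AccuracyResult, CVConfig, cross_validate
from .features.matrix import FeatureMatrix, extract_matrix
from .features.registry import get_spec
from .segment import WindowSet
from .synth import REST

__all__ = ["ReductionStep", "ReductionTrace", "reduce_movements",
           "count_reduced_movements"]


@dataclass
class ReductionStep:
    active: tuple[int, ...]          # class ids in this state (incl. rest)
    result: AccuracyResult
    removed: int | None              # movement removed after this step

    def to_json(self) -> dict:
        return {"active": list(self.active), "removed": self.removed,
                "overall": self.result.overall,
                "per_movement": self.result.to_json()["per_movement"],
                "classes": self.result.classes.tolist()}


@dataclass
class ReductionTrace:
    steps: list[ReductionStep]
    threshold: float = 85.0

    @property
    def at_k(self) -> dict[int, ReductionStep]:
        return {len(s.active): s for s in self.steps}

    @property
    def at_five(self) -> float | None:
        """Overall accuracy when 5 classes (rest + 4 movements) remain."""
        step = self.at_k.get(5)
        return step.result.overall if step else None

    def active_at(self, k: int) -> tuple[int, ...]:
        return self.at_k[k].active

    def to_json(self) -> dict:
        return {"threshold": self.threshold, "at_five": self.at_five,
                "steps": [s.to_json() for s in self.steps]}


def reduce_movements(ws: WindowSet, feature_set, spec: ClassifierSpec,
                     cv: CVConfig, threshold: float = 85.0,
                     fs: float | None = None) -> ReductionTrace:
    """Iterative worst-movement removal on one feature set.

    ``feature_set`` is a sequence of feature ids (a named set resolves via
    :data:`emgintent.select.NAMED_SETS` before calling).  At each state the
    full cross-validation protocol reruns on the active classes; ties on
    the lowest accuracy remove the higher class id.
    """
    classes = sorted(int(c) for c in np.unique(ws.labels))
    if REST not in classes:
        raise ValueError("rest class (0) must be present")
    if len(classes) < 3:
        raise ValueError("need at least rest plus two movements to reduce")

    specs = [get_spec(f) for f in feature_set]
    full = extract_matrix(ws, specs, fs)
    y = np.asarray(full.labels)

    active = list(classes)
    steps: list[ReductionStep] = []
    while len(active) >= 2:
        mask = np.isin(y, active)
        sub = FeatureMatrix(values=full.values[mask], columns=full.columns,
                            labels=y[mask])
        res = cross_validate(sub, spec, cv)
        removed = None
        if len(active) > 2:
            movers = [(acc, -c) for c, acc in zip(res.classes, res.per_movement)
                      if c != REST]
            worst_acc = min(movers)[0]
            # tie -> higher class id removed
            removed = max(int(c) for c, acc in
                          zip(res.classes, res.per_movement)
                          if c != REST and acc == worst_acc)
        steps.append(ReductionStep(active=tuple(active), result=res,
                                   removed=removed))
        if removed is None:
            break
        active.remove(removed)
    return ReductionTrace(steps=steps, threshold=threshold)


def count_reduced_movements(traces, at_k: int = 5) -> dict[int, int]:
    """Across (participant x classifier) traces, count each movement's
    membership in the ``at_k``-class state; rest's count equals the number
    of cells."""
    counts: dict[int, int] = {}
    for tr in traces:
        state = tr.at_k.get(at_k)
        if state is None:
            raise ValueError(f"a trace never reaches {at_k} classes")
        for c in state.active:
            counts[int(c)] = counts.get(int(c), 0) + 1
    return counts
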