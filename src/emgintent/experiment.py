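"""End-to-end experiment orchestration from a single JSON config.

A cohort of synthetic "participants" (each a protocol + separability model +
seed) is generated, segmented and evaluated through any subset of four
stages:

* ``screen``  — individual-feature accuracies per domain and classifier,
  with top-5 occurrence counts across cohort cells;
* ``select``  — wrapper + filter selection per domain and classifier
  (TMS/FQS/TFS-style sets), combined-domain re-run (CDS-style), and the
  cross-cohort generalized-set aggregation;
* ``compare`` — per-cell Friedman + Nemenyi comparison of the evaluated
  feature sets (named built-ins plus, when available, the selected sets),
  and the across-classifier comparison on the CFS;
* ``reduce``  — rest-preserving movement reduction on the CFS.

The default candidate pools are a scaled profile (a handful of features per
domain, n_rand = 10) sized for minutes on one CPU; the full catalog and the
100-randomization protocol are configuration away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import ClassifierSpec, default_specs
from .evaluate import CVConfig, cross_validate, screen_individual_features, count_top5
from .features.matrix import extract_matrix
from .features.registry import get_spec, specs_for_domain
from .rankstats import friedman_improved, nemenyi_cd, nemenyi_pairwise, rank_blocks
from .reduce import count_reduced_movements, reduce_movements
from .segment import SegmentationConfig, build_windowset
from .select import (NAMED_SETS, aggregate_generalized_set, combine_domains,
                     select_optimal_set)
from .synth import ProtocolSpec, default_separability, generate_recording

__all__ = ["ExperimentConfig", "run_experiment"]

STAGES = ("screen", "select", "compare", "reduce")

#: Scaled default candidate pools (<= 15 features across domains).
DEFAULT_CANDIDATES = {
    "time": ["tmabs", "twl", "tzc", "tslpch", "tiabs", "tlogd"],
    "frequency": ["fmn", "fmd", "fmxp", "fr"],
    "timefreq": ["tfstd", "tfwl", "tfe", "tfmabs"],
}


@dataclass
class CohortMember:
    name: str
    protocol: ProtocolSpec
    sep: float
    seed: int
    rep_jitter: float = 0.1
    noise_rms: float = 0.05


@dataclass
class ExperimentConfig:
    cohort: list[CohortMember]
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cv: CVConfig = field(default_factory=lambda: CVConfig(n_rand=10))
    classifiers: list[ClassifierSpec] = field(default_factory=default_specs)
    feature_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(NAMED_SETS))
    candidates: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CANDIDATES.items()})
    stages: tuple[str, ...] = ("screen", "select", "compare", "reduce")
    alpha: float = 0.05

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        for fid_list in self.candidates.values():
            for fid in fid_list:
                get_spec(fid)
        for name, feats in self.feature_sets.items():
            for fid in feats:
                get_spec(fid)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cohort = []
        for i, m in enumerate(raw.get("cohort", [])):
            proto_kw = dict(m.get("protocol", {}))
            if "band" in proto_kw:
                proto_kw["band"] = tuple(proto_kw["band"])
            cohort.append(CohortMember(
                name=m.get("name", f"P{i + 1}"),
                protocol=ProtocolSpec(**proto_kw),
                sep=float(m.get("sep", 2.0)),
                seed=int(m.get("seed", i + 1)),
                rep_jitter=float(m.get("rep_jitter", 0.1)),
                noise_rms=float(m.get("noise_rms", 0.05)),
            ))
        kw: dict = {"cohort": cohort}
        if "segmentation" in raw:
            kw["segmentation"] = SegmentationConfig(**raw["segmentation"])
        if "cv" in raw:
            kw["cv"] = CVConfig(**raw["cv"])
        if "classifiers" in raw:
            kw["classifiers"] = [ClassifierSpec(**c) if isinstance(c, dict)
                                 else ClassifierSpec(c) for c in raw["classifiers"]]
        if "feature_sets" in raw:
            kw["feature_sets"] = {k: tuple(v) for k, v in raw["feature_sets"].items()}
        if "candidates" in raw:
            kw["candidates"] = {k: list(v) for k, v in raw["candidates"].items()}
        if "stages" in raw:
            kw["stages"] = tuple(raw["stages"])
        if "alpha" in raw:
            kw["alpha"] = float(raw["alpha"])
        return cls(**kw)


def _member_windowset(m: CohortMember, seg: SegmentationConfig):
    model = default_separability(
        m.protocol.n_movements, m.protocol.n_channels, sep=m.sep,
        seed=m.seed, rep_jitter=m.rep_jitter, noise_rms=m.noise_rms)
    rec = generate_recording(m.protocol, model, seed=m.seed)
    return build_windowset(rec, seg)


def run_experiment(cfg: ExperimentConfig, outdir) -> dict:
    """Run the configured stages; write per-stage JSON under ``outdir`` and
    return the results bundle as a dict."""
    if "compare" in cfg.stages and not cfg.feature_sets and "select" not in cfg.stages:
        raise ValueError("compare stage needs evaluated feature sets")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle: dict = {"version": __version__,
                    "config": {"stages": list(cfg.stages),
                               "cv": {"n_rand": cfg.cv.n_rand, "seed": cfg.cv.seed},
                               "cohort": [m.name for m in cfg.cohort]}}
    windowsets = {m.name: _member_windowset(m, cfg.segmentation)
                  for m in cfg.cohort}
    # full-candidate matrices, one per member, reused across stages
    all_cand = sorted({f for v in cfg.candidates.values() for f in v}
                      | {f for v in cfg.feature_sets.values() for f in v},
                      key=lambda f: get_spec(f).index)
    matrices = {name: extract_matrix(ws, [get_spec(f) for f in all_cand])
                for name, ws in windowsets.items()}

    if "screen" in cfg.stages:
        screen: dict = {}
        cells = []
        for m in cfg.cohort:
            screen[m.name] = {}
            for domain, cand in cfg.candidates.items():
                res = screen_individual_features(
                    matrices[m.name], domain, cfg.classifiers, cfg.cv,
                    features=cand)
                screen[m.name][domain] = {
                    kind: {fid: r.to_json() for fid, r in d.items()}
                    for kind, d in res.items()}
                cells.extend(res.values())
        k = min(5, min(len(c) for c in cells))
        top5 = count_top5(cells, k=k)
        bundle["screen"] = {"results": screen,
                            "top5_counts": top5.counts,
                            "max_possible": top5.max_possible,
                            "top5": top5.top()}

    if "select" in cfg.stages:
        select_out: dict = {}
        combined_cells = []
        for m in cfg.cohort:
            fm = matrices[m.name]
            select_out[m.name] = {}
            for cspec in cfg.classifiers:
                per_dom = {}
                for domain in ("time", "frequency", "timefreq"):
                    cand = [f for f in cfg.candidates.get(domain, [])]
                    if not cand:
                        continue
                    per_dom[domain] = select_optimal_set(fm, cand, cspec, cfg.cv)
                entry = {d: o.to_json() for d, o in per_dom.items()}
                if len(per_dom) == 3:
                    cds = combine_domains(per_dom["time"], per_dom["frequency"],
                                          per_dom["timefreq"], fm, cspec, cfg.cv)
                    entry["combined"] = cds.to_json()
                    combined_cells.append(cds.features)
                select_out[m.name][cspec.kind] = entry
        bundle["select"] = {"per_cell": select_out}
        if combined_cells:
            counts, gen = aggregate_generalized_set(combined_cells)
            bundle["select"]["generalized"] = {"counts": counts,
                                               "set": list(gen)}

    if "compare" in cfg.stages:
        sets = dict(cfg.feature_sets)
        compare: dict = {"feature_sets": {}, "classifiers": {}}
        cfs_acc: dict[str, dict[str, object]] = {}
        for m in cfg.cohort:
            fm = matrices[m.name]
            compare["feature_sets"][m.name] = {}
            for cspec in cfg.classifiers:
                accs, names = [], []
                for sname, feats in sets.items():
                    r = cross_validate(fm.select_features(list(feats)),
                                       cspec, cfg.cv)
                    accs.append(r.per_movement)
                    names.append(sname)
                    if sname == "CFS":
                        cfs_acc.setdefault(m.name, {})[cspec.kind] = r
                A = np.column_stack(accs)
                rt = rank_blocks(A)
                fr = friedman_improved(rt, cfg.alpha)
                cd = nemenyi_cd(rt.k, rt.N, cfg.alpha)
                compare["feature_sets"][m.name][cspec.kind] = {
                    "treatments": names,
                    "avg_rank": rt.avg_rank.tolist(),
                    "friedman": fr.to_json(),
                    "nemenyi": nemenyi_pairwise(rt, cd).to_json(),
                }
        # classifier comparison on the CFS
        for m in cfg.cohort:
            if m.name not in cfs_acc or len(cfs_acc[m.name]) < 2:
                continue
            kinds = [c.kind for c in cfg.classifiers if c.kind in cfs_acc[m.name]]
            A = np.column_stack([cfs_acc[m.name][k].per_movement for k in kinds])
            rt = rank_blocks(A)
            fr = friedman_improved(rt, cfg.alpha)
            cd = nemenyi_cd(rt.k, rt.N, cfg.alpha)
            compare["classifiers"][m.name] = {
                "treatments": kinds,
                "avg_rank": rt.avg_rank.tolist(),
                "friedman": fr.to_json(),
                "nemenyi": nemenyi_pairwise(rt, cd).to_json(),
            }
        bundle["compare"] = compare

    if "reduce" in cfg.stages:
        red: dict = {}
        traces = []
        feats = cfg.feature_sets.get("CFS", NAMED_SETS["CFS"])
        for m in cfg.cohort:
            red[m.name] = {}
            for cspec in cfg.classifiers:
                tr = reduce_movements(windowsets[m.name], feats, cspec, cfg.cv)
                red[m.name][cspec.kind] = tr.to_json()
                traces.append(tr)
        at_k = min(5, min(len(t.steps[0].active) for t in traces))
        bundle["reduce"] = {"per_cell": red,
                            "at_k": at_k,
                            "movement_counts": count_reduced_movements(traces, at_k)}

    with open(outdir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonable)
    return bundle


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
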