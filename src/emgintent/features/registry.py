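"""Feature registry: exactly 31 time, 9 frequency and 9 time-frequency
entries, each mapping a short id to its implementation, arity, output
dimensionality and declared amplitude-scale behavior.

``index`` is the catalog position (1-31 within the time domain, continuing
through frequency and time-frequency); it is the deterministic tie-break
used by ranking and search routines throughout the package.

``scale`` declares how the feature responds to ``x -> c*x`` (c > 0):
``linear`` (value scales by c), ``quadratic`` (by c^2), ``invariant``
(unchanged), or ``other`` (threshold- or log-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

from . import time_domain as td
from . import frequency as fq
from . import wavelet as wv

__all__ = ["FeatureSpec", "REGISTRY", "get_spec", "specs_for_domain",
           "registry_json"]


@dataclass(frozen=True)
class FeatureSpec:
    id: str
    domain: str                      # time | frequency | timefreq
    func: Callable
    index: int                       # catalog order, global tie-break key
    arity: str = "per_channel"       # per_channel | cross_channel
    out_dim: int = 1                 # values per application (per channel
                                     # for per_channel features)
    scale: str = "other"
    params: dict = field(default_factory=dict)
    description: str = ""

    def n_columns(self, n_channels: int) -> int:
        """Total matrix columns this feature contributes."""
        if self.arity == "per_channel":
            return n_channels * self.out_dim
        if self.id in ("tcr", "tcv"):
            return n_channels * (n_channels - 1) // 2
        if self.id == "tmcer":
            return n_channels
        raise ValueError(f"unknown cross-channel feature {self.id}")


def _pair_labels(n: int) -> list[str]:
    return [f"ch{i + 1}:ch{j + 1}" for i in range(n) for j in range(i + 1, n)]


def column_tags(spec: FeatureSpec, n_channels: int) -> list[tuple[str, str, int]]:
    """(feature id, channel tag, sub-index) for every column the feature
    contributes, in emission order."""
    if spec.arity == "per_channel":
        return [(spec.id, f"ch{c + 1}", k)
                for c in range(n_channels) for k in range(spec.out_dim)]
    if spec.id in ("tcr", "tcv"):
        return [(spec.id, p, 0) for p in _pair_labels(n_channels)]
    if spec.id == "tmcer":
        return [(spec.id, f"ch{c + 1}", 0) for c in range(n_channels)]
    raise ValueError(spec.id)


_ENTRIES: list[FeatureSpec] = []


def _reg(fid, domain, func, *, arity="per_channel", out_dim=1, scale="other",
         params=None, desc=""):
    _ENTRIES.append(FeatureSpec(
        id=fid, domain=domain, func=func, index=len(_ENTRIES) + 1,
        arity=arity, out_dim=out_dim, scale=scale, params=params or {},
        description=desc,
    ))


# ------------------------------------------------------------- time domain
_reg("tmabs", "time", td.tmabs, scale="linear", desc="Mean absolute value")
_reg("tstd", "time", td.tstd, scale="linear", desc="Standard deviation")
_reg("tvar", "time", td.tvar, scale="quadratic", desc="Variance")
_reg("twl", "time", td.twl, scale="linear", desc="Waveform length")
_reg("trms", "time", td.trms, scale="linear", desc="Root mean square")
_reg("tzc", "time", td.tzc, scale="invariant", desc="Zero crossings")
_reg("tpks", "time", td.tpks, scale="invariant",
     desc="Peaks above the RMS level")
_reg("tmpks", "time", td.tmpks, scale="linear", desc="Mean peak amplitude")
_reg("tmvel", "time", td.tmvel, scale="linear",
     desc="Mean velocity between peaks")
_reg("tslpch", "time", td.tslpch, scale="invariant", desc="Slope sign changes")
_reg("tpwr", "time", td.tpwr, scale="quadratic", desc="Mean power")
_reg("tdam", "time", td.tdam, scale="linear",
     desc="Difference absolute mean value")
_reg("tmfl", "time", td.tmfl, desc="Maximum fractal length")
_reg("tfd", "time", td.tfd, scale="invariant", desc="Katz fractal dimension")
_reg("tfdh", "time", td.tfdh, scale="invariant", params={"k_max": 8},
     desc="Higuchi fractal dimension")
_reg("tren", "time", td.tren, scale="invariant", desc="Rough (energy) entropy")
_reg("tcr", "time", td.tcr, arity="cross_channel", scale="invariant",
     desc="Channel-pair correlation coefficient")
_reg("tcv", "time", td.tcv, arity="cross_channel", scale="quadratic",
     desc="Channel-pair covariance")
_reg("tcard", "time", td.tcard, params={"threshold": 0.01},
     desc="Cardinality (distinct levels)")
_reg("tHmob", "time", td.tHmob, scale="invariant", desc="Hjorth mobility")
_reg("tHcom", "time", td.tHcom, scale="invariant", desc="Hjorth complexity")
_reg("tskw", "time", td.tskw, scale="invariant", desc="Skewness")
_reg("tdasdv", "time", td.tdasdv, scale="linear",
     desc="Difference absolute standard deviation value")
_reg("tkurt", "time", td.tkurt, scale="invariant",
     desc="Kurtosis (non-excess)")
_reg("twam", "time", td.twam, params={"threshold": 0.01},
     desc="Willison amplitude, threshold 0.01")
_reg("tmcer", "time", td.tmcer, arity="cross_channel", scale="invariant",
     desc="Multi-channel energy ratio")
_reg("tperc75", "time", td.tperc75, scale="linear", desc="75th percentile")
_reg("tiabs", "time", td.tiabs, scale="linear", desc="Integrated absolute value")
_reg("thist", "time", td.thist, out_dim=9, scale="invariant",
     params={"bins": 9}, desc="9-bin min-max histogram")
_reg("tssi", "time", td.tssi, scale="quadratic", desc="Simple square integral")
_reg("tlogd", "time", td.tlogd, scale="linear", desc="Log detector")

# -------------------------------------------------------- frequency domain
_reg("fwl", "frequency", fq.fwl, scale="quadratic", desc="Spectral waveform length")
_reg("fmn", "frequency", fq.fmn, scale="invariant", desc="Mean frequency")
_reg("fmd", "frequency", fq.fmd, scale="invariant", desc="Median frequency")
_reg("fpmn", "frequency", fq.fpmn, scale="quadratic",
     desc="Mean spectral-peak power above RMS")
_reg("fpmd", "frequency", fq.fpmd, scale="quadratic",
     desc="Median spectral-peak power above RMS")
_reg("fpstd", "frequency", fq.fpstd, scale="quadratic",
     desc="Std of spectral-peak power above RMS")
_reg("fmxp", "frequency", fq.fmxp, scale="quadratic", desc="Maximum spectral power")
_reg("fr", "frequency", fq.fr, scale="invariant",
     params={"low_band": (20.0, 250.0), "high_band": (250.0, 450.0)},
     desc="Band power ratio 20-250 / 251-450 Hz")
_reg("fe", "frequency", fq.fe, out_dim=fq.FE_BINS, scale="quadratic",
     params={"band": (20.0, 450.0), "bin_hz": 10.0},
     desc="Spectral energy in 10 Hz bins over 20-450 Hz")

# --------------------------------------------------- time-frequency domain
_reg("tfstd", "timefreq", wv.tfstd, scale="linear",
     desc="Std of level-4 DWT approximation")
_reg("tfvar", "timefreq", wv.tfvar, scale="quadratic",
     desc="Variance of level-4 DWT approximation")
_reg("tfwl", "timefreq", wv.tfwl, scale="linear",
     desc="Waveform length of level-4 DWT approximation")
_reg("tfe", "timefreq", wv.tfe, scale="quadratic",
     desc="Energy of level-4 DWT approximation")
_reg("tfmxabs1", "timefreq", wv.tfmxabs1, scale="linear",
     desc="Max |cA4| coefficient")
_reg("tfmxabs2", "timefreq", wv.tfmxabs2, scale="linear",
     desc="Max |coefficient| over cA4 and all detail levels")
_reg("tfzc", "timefreq", wv.tfzc, scale="invariant",
     desc="Zero crossings of cA4")
_reg("tfmn", "timefreq", wv.tfmn, scale="linear", desc="Mean of cA4")
_reg("tfmabs", "timefreq", wv.tfmabs, scale="linear",
     desc="Mean absolute value of cA4")

REGISTRY: dict[str, FeatureSpec] = {s.id: s for s in _ENTRIES}
assert len(REGISTRY) == 49


def get_spec(fid: str) -> FeatureSpec:
    try:
        return REGISTRY[fid]
    except KeyError:
        raise KeyError(f"unknown feature id {fid!r}") from None


def specs_for_domain(domain: str) -> list[FeatureSpec]:
    """All specs of one domain in catalog order."""
    if domain not in ("time", "frequency", "timefreq"):
        raise ValueError(f"unknown domain {domain!r}")
    return [s for s in _ENTRIES if s.domain == domain]


def registry_json() -> str:
    """The registry (sans callables) as JSON."""
    return json.dumps(
        [{"id": s.id, "domain": s.domain, "index": s.index, "arity": s.arity,
          "out_dim": s.out_dim, "scale": s.scale, "params": s.params,
          "description": s.description} for s in _ENTRIES],
        indent=2,
    )
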