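"""Synthetic multichannel sEMG session generator.

Emulates a metronome-paced motor-intent protocol: each of ``n_movements``
attempted hand movements is repeated ``n_reps`` times, every repetition a
3-s static contraction followed by a 4-s rest phase.  Contraction signal is
band-limited (20-450 Hz) Gaussian noise amplitude-modulated by a trapezoidal
envelope whose plateau height is the class- and channel-specific RMS level;
rest is generated at a small baseline RMS so that rest-class windows carry
realistic nonzero feature values.  The degree to which movements are
distinguishable is a single knob (``sep``) scaling between-class differences
of the per-channel excitation patterns.

No motor-unit-level physiology is modelled: every downstream statistic in
this package consumes 300-ms windows, for which amplitude-modulated
band-limited Gaussian noise is the standard surrogate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ProtocolSpec",
    "SeparabilityModel",
    "Recording",
    "default_separability",
    "generate_recording",
    "write_recording_csv",
    "read_recording_csv",
]

REST = 0  # class id of the rest state, everywhere in the package


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition protocol: channel count, timing and bandwidth."""

    n_channels: int = 7
    fs: float = 6000.0
    n_movements: int = 10
    n_reps: int = 10
    contraction_s: float = 3.0
    rest_s: float = 4.0
    band: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        if min(self.n_channels, self.n_movements, self.n_reps) < 1:
            raise ValueError("counts must be >= 1")
        if self.contraction_s <= 0 or self.rest_s <= 0:
            raise ValueError("phase durations must be positive")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"invalid band {self.band}")
        if self.fs <= 2 * hi:
            raise ValueError(
                f"fs={self.fs} must exceed twice the band upper edge {hi}"
            )

    @property
    def contraction_samples(self) -> int:
        return int(round(self.contraction_s * self.fs))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_s * self.fs))


@dataclass(frozen=True)
class SeparabilityModel:
    """Per-class, per-channel RMS excitation levels plus noise/jitter knobs.

    ``amplitude`` has ``n_movements + 1`` rows; row 0 is the rest baseline.
    """

    amplitude: np.ndarray
    sep: float
    noise_rms: float = 0.05
    rep_jitter: float = 0.1

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise ValueError("amplitudes must be finite and nonnegative")
        if self.sep < 0:
            raise ValueError("sep must be >= 0")
        if self.noise_rms <= 0:
            raise ValueError("noise_rms must be > 0")
        object.__setattr__(self, "amplitude", amp)


@dataclass
class Recording:
    """One labeled synthetic session.

    ``labels`` gives the class id per sample (0 = rest); ``rep_ids`` the
    repetition index per sample (repetitions of the active movement; rest
    samples inherit the repetition they follow).
    """

    signal: np.ndarray          # [n_samples, n_channels]
    labels: np.ndarray          # [n_samples] int
    rep_ids: np.ndarray         # [n_samples] int
    protocol: ProtocolSpec
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


def default_separability(
    n_movements: int,
    n_channels: int,
    sep: float,
    seed: int,
    *,
    baseline: float = 1.0,
    rest_level: float = 0.0,
    noise_rms: float = 0.05,
    rep_jitter: float = 0.1,
) -> SeparabilityModel:
    """Random per-movement excitation patterns at a given separability.

    Movement row ``m`` = ``rest_level + sep * baseline * (1/2 + u_m)`` with
    ``u_m`` a random nonnegative unit-norm channel pattern.  The rest row is
    the excitation *above* the noise floor during rest (0 by default), so
    ``sep = 0`` makes every class — rest included — statistically
    identical, the null condition for chance-level calibration; any
    ``sep > 0`` puts every movement strictly above rest.
    """
    if n_movements < 1 or n_channels < 1:
        raise ValueError("counts must be >= 1")
    if sep < 0:
        raise ValueError("sep must be >= 0")
    rng = np.random.default_rng(seed)
    patterns = np.abs(rng.standard_normal((n_movements, n_channels)))
    patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
    amp = np.empty((n_movements + 1, n_channels))
    amp[REST] = rest_level
    amp[1:] = rest_level + sep * baseline * (0.5 + patterns)
    return SeparabilityModel(
        amplitude=amp, sep=sep, noise_rms=noise_rms, rep_jitter=rep_jitter
    )


def _bandlimited_noise(
    n_samples: int, n_channels: int, protocol: ProtocolSpec, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited with a zero-phase Butterworth."""
    lo, hi = protocol.band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=protocol.fs, output="sos")
    white = rng.standard_normal((n_samples, n_channels))
    x = sps.sosfiltfilt(sos, white, axis=0)
    x /= np.sqrt(np.mean(x**2, axis=0, keepdims=True))
    return x


def _trapezoid(n: int, ramp_frac: float = 0.10) -> np.ndarray:
    """Trapezoidal envelope: linear rise/fall over ``ramp_frac`` of n each."""
    n_ramp = max(int(round(ramp_frac * n)), 1)
    env = np.ones(n)
    env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[n - n_ramp:] = np.linspace(1.0, 0.0, n_ramp)
    return env


def generate_recording(
    protocol: ProtocolSpec, model: SeparabilityModel, seed: int
) -> Recording:
    """Generate one full labeled session.

    Movements run in class order 1..n_movements; each contributes ``n_reps``
    repetitions of (contraction, rest).  Deterministic: the same
    (protocol, model, seed) reproduces the identical sample stream.
    """
    n_classes = protocol.n_movements + 1
    if model.amplitude.shape != (n_classes, protocol.n_channels):
        raise ValueError(
            f"amplitude must be [{n_classes} x {protocol.n_channels}], "
            f"got {model.amplitude.shape}"
        )
    rng = np.random.default_rng(seed)
    nc, nr = protocol.contraction_samples, protocol.rest_samples
    seg = nc + nr
    total = protocol.n_movements * protocol.n_reps * seg

    carrier = _bandlimited_noise(total, protocol.n_channels, protocol, rng)
    envelope = np.full((total, protocol.n_channels), model.noise_rms)
    labels = np.zeros(total, dtype=np.int64)
    rep_ids = np.zeros(total, dtype=np.int64)
    trap = _trapezoid(nc)

    pos = 0
    for mv in range(1, protocol.n_movements + 1):
        for rep in range(protocol.n_reps):
            jitter = 1.0 + model.rep_jitter * rng.standard_normal()
            jitter = max(jitter, 0.1)
            plateau = model.amplitude[mv] * jitter  # per-channel RMS
            envelope[pos:pos + nc] = (
                model.noise_rms + trap[:, None] * plateau[None, :]
            )
            labels[pos:pos + nc] = mv
            rep_ids[pos:pos + seg] = rep
            pos += seg

    sig = carrier * envelope
    sig -= sig.mean(axis=0, keepdims=True)
    return Recording(
        signal=sig,
        labels=labels,
        rep_ids=rep_ids,
        protocol=protocol,
        seed=seed,
        meta={"sep": model.sep, "noise_rms": model.noise_rms,
              "rep_jitter": model.rep_jitter},
    )


def write_recording_csv(rec: Recording, path) -> None:
    """One CSV per recording plus a JSON sidecar with protocol and seed."""
    t = np.arange(rec.signal.shape[0]) / rec.protocol.fs
    cols = {"time_s": t}
    for ch in range(rec.n_channels):
        cols[f"ch{ch + 1}"] = rec.signal[:, ch]
    cols["label"] = rec.labels
    cols["rep_id"] = rec.rep_ids
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"protocol": asdict(rec.protocol), "seed": rec.seed, "meta": rec.meta},
            fh,
            indent=2,
            default=list,
        )


def read_recording_csv(path) -> Recording:
    """Read a session written by :func:`write_recording_csv`."""
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    proto_kw = dict(side["protocol"])
    proto_kw["band"] = tuple(proto_kw["band"])
    protocol = ProtocolSpec(**proto_kw)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    return Recording(
        signal=df[ch_cols].to_numpy(),
        labels=df["label"].to_numpy(dtype=np.int64),
        rep_ids=df["rep_id"].to_numpy(dtype=np.int64),
        protocol=protocol,
        seed=side.get("seed"),
        meta=side.get("meta", {}),
    )
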