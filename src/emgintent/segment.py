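"""Segmentation of a labeled recording into equal-size windowed datasets.

The processing chain mirrors standard offline myoelectric-decoding practice:
15% of each 3-s contraction is cropped from both ends to isolate the static
muscle state, the rest class is built from the rest phases following a single
designated movement (trimmed to the contraction duration so every class
contributes the same amount of data), and the cropped segments are cut into
overlapping analysis windows (300 ms window, 150 ms increment by default).

Windowing is applied per repetition, never across a concatenation seam, so no
window mixes samples from two repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synth import Recording, REST

__all__ = [
    "SegmentationConfig",
    "WindowSet",
    "crop_contraction",
    "extract_rest",
    "window_signal",
    "build_windowset",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing and cropping parameters.

    ``rest_source_movement`` names the movement whose trailing rest phases
    supply the rest class (index flexion, class 1, in the emulated protocol).
    """

    window_ms: float = 300.0
    increment_ms: float = 150.0
    crop_frac: float = 0.15
    rest_source_movement: int = 1
    rest_trim_s: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.crop_frac < 0.5:
            raise ValueError("crop_frac must be in [0, 0.5)")
        if self.increment_ms > self.window_ms:
            raise ValueError("increment_ms must not exceed window_ms")
        if self.window_ms <= 0 or self.increment_ms <= 0:
            raise ValueError("window and increment must be positive")
        if self.window_ms > 300.0:
            warnings.warn(
                "window_ms > 300 exceeds the perceptible control-delay bound "
                "for real-time prosthetic use",
                stacklevel=2,
            )


@dataclass
class WindowSet:
    """Windowed samples keyed by movement class.

    ``provenance[i] = (class_id, repetition, window_index_within_repetition)``.
    """

    windows: list[np.ndarray]            # each [window_samples, n_channels]
    labels: np.ndarray                   # [n_windows] int
    provenance: list[tuple[int, int, int]] = field(default_factory=list)
    fs: float = 6000.0

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, classes) -> "WindowSet":
        """Restrict to the given class ids (used by movement reduction)."""
        keep = np.isin(self.labels, np.asarray(list(classes)))
        idx = np.flatnonzero(keep)
        return WindowSet(
            windows=[self.windows[i] for i in idx],
            labels=self.labels[idx],
            provenance=[self.provenance[i] for i in idx],
            fs=self.fs,
        )


def crop_contraction(segment: np.ndarray, crop_frac: float) -> np.ndarray:
    """Return the central ``1 - 2*crop_frac`` portion of a contraction.

    The cut on each side is ``floor(crop_frac * n)`` samples; if the retained
    length then exceeds ``round((1 - 2 crop) * n)`` by one (odd parity), one
    trailing sample is dropped to keep the trim symmetric in expectation.
    """
    segment = np.asarray(segment)
    n = segment.shape[0]
    if n == 0:
        raise ValueError("empty segment")
    if not 0 <= crop_frac < 0.5:
        raise ValueError("crop_frac must be in [0, 0.5)")
    cut = int(np.floor(crop_frac * n))
    out = segment[cut:n - cut]
    target = int(round((1 - 2 * crop_frac) * n))
    if out.shape[0] > target:
        out = out[: target]
    return out


def window_signal(
    segment: np.ndarray, window_ms: float, increment_ms: float, fs: float
) -> list[np.ndarray]:
    """Slide a window over a segment; the last partial window is discarded.

    Returns ``floor((L - W) / I) + 1`` windows for L >= W, else an empty
    list (with a warning).
    """
    segment = np.atleast_2d(np.asarray(segment))
    if segment.shape[0] == 1 and segment.shape[1] > 1 and segment.ndim == 2:
        # 1-D input arrived as a row; treat samples along axis 0
        segment = segment.T
    w = int(round(window_ms * fs / 1000.0))
    inc = int(round(increment_ms * fs / 1000.0))
    L = segment.shape[0]
    if L < w:
        warnings.warn(f"segment of {L} samples shorter than one {w}-sample window",
                      stacklevel=2)
        return []
    n_win = (L - w) // inc + 1
    return [segment[i * inc: i * inc + w] for i in range(n_win)]


def _contraction_segments(rec: Recording, movement: int) -> list[np.ndarray]:
    """Per-repetition contraction sample blocks for one movement, in order."""
    segs = []
    mask = rec.labels == movement
    if not mask.any():
        raise ValueError(f"movement {movement} not present in recording")
    # repetition boundaries within this movement
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [idx.size]])
    for a, b in zip(starts, stops):
        segs.append(rec.signal[idx[a]:idx[b - 1] + 1])
    return segs


def extract_rest(rec: Recording, cfg: SegmentationConfig) -> list[np.ndarray]:
    """Rest segments: the rest phase after each ``rest_source_movement``
    repetition, truncated to ``rest_trim_s`` and cropped like contractions."""
    mv = cfg.rest_source_movement
    mask = rec.labels == mv
    if not mask.any():
        raise ValueError(f"rest source movement {mv} not present")
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    ends = np.concatenate([idx[breaks], [idx[-1]]])  # last sample of each rep
    n_trim = int(round(cfg.rest_trim_s * rec.protocol.fs))
    segs = []
    for k, end in enumerate(ends):
        start = end + 1
        stop = start
        n = rec.labels.size
        while stop < n and rec.labels[stop] == REST:
            stop += 1
        if stop == start:
            raise ValueError(f"no rest phase after repetition {k} of movement {mv}")
        rest = rec.signal[start: min(stop, start + n_trim)]
        segs.append(crop_contraction(rest, cfg.crop_frac))
    return segs


def build_windowset(rec: Recording, cfg: SegmentationConfig) -> WindowSet:
    """Crop, window and assemble all classes into one balanced WindowSet."""
    fs = rec.protocol.fs
    windows: list[np.ndarray] = []
    labels: list[int] = []
    prov: list[tuple[int, int, int]] = []

    def add(segs, class_id):
        count = 0
        for rep, seg in enumerate(segs):
            ws = window_signal(seg, cfg.window_ms, cfg.increment_ms, fs)
            for j, w in enumerate(ws):
                windows.append(np.ascontiguousarray(w))
                labels.append(class_id)
                prov.append((class_id, rep, j))
                count += 1
        if count == 0:
            raise ValueError(f"class {class_id} produced zero windows")

    add(extract_rest(rec, cfg), REST)
    for mv in range(1, rec.protocol.n_movements + 1):
        segs = [crop_contraction(s, cfg.crop_frac)
                for s in _contraction_segments(rec, mv)]
        add(segs, mv)
    return WindowSet(windows=windows, labels=np.asarray(labels), provenance=prov,
                     fs=fs)
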