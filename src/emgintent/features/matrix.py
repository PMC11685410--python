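"""Feature-matrix assembly: windows x (feature, channel) columns."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..segment import WindowSet
from .registry import FeatureSpec, column_tags, get_spec

__all__ = ["FeatureMatrix", "extract_feature", "extract_matrix",
           "read_matrix_csv", "write_matrix_csv"]


@dataclass
class FeatureMatrix:
    """Rows = windows, columns = flattened feature values across channels.

    ``groups`` (optional) carries the source repetition of each row, used by
    the repetition-grouped split that controls window-overlap leakage.
    """

    values: np.ndarray                         # [n_windows, n_columns]
    columns: list[tuple[str, str, int]]        # (feature id, channel tag, sub)
    labels: np.ndarray                         # [n_windows]
    groups: np.ndarray | None = None           # [n_windows] repetition ids

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata length must equal column count")

    @property
    def feature_ids(self) -> list[str]:
        """Distinct feature ids in first-appearance (catalog) order."""
        seen: list[str] = []
        for fid, _, _ in self.columns:
            if fid not in seen:
                seen.append(fid)
        return seen

    def column_indices(self, feature_ids) -> np.ndarray:
        """Indices of all columns belonging to the given feature ids."""
        wanted = set(feature_ids)
        return np.array([i for i, (fid, _, _) in enumerate(self.columns)
                         if fid in wanted], dtype=int)

    def select_features(self, feature_ids) -> "FeatureMatrix":
        """Sub-matrix restricted to the given feature ids."""
        idx = self.column_indices(feature_ids)
        return FeatureMatrix(
            values=self.values[:, idx],
            columns=[self.columns[i] for i in idx],
            labels=self.labels,
            groups=self.groups,
        )


def extract_feature(window: np.ndarray, spec: FeatureSpec, fs: float) -> np.ndarray:
    """Evaluate one feature on one window.

    Per-channel features return one value block per channel (channel-major);
    cross-channel features return their declared vector over channel pairs
    or channels.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.shape[0] <= 1:
        raise ValueError("window must contain more than one sample")
    out = np.asarray(spec.func(window, fs), dtype=float)
    return out.ravel()


def extract_matrix(ws: WindowSet, specs: list[FeatureSpec], fs: float | None = None
                   ) -> FeatureMatrix:
    """Extract all features for every window of a WindowSet.

    Row order follows the WindowSet's provenance order; columns are grouped
    by feature (catalog order of ``specs``), then channel.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    fs = ws.fs if fs is None else fs
    n_ch = ws.windows[0].shape[1]
    columns: list[tuple[str, str, int]] = []
    for s in specs:
        columns.extend(column_tags(s, n_ch))

    rows = np.empty((len(ws.windows), len(columns)))
    for i, w in enumerate(ws.windows):
        parts = [extract_feature(w, s, fs) for s in specs]
        rows[i] = np.concatenate(parts)
        if not np.all(np.isfinite(rows[i])):
            off = 0
            for s, p in zip(specs, parts):
                if not np.all(np.isfinite(p)):
                    raise ValueError(
                        f"non-finite value for feature {s.id!r} on window {i}"
                    )
                off += p.size
    groups = (np.array([p[1] for p in ws.provenance])
              if ws.provenance else None)
    return FeatureMatrix(values=rows, columns=columns,
                         labels=np.asarray(ws.labels), groups=groups)


def write_matrix_csv(fm: FeatureMatrix, path) -> None:
    """CSV of values+labels plus a JSON header with column metadata."""
    names = [f"{fid}|{tag}|{sub}" for fid, tag, sub in fm.columns]
    df = pd.DataFrame(fm.values, columns=names)
    df["label"] = fm.labels
    df.to_csv(path, index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"columns": [list(c) for c in fm.columns]}, fh)


def read_matrix_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    cols = [tuple(c) for c in meta["columns"]]
    return FeatureMatrix(
        values=df.drop(columns=["label"]).to_numpy(),
        columns=[(c[0], c[1], int(c[2])) for c in cols],
        labels=df["label"].to_numpy(),
    )
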