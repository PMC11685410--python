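"""Time-frequency features (9 entries): statistics of the discrete wavelet
transform, 4th-order Coiflet, 4-level decomposition, symmetric padding.

"4th level wavelet coefficients" means the level-4 approximation band cA4;
``tfmxabs2`` additionally spans all detail bands cD1..cD4.
"""

from __future__ import annotations

import numpy as np
import pywt

WAVELET = "coif4"
LEVEL = 4
MODE = "symmetric"


def min_window_length() -> int:
    """Smallest window supporting a 4-level decomposition with coif4."""
    # wavedec requires len(x) >= filter_len at the deepest level; a practical
    # bound is filter_len * 2**level
    return pywt.Wavelet(WAVELET).dec_len * 2 ** LEVEL


def decompose(x: np.ndarray) -> list[np.ndarray]:
    """[cA4, cD4, cD3, cD2, cD1] for one channel."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < pywt.Wavelet(WAVELET).dec_len * 2:
        raise ValueError(
            f"window of {x.shape[0]} samples too short for a {LEVEL}-level "
            f"{WAVELET} DWT; need >= {min_window_length()}"
        )
    return pywt.wavedec(x, WAVELET, mode=MODE, level=LEVEL)


def _per_channel(X, func):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.array([func(decompose(X[:, c])) for c in range(X.shape[1])])


def tfstd(X, fs=None):
    """Standard deviation of the level-4 approximation coefficients."""
    return _per_channel(X, lambda co: np.std(co[0], ddof=1))


def tfvar(X, fs=None):
    """Variance of the level-4 approximation coefficients."""
    return _per_channel(X, lambda co: np.var(co[0], ddof=1))


def tfwl(X, fs=None):
    """Waveform length of the level-4 approximation coefficients."""
    return _per_channel(X, lambda co: np.sum(np.abs(np.diff(co[0]))))


def tfe(X, fs=None):
    """Energy of the level-4 approximation coefficients."""
    return _per_channel(X, lambda co: np.sum(co[0] ** 2))


def tfmxabs1(X, fs=None):
    """Maximum absolute level-4 approximation coefficient."""
    return _per_channel(X, lambda co: np.max(np.abs(co[0])))


def tfmxabs2(X, fs=None):
    """Maximum absolute coefficient over the approximation and all detail
    levels."""
    return _per_channel(
        X, lambda co: max(np.max(np.abs(c)) for c in co)
    )


def tfzc(X, fs=None):
    """Zero crossings of the level-4 approximation coefficients."""
    def zc(co):
        a = co[0]
        return float(np.sum(a[:-1] * a[1:] < 0))
    return _per_channel(X, zc)


def tfmn(X, fs=None):
    """Mean of the level-4 approximation coefficients."""
    return _per_channel(X, lambda co: np.mean(co[0]))


def tfmabs(X, fs=None):
    """Mean absolute value of the level-4 approximation coefficients."""
    return _per_channel(X, lambda co: np.mean(np.abs(co[0])))
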