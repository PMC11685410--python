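"""Time-domain features (31 entries of the catalog).

Every per-channel function takes a window ``X`` of shape ``[n_samples,
n_channels]`` and returns ``[n_channels]`` (or ``[n_channels, d]`` for
vector-valued features); cross-channel functions return a flat vector over
channel pairs or channels.  All are numpy-vectorized along channels except
the few that need a per-channel scan (peak-velocity, Higuchi).

Counting features (zero crossings, slope sign changes) use a zero deadband;
only the Willison amplitude carries an explicit 0.01 V threshold.  Degenerate
(constant) windows return finite values by convention so that downstream
matrices never contain NaN/inf.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_EPS = 1e-30


def _as2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


# ---------------------------------------------------------------- amplitude

def tmabs(X, fs=None):
    """Mean absolute value."""
    return np.mean(np.abs(_as2d(X)), axis=0)


def tstd(X, fs=None):
    """Sample standard deviation."""
    return np.std(_as2d(X), axis=0, ddof=1)


def tvar(X, fs=None):
    """Sample variance (Hjorth activity)."""
    return np.var(_as2d(X), axis=0, ddof=1)


def twl(X, fs=None):
    """Waveform length: total path length of the signal."""
    return np.sum(np.abs(np.diff(_as2d(X), axis=0)), axis=0)


def trms(X, fs=None):
    """Root mean square."""
    return np.sqrt(np.mean(_as2d(X) ** 2, axis=0))


def tpwr(X, fs=None):
    """Mean power."""
    return np.mean(_as2d(X) ** 2, axis=0)


def tiabs(X, fs=None):
    """Integrated absolute value: sum of |x|."""
    return np.sum(np.abs(_as2d(X)), axis=0)


def tssi(X, fs=None):
    """Simple square integral: sum of x^2."""
    return np.sum(_as2d(X) ** 2, axis=0)


def tperc75(X, fs=None):
    """75th percentile of the raw samples."""
    return np.percentile(_as2d(X), 75, axis=0)


def tlogd(X, fs=None):
    """Log detector: exp of the mean log magnitude."""
    return np.exp(np.mean(np.log(np.abs(_as2d(X)) + _EPS), axis=0))


# ----------------------------------------------------------------- counting

def tzc(X, fs=None):
    """Zero crossings (zero deadband): strict sign changes."""
    X = _as2d(X)
    return np.sum(X[:-1] * X[1:] < 0, axis=0).astype(float)


def tslpch(X, fs=None):
    """Slope sign changes (zero deadband)."""
    d = np.diff(_as2d(X), axis=0)
    return np.sum(d[:-1] * d[1:] < 0, axis=0).astype(float)


def twam(X, fs=None, threshold=0.01):
    """Willison amplitude: successive differences exceeding the threshold."""
    d = np.abs(np.diff(_as2d(X), axis=0))
    return np.sum(d > threshold, axis=0).astype(float)


def tcard(X, fs=None, threshold=0.01):
    """Cardinality: distinct amplitude levels — sorted adjacent differences
    above the threshold."""
    Y = np.sort(_as2d(X), axis=0)
    return np.sum(np.abs(np.diff(Y, axis=0)) > threshold, axis=0).astype(float)


def _peak_mask(X: np.ndarray) -> np.ndarray:
    """Local maxima exceeding the channel RMS; boolean over X[1:-1]."""
    r = np.sqrt(np.mean(X ** 2, axis=0))
    mid = X[1:-1]
    return (mid > X[:-2]) & (mid > X[2:]) & (mid > r)


def tpks(X, fs=None):
    """Number of local peaks above the RMS level."""
    return np.sum(_peak_mask(_as2d(X)), axis=0).astype(float)


def tmpks(X, fs=None):
    """Mean amplitude of the above-RMS peaks (0 if none)."""
    X = _as2d(X)
    m = _peak_mask(X)
    mid = X[1:-1]
    out = np.zeros(X.shape[1])
    for c in range(X.shape[1]):
        v = mid[m[:, c], c]
        if v.size:
            out[c] = v.mean()
    return out


def tmvel(X, fs=6000.0):
    """Mean velocity between successive above-RMS peaks (0 if < 2 peaks)."""
    X = _as2d(X)
    m = _peak_mask(X)
    out = np.zeros(X.shape[1])
    for c in range(X.shape[1]):
        idx = np.flatnonzero(m[:, c]) + 1
        if idx.size >= 2:
            v = X[idx, c]
            out[c] = np.mean(np.diff(v) / (np.diff(idx) / fs))
    return out


# --------------------------------------------------------------- difference

def tdam(X, fs=None):
    """Difference absolute mean value: mean |Δx|."""
    return np.mean(np.abs(np.diff(_as2d(X), axis=0)), axis=0)


def tdasdv(X, fs=None):
    """Difference absolute standard deviation value: RMS of Δx."""
    return np.sqrt(np.mean(np.diff(_as2d(X), axis=0) ** 2, axis=0))


# ------------------------------------------------------------------ fractal

def tmfl(X, fs=None):
    """Maximum fractal length: log10 of the RMS path increment norm."""
    s = np.sum(np.diff(_as2d(X), axis=0) ** 2, axis=0)
    return np.log10(np.sqrt(s) + _EPS)


def tfd(X, fs=None):
    """Katz fractal dimension."""
    X = _as2d(X)
    n = X.shape[0] - 1
    L = np.sum(np.abs(np.diff(X, axis=0)), axis=0)
    d = np.max(np.abs(X - X[0]), axis=0)
    out = np.ones(X.shape[1])
    ok = (L > 0) & (d > 0)
    out[ok] = np.log10(n) / (np.log10(n) + np.log10(d[ok] / L[ok]))
    return out


def tfdh(X, fs=None, k_max=8):
    """Higuchi fractal dimension (k_max = 8)."""
    X = _as2d(X)
    N = X.shape[0]
    ks = np.arange(1, k_max + 1)
    out = np.empty(X.shape[1])
    for c in range(X.shape[1]):
        x = X[:, c]
        Lk = np.empty(k_max)
        for i, k in enumerate(ks):
            lengths = []
            for m in range(k):
                idx = np.arange(m, N, k)
                if idx.size < 2:
                    continue
                norm = (N - 1) / ((idx.size - 1) * k)
                lengths.append(np.sum(np.abs(np.diff(x[idx]))) * norm / k)
            Lk[i] = np.mean(lengths) if lengths else 0.0
        good = Lk > 0
        if good.sum() >= 2:
            slope, _ = np.polyfit(np.log(1.0 / ks[good]), np.log(Lk[good]), 1)
            out[c] = slope
        else:
            out[c] = 0.0
    return out


# ------------------------------------------------------------------ entropy

def tren(X, fs=None):
    """Rough (energy) entropy: Shannon entropy of per-sample normalized
    energy."""
    X = _as2d(X)
    e = X ** 2
    tot = np.sum(e, axis=0)
    out = np.zeros(X.shape[1])
    for c in range(X.shape[1]):
        if tot[c] > 0:
            p = e[:, c] / tot[c]
            p = p[p > 0]
            out[c] = -np.sum(p * np.log(p))
    return out


# ------------------------------------------------------------------- Hjorth

def tHmob(X, fs=None):
    """Hjorth mobility: sqrt(var(dx) / var(x))."""
    X = _as2d(X)
    v0 = np.var(X, axis=0)
    v1 = np.var(np.diff(X, axis=0), axis=0)
    return np.sqrt(np.divide(v1, v0, out=np.zeros_like(v0), where=v0 > 0))


def tHcom(X, fs=None):
    """Hjorth complexity: mobility of the derivative over mobility of x."""
    X = _as2d(X)
    d = np.diff(X, axis=0)
    m1 = tHmob(X)
    m2 = tHmob(d)
    return np.divide(m2, m1, out=np.zeros_like(m1), where=m1 > 0)


# ------------------------------------------------------------------ moments

def tskw(X, fs=None):
    """Skewness (3rd standardized moment)."""
    out = stats.skew(_as2d(X), axis=0)
    return np.nan_to_num(np.atleast_1d(out))


def tkurt(X, fs=None):
    """Kurtosis (4th standardized moment, non-excess)."""
    out = stats.kurtosis(_as2d(X), axis=0, fisher=False)
    return np.nan_to_num(np.atleast_1d(out))


# ---------------------------------------------------------------- histogram

def thist(X, fs=None, bins=9):
    """9-bin amplitude histogram spanning the window's min-max voltage."""
    X = _as2d(X)
    out = np.empty((X.shape[1], bins))
    for c in range(X.shape[1]):
        lo, hi = X[:, c].min(), X[:, c].max()
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        out[c], _ = np.histogram(X[:, c], bins=bins, range=(lo, hi))
    return out


# ------------------------------------------------------------ cross-channel

def tcr(X, fs=None):
    """Pearson correlation coefficient, one value per unordered channel
    pair (upper triangle, row-major)."""
    X = _as2d(X)
    c = X.shape[1]
    if c < 2:
        return np.zeros(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X.T)
    R = np.nan_to_num(R)
    iu = np.triu_indices(c, k=1)
    return R[iu]


def tcv(X, fs=None):
    """Covariance, one value per unordered channel pair."""
    X = _as2d(X)
    c = X.shape[1]
    if c < 2:
        return np.zeros(0)
    C = np.cov(X.T, ddof=1)
    iu = np.triu_indices(c, k=1)
    return np.atleast_2d(C)[iu]


def tmcer(X, fs=None):
    """Multi-channel energy ratio: each channel's energy over the total."""
    X = _as2d(X)
    e = np.sum(X ** 2, axis=0)
    tot = e.sum()
    return e / tot if tot > 0 else np.full(X.shape[1], 1.0 / X.shape[1])
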