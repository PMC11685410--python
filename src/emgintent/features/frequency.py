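"""Frequency-domain features (9 entries), computed per channel from the
one-sided FFT power spectrum of the unwindowed (rectangular) segment."""

from __future__ import annotations

import numpy as np

_EPS = 1e-30


def power_spectrum(X: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT periodogram: (freqs [m], power [m, n_channels])."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    spec = np.fft.rfft(X, axis=0)
    P = (np.abs(spec) ** 2) / n
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return f, P


def fwl(X, fs):
    """Spectral waveform length: path length of the power spectrum."""
    _, P = power_spectrum(X, fs)
    return np.sum(np.abs(np.diff(P, axis=0)), axis=0)


def fmn(X, fs):
    """Mean frequency: power-weighted average frequency."""
    f, P = power_spectrum(X, fs)
    tot = P.sum(axis=0)
    return (f[:, None] * P).sum(axis=0) / np.where(tot > 0, tot, _EPS)


def fmd(X, fs):
    """Median frequency: splits the spectral power in half."""
    f, P = power_spectrum(X, fs)
    out = np.empty(P.shape[1])
    for c in range(P.shape[1]):
        cum = np.cumsum(P[:, c])
        tot = cum[-1]
        if tot <= 0:
            out[c] = 0.0
            continue
        out[c] = f[np.searchsorted(cum, tot / 2.0)]
    return out


def _spectral_peaks(P: np.ndarray) -> list[np.ndarray]:
    """Per channel, amplitudes of local spectral maxima above the spectrum's
    RMS level."""
    r = np.sqrt(np.mean(P ** 2, axis=0))
    mid = P[1:-1]
    mask = (mid > P[:-2]) & (mid > P[2:]) & (mid > r)
    return [mid[mask[:, c], c] for c in range(P.shape[1])]


def fpmn(X, fs):
    """Mean amplitude of spectral peaks above the spectrum RMS."""
    _, P = power_spectrum(X, fs)
    return np.array([v.mean() if v.size else 0.0 for v in _spectral_peaks(P)])


def fpmd(X, fs):
    """Median amplitude of spectral peaks above the spectrum RMS."""
    _, P = power_spectrum(X, fs)
    return np.array([np.median(v) if v.size else 0.0 for v in _spectral_peaks(P)])


def fpstd(X, fs):
    """Standard deviation of spectral-peak amplitudes above the RMS."""
    _, P = power_spectrum(X, fs)
    return np.array(
        [v.std(ddof=1) if v.size > 1 else 0.0 for v in _spectral_peaks(P)]
    )


def fmxp(X, fs):
    """Maximum spectral power."""
    _, P = power_spectrum(X, fs)
    return P.max(axis=0)


def fr(X, fs, low_band=(20.0, 250.0), high_band=(250.0, 450.0)):
    """Frequency ratio: band power 20-250 Hz over 251-450 Hz."""
    f, P = power_spectrum(X, fs)
    lo = P[(f >= low_band[0]) & (f <= low_band[1])].sum(axis=0)
    hi = P[(f > high_band[0]) & (f <= high_band[1])].sum(axis=0)
    return lo / np.where(hi > 0, hi, _EPS)


def fe(X, fs, band=(20.0, 450.0), bin_hz=10.0):
    """Spectral energies in 10 Hz bins spanning 20-450 Hz (43 values per
    channel)."""
    f, P = power_spectrum(X, fs)
    edges = np.arange(band[0], band[1] + bin_hz / 2, bin_hz)
    n_bins = len(edges) - 1
    out = np.empty((P.shape[1], n_bins))
    idx = np.digitize(f, edges) - 1
    for b in range(n_bins):
        sel = idx == b
        out[:, b] = P[sel].sum(axis=0) if sel.any() else 0.0
    return out


FE_BINS = 43  # (450 - 20) / 10
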