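"""Rank-based comparison of feature sets or classifiers.

Accuracy matrices are N blocks (the movements, here N = 11) by k treatments
(feature sets or classifiers).  Within each block the best accuracy gets
rank 1 (ties averaged).  The Friedman chi-square on average ranks,

    chi2_F = 12 N / (k (k+1)) * [ sum_j Rbar_j^2 - k (k+1)^2 / 4 ],

is converted to the improved (Iman-Davenport) statistic

    F_F = (N - 1) chi2_F / (N (k - 1) - chi2_F),

compared to the F distribution with df (k-1, (k-1)(N-1)).  When the null of
equal ranks is rejected, the post-hoc two-tailed Nemenyi test flags any
treatment pair whose average-rank difference exceeds the critical distance

    CD = q_alpha * sqrt(k (k+1) / (6 N)),

with q_alpha the studentized-range critical value (infinite df) divided by
sqrt(2).  For the matrices used in this field's comparisons these constants
are F(6,60) = 2.25, F(4,40) = 2.60, CD(k=7, N=11) = 2.72 and
CD(k=5, N=11) = 1.84 at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RankTable", "FriedmanResult", "NemenyiResult", "rank_blocks",
           "friedman_improved", "nemenyi_cd", "nemenyi_pairwise",
           "Q_ALPHA_05_FALLBACK"]

#: q_alpha / sqrt(2) at alpha = 0.05 for k = 2..10 treatments (infinite df),
#: the standard two-tailed Nemenyi constants; used as a cross-check against
#: the distribution-based computation.
Q_ALPHA_05_FALLBACK = {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
                       7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164}


@dataclass
class RankTable:
    accuracy: np.ndarray     # [N, k] percent
    ranks: np.ndarray        # [N, k], 1 = best within block
    avg_rank: np.ndarray     # [k]

    @property
    def N(self) -> int:
        return self.accuracy.shape[0]

    @property
    def k(self) -> int:
        return self.accuracy.shape[1]


@dataclass
class FriedmanResult:
    chi2: float
    FF: float
    df: tuple[int, int]
    critical: float
    reject: bool
    alpha: float

    def to_json(self) -> dict:
        return {"chi2": self.chi2, "FF": self.FF, "df": list(self.df),
                "critical": self.critical, "reject": self.reject,
                "alpha": self.alpha}


@dataclass
class NemenyiResult:
    cd: float
    pairwise: list[dict]     # {i, j, diff, significant}

    def to_json(self) -> dict:
        return {"cd": self.cd, "pairwise": self.pairwise}


def rank_blocks(accuracy: np.ndarray) -> RankTable:
    """Within-block ranks, 1 = highest accuracy, ties averaged."""
    A = np.asarray(accuracy, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("accuracy must be an N x k matrix with N, k >= 2")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite accuracy entries")
    ranks = np.apply_along_axis(stats.rankdata, 1, -A)
    return RankTable(accuracy=A, ranks=ranks, avg_rank=ranks.mean(axis=0))


def friedman_improved(rt: RankTable, alpha: float = 0.05) -> FriedmanResult:
    """Friedman chi-square and Iman-Davenport improved F statistic."""
    N, k = rt.N, rt.k
    Rbar = rt.avg_rank
    chi2 = 12.0 * N / (k * (k + 1)) * (np.sum(Rbar**2) - k * (k + 1) ** 2 / 4.0)
    denom = N * (k - 1) - chi2
    df = (k - 1, (k - 1) * (N - 1))
    critical = float(stats.f.ppf(1 - alpha, *df))
    if denom <= 0:
        return FriedmanResult(chi2=float(chi2), FF=float("inf"), df=df,
                              critical=critical, reject=True, alpha=alpha)
    FF = (N - 1) * chi2 / denom
    return FriedmanResult(chi2=float(chi2), FF=float(FF), df=df,
                          critical=critical, reject=bool(FF > critical),
                          alpha=alpha)


def nemenyi_cd(k: int, N: int, alpha: float = 0.05,
               use_fallback: bool = False) -> float:
    """Two-tailed Nemenyi critical distance for k treatments over N blocks."""
    if k < 2 or N < 1:
        raise ValueError("need k >= 2 and N >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if use_fallback:
        if alpha != 0.05 or k not in Q_ALPHA_05_FALLBACK:
            raise ValueError("fallback table covers alpha=0.05, k <= 10")
        q = Q_ALPHA_05_FALLBACK[k]
    else:
        # studentized range with infinite df; large finite df for stability
        q = float(stats.studentized_range.ppf(1 - alpha, k, 1e7)) / np.sqrt(2)
    return q * np.sqrt(k * (k + 1) / (6.0 * N))


def nemenyi_pairwise(rt: RankTable, cd: float) -> NemenyiResult:
    """All k(k-1)/2 average-rank differences flagged against the CD."""
    pairs = []
    for i in range(rt.k):
        for j in range(i + 1, rt.k):
            diff = float(abs(rt.avg_rank[i] - rt.avg_rank[j]))
            pairs.append({"i": i, "j": j, "diff": diff,
                          "significant": bool(diff > cd)})
    return NemenyiResult(cd=float(cd), pairwise=pairs)
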