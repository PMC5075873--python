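"""The three statistical tests used by the analysis pipeline.

Implemented self-contained so the statistic definitions stay explicit:
Wilcoxon rank sum (rank-sum statistic of the smaller group, exact by
enumeration for small samples, otherwise a tie-corrected normal
approximation), the pooled two-sample proportion z test without continuity
correction, and the binomial point probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm, rankdata

EXACT_LIMIT = 12  # enumerate all label assignments when n1 + n2 <= this


@dataclass(frozen=True)
class RankSumReport:
    W: float
    n1: int
    n2: int
    p: float
    method: Literal["exact", "normal"]
    swapped: bool = False  # True when the input groups were reordered by size

    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "n1": self.n1,
            "n2": self.n2,
            "p": self.p,
            "method": self.method,
        }


@dataclass(frozen=True)
class ProportionReport:
    z: float
    p_hat: float
    m: int
    n: int
    p: float
    sided: Literal["one", "two"]

    def to_dict(self) -> dict:
        return {
            "z": self.z,
            "p_hat": self.p_hat,
            "m": self.m,
            "n": self.n,
            "p": self.p,
            "sided": self.sided,
        }


def wilcoxon_rank_sum(
    group1: Sequence[float],
    group2: Sequence[float],
    exact_limit: int = EXACT_LIMIT,
) -> RankSumReport:
    """Two-sided Wilcoxon rank-sum test.

    ``W`` is the sum of pooled mid-ranks of group-1, where group-1 is the
    smaller group (inputs are swapped if needed).  The exact p enumerates
    every assignment of group labels to the pooled values; the
    approximation uses the normal distribution with tie-corrected variance
    and no continuity correction.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    swapped = g1.size > g2.size
    if swapped:
        g1, g2 = g2, g1
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    ranks = rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0

    if n <= exact_limit:
        sums = [
            ranks[list(pos)].sum() for pos in combinations(range(n), n1)
        ]
        dev = abs(w - mu)
        hits = sum(1 for s in sums if abs(s - mu) >= dev - 1e-12)
        return RankSumReport(
            W=w, n1=n1, n2=n2, p=hits / len(sums), method="exact", swapped=swapped
        )

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # every pooled value identical: no evidence against equal medians
        return RankSumReport(W=w, n1=n1, n2=n2, p=1.0, method="normal", swapped=swapped)
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return RankSumReport(W=w, n1=n1, n2=n2, p=min(p, 1.0), method="normal", swapped=swapped)


def two_sample_proportion(
    k1: int,
    m: int,
    k2: int,
    n: int,
    sided: Literal["one", "two"] = "two",
) -> ProportionReport:
    """Pooled-estimate z test for equality of two proportions.

    ``z = (k1/m - k2/n) / sqrt(p_hat (1 - p_hat) (1/m + 1/n))`` with the
    pooled ``p_hat = (k1 + k2) / (m + n)``; no continuity correction.  The
    one-sided p is the upper tail of z (proportion 1 greater).
    """
    if m <= 0 or n <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= m and 0 <= k2 <= n):
        raise ValueError("success counts must lie within sample sizes")
    p_hat = (k1 + k2) / (m + n)
    if p_hat in (0.0, 1.0):
        raise ValueError(
            f"pooled proportion is {p_hat}; the z statistic is undefined"
        )
    z = (k1 / m - k2 / n) / math.sqrt(p_hat * (1 - p_hat) * (1 / m + 1 / n))
    p = float(norm.sf(z)) if sided == "one" else float(2.0 * norm.sf(abs(z)))
    return ProportionReport(z=z, p_hat=p_hat, m=m, n=n, p=min(p, 1.0), sided=sided)


def binomial_point(n: int, k: int, q: float) -> float:
    """Point probability C(n, k) q^k (1 - q)^(n - k)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    # 0^0 := 1 so degenerate q with matching k gives probability 1
    return math.comb(n, k) * q ** k * (1.0 - q) ** (n - k)
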