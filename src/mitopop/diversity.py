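"""Haplotype diversity, nucleotide diversity, Tajima's D, and Fu's Fs.

Conventions
-----------
* h = n(1 - sum p_i^2)/(n - 1)               (Nei 1987)
* pi = (n/(n-1)) * sum_{i<j} 2 p_i p_j d_ij  (per-site p-distance d_ij);
  this equals the direct mean of per-site differences over all C(n,2)
  individual pairs.
* Tajima's D = (kbar - S/a1) / sqrt(e1*S + e2*S*(S-1))   (Tajima 1989)
* Fu's Fs = ln(S'/(1-S')) with S' = P(K >= K_obs) under the Ewens sampling
  distribution at theta = kbar (Fu 1997), computed entirely in log space
  via the unsigned-Stirling-number recurrence.

Undefined statistics (S=0 for D, theta=0 for Fs, n<2 for h) are signalled
with ``UndefinedStatistic`` and reported as NA downstream, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from mitopop.haplotypes import HaplotypeSet


class UndefinedStatistic(ValueError):
    """A statistic is undefined for the given sample (e.g. S=0, n<2)."""


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    K: int
    h: float
    pi: float
    kbar: float
    S: int
    D: float | None
    Fs: float | None


def haplotype_diversity(hset: HaplotypeSet) -> float:
    """Nei's haplotype (gene) diversity with small-sample correction."""
    n = hset.n
    if n < 2:
        raise UndefinedStatistic("haplotype diversity needs n >= 2")
    p = hset.p
    return n * (1.0 - float(p @ p)) / (n - 1)


def _hap_pdist(hset: HaplotypeSet) -> np.ndarray:
    """Per-site p-distance between haplotypes over the analysis sites."""
    K = hset.K
    L = len(hset.sequences[0])
    mat = np.frombuffer("".join(hset.sequences).encode(), dtype="S1")
    mat = mat.reshape(K, L)
    d = np.zeros((K, K))
    for i in range(K):
        diff = (mat != mat[i]).sum(axis=1) / L
        d[i] = diff
    return d


def nucleotide_diversity(hset: HaplotypeSet) -> tuple[float, float]:
    """Return (pi, kbar): per-site nucleotide diversity and mean pairwise
    differences in sites."""
    n = hset.n
    if n < 2:
        raise UndefinedStatistic("nucleotide diversity needs n >= 2")
    if hset.sequences[0].startswith("?"):
        raise UndefinedStatistic(
            "nucleotide diversity requires haplotype sequences, not a bare "
            "frequency spectrum"
        )
    L = len(hset.sequences[0])
    p = hset.p
    d = _hap_pdist(hset)
    pi = (n / (n - 1)) * float(p @ d @ p)  # off-diagonal double-counts i<j pairs
    return pi, pi * L


def tajima_constants(n: int) -> dict[str, float]:
    """a1, a2, b1, b2, c1, c2, e1, e2 of Tajima (1989)."""
    if n < 2:
        raise UndefinedStatistic("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, kbar: float) -> float:
    """Tajima's D from sample size, segregating sites, and mean pairwise
    differences."""
    if n < 4:
        raise UndefinedStatistic("Tajima's D needs n >= 4")
    if S < 1:
        raise UndefinedStatistic("Tajima's D is undefined for S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (kbar - S / c["a1"]) / math.sqrt(var)


def log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind).

    Built iteratively from |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)| with
    log-sum-exp, so rows stay finite for n in the thousands.
    """
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1 (and |s(0,0)| = 1 when n=0)
    if n == 0:
        row[0] = 0.0
        return row
    for m in range(2, n + 1):
        new = np.full(n + 1, -np.inf)
        lm = math.log(m - 1)
        # new[k] = logaddexp(row[k-1], log(m-1) + row[k])
        new[1 : m + 1] = np.logaddexp(row[0:m], lm + row[1 : m + 1])
        row = new
    return row


def fus_fs(n: int, K_obs: int, theta: float) -> float:
    """Fu's Fs = ln(S'/(1-S')), S' = P(K >= K_obs | theta) under Ewens.

    Returns +inf when K_obs == 1 (S' = 1) and raises for theta <= 0.
    Computed in log space; stable for n up to a few thousand.
    """
    if n < 2 or not (1 <= K_obs <= n):
        raise UndefinedStatistic("Fu's Fs needs n >= 2 and 1 <= K_obs <= n")
    if theta <= 0:
        raise UndefinedStatistic("Fu's Fs is undefined for theta <= 0")
    if K_obs == 1:
        return math.inf
    log_s = log_stirling_row(n)
    lth = math.log(theta)
    k = np.arange(n + 1)
    log_terms = log_s + k * lth
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    # S' and 1-S' from the same table, both in log space
    log_Sp = float(logsumexp(log_terms[K_obs:])) - log_rising
    log_1mSp = float(logsumexp(log_terms[1:K_obs])) - log_rising
    return log_Sp - log_1mSp


def diversity_summary(hset: HaplotypeSet, S: int | None = None) -> DiversitySummary:
    """Full per-sample summary; D and Fs are None where undefined."""
    from mitopop.haplotypes import site_summary

    n, K = hset.n, hset.K
    h = haplotype_diversity(hset)
    pi, kbar = nucleotide_diversity(hset)
    if S is None:
        S = site_summary(hset).S
    try:
        D = tajimas_d(n, S, kbar)
    except UndefinedStatistic:
        D = None
    try:
        Fs = fus_fs(n, K, kbar)
    except UndefinedStatistic:
        Fs = None
    return DiversitySummary(n=n, K=K, h=h, pi=pi, kbar=kbar, S=S, D=D, Fs=Fs)
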