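"""Exact probabilistic pairwise co-occurrence / co-exclusion testing.

Under the null that each of two taxa occupies its observed number of sites
uniformly at random and independently of the other, the number J of shared
sites is hypergeometric:

    P(J = j) = C(n_a, j) * C(N - n_a, n_b - j) / C(N, n_b)

A pair is *positive* (co-occurrence) when the inclusive upper tail
P(J >= j_obs) falls below the confidence level P0, *negative*
(co-exclusion) when the inclusive lower tail P(J <= j_obs) does, and
*random* otherwise.  Link strength is the order-of-magnitude gap
s = log10(P0 / P) between the assigned tail probability and P0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .community_data import CommunityMatrix

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"
SIGN_RANDOM = "random"


@dataclass(frozen=True)
class TestConfig:
    """Significance level P0 (default 0.01) and log base for link strength."""

    alpha: float = 0.01
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


@dataclass(frozen=True)
class PairTest:
    """Result of the exact test for one unordered taxon pair."""

    taxon_a: str
    taxon_b: str
    n_samples: int
    occ_a: int
    occ_b: int
    j_obs: int
    p_lt: float
    p_gt: float
    sign: str
    strength: float  # NaN when sign is random

    @property
    def significant(self) -> bool:
        return self.sign != SIGN_RANDOM


def cooccurrence_pmf(N: int, n_a: int, n_b: int, j: int) -> float:
    """P(J = j): hypergeometric probability of sharing exactly j of N sites.

    For moderate N the ratio of binomial coefficients is evaluated in exact
    integer arithmetic (the returned float is correctly rounded); very large
    N falls back to the log-space evaluation in scipy.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"need 0 <= n_a, n_b <= N, got N={N}, "
                         f"n_a={n_a}, n_b={n_b}")
    if j < max(0, n_a + n_b - N) or j > min(n_a, n_b):
        return 0.0
    if N <= 2000:
        from fractions import Fraction
        num = math.comb(n_a, j) * math.comb(N - n_a, n_b - j)
        return float(Fraction(num, math.comb(N, n_b)))
    return float(hypergeom.pmf(j, N, n_a, n_b))


def link_strength(P: float, cfg: TestConfig = TestConfig()) -> float:
    """s = log_base(P0 / P); positive iff P beats the confidence level."""
    if P < 0 or P > 1:
        raise ValueError(f"P must be a probability, got {P}")
    if P == 0:
        warnings.warn("tail probability underflowed to 0; capping strength",
                      stacklevel=2)
        P = np.finfo(float).tiny
    return float(np.log(cfg.alpha / P) / np.log(cfg.log_base))


def _classify(N: int, n_a: int, n_b: int, j_obs: int,
              cfg: TestConfig) -> tuple[float, float, str, float]:
    if n_a == 0 or n_b == 0:
        return 1.0, 1.0, SIGN_RANDOM, float("nan")
    # canonical argument order keeps the test exactly symmetric in (a, b)
    n_lo, n_hi = sorted((n_a, n_b))
    p_lt = float(hypergeom.cdf(j_obs, N, n_lo, n_hi))
    p_gt = float(hypergeom.sf(j_obs - 1, N, n_lo, n_hi))
    if p_gt < cfg.alpha:
        return p_lt, p_gt, SIGN_POSITIVE, link_strength(p_gt, cfg)
    if p_lt < cfg.alpha:
        return p_lt, p_gt, SIGN_NEGATIVE, link_strength(p_lt, cfg)
    return p_lt, p_gt, SIGN_RANDOM, float("nan")


def test_pair(presence_a, presence_b, cfg: TestConfig = TestConfig(), *,
              taxon_a: str = "a", taxon_b: str = "b") -> PairTest:
    """Exact test for two equal-length binary presence vectors."""
    a = np.asarray(presence_a).astype(bool)
    b = np.asarray(presence_b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("presence vectors must be 1-D and equal length")
    N = a.size
    n_a, n_b = int(a.sum()), int(b.sum())
    j_obs = int((a & b).sum())
    p_lt, p_gt, sign, s = _classify(N, n_a, n_b, j_obs, cfg)
    return PairTest(taxon_a=taxon_a, taxon_b=taxon_b, n_samples=N,
                    occ_a=n_a, occ_b=n_b, j_obs=j_obs,
                    p_lt=p_lt, p_gt=p_gt, sign=sign, strength=s)


def all_pairs(m: CommunityMatrix, cfg: TestConfig = TestConfig(), *,
              significant_only: bool = False) -> list[PairTest]:
    """Exact test for every unordered taxon pair of a (filtered) matrix.

    Pairs are emitted in lexicographic order of taxon ids.  The tail
    probabilities are computed vectorized over all pairs; with
    ``significant_only`` the random pairs are dropped (the confound and
    network stages only consume significant ones).
    """
    if m.n_taxa < 2:
        return []
    order = np.argsort(np.asarray(m.taxa, dtype=object))
    taxa = [m.taxa[i] for i in order]
    pres = m.presence[order].astype(np.int64)
    N = m.n_samples
    occ = pres.sum(axis=1)
    joint = pres @ pres.T

    ia, ib = np.triu_indices(len(taxa), k=1)
    n_a, n_b, j = occ[ia], occ[ib], joint[ia, ib]
    n_lo, n_hi = np.minimum(n_a, n_b), np.maximum(n_a, n_b)
    with np.errstate(divide="ignore"):
        p_lt = hypergeom.cdf(j, N, n_lo, n_hi)
        p_gt = hypergeom.sf(j - 1, N, n_lo, n_hi)
    degenerate = (n_a == 0) | (n_b == 0)
    p_lt = np.where(degenerate, 1.0, p_lt)
    p_gt = np.where(degenerate, 1.0, p_gt)
    pos = ~degenerate & (p_gt < cfg.alpha)
    neg = ~degenerate & ~pos & (p_lt < cfg.alpha)

    log_b = np.log(cfg.log_base)
    tiny = np.finfo(float).tiny
    tail = np.where(pos, p_gt, np.where(neg, p_lt, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        strength = np.log(cfg.alpha / np.maximum(tail, tiny)) / log_b
    strength = np.where(pos | neg, strength, np.nan)

    out: list[PairTest] = []
    for k in range(ia.size):
        if significant_only and not (pos[k] or neg[k]):
            continue
        sign = (SIGN_POSITIVE if pos[k]
                else SIGN_NEGATIVE if neg[k] else SIGN_RANDOM)
        out.append(PairTest(
            taxon_a=taxa[ia[k]], taxon_b=taxa[ib[k]], n_samples=N,
            occ_a=int(n_a[k]), occ_b=int(n_b[k]), j_obs=int(j[k]),
            p_lt=float(p_lt[k]), p_gt=float(p_gt[k]),
            sign=sign, strength=float(strength[k])))
    return out


def pair_table(tests: list[PairTest]) -> pd.DataFrame:
    """Pair tests as a tidy table (one row per pair)."""
    return pd.DataFrame(
        [{"taxon_a": t.taxon_a, "taxon_b": t.taxon_b, "N": t.n_samples,
          "n_a": t.occ_a, "n_b": t.occ_b, "j_obs": t.j_obs,
          "p_lt": t.p_lt, "p_gt": t.p_gt, "sign": t.sign,
          "strength": t.strength} for t in tests],
        columns=["taxon_a", "taxon_b", "N", "n_a", "n_b", "j_obs",
                 "p_lt", "p_gt", "sign", "strength"])


def write_pair_table(tests: list[PairTest], path) -> None:
    pair_table(tests).to_csv(path, sep="\t", index=False)
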