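"""Individuals-from-haplotypes estimation on a reference frequency distribution.

A reference sample of ``n`` individuals with haplotype counts ``n_i``
defines an individual-based accumulation curve of distinct haplotypes
(Hill number of order 0):

* interpolation (rarefaction), for ``m <= n``::

      H(m) = S_obs - sum_i C(n - n_i, m) / C(n, m)

* extrapolation beyond ``n`` via the Chao1 unseen-richness estimate
  ``f0 = ((n-1)/n) f1^2 / (2 f2)`` (or ``((n-1)/n) f1 (f1 - 1) / 2`` when
  ``f2 = 0``)::

      H(n + m*) = S_obs + f0 * (1 - (1 - f1 / (n f0 + f1))**m*)

Inverting the combined monotone curve maps an observed haplotype count to
an individual count; a percentile bootstrap (multinomial resampling of the
``n`` reference individuals) gives its interval. Nei's unbiased haplotype
diversity ``h = n/(n-1) (1 - sum (n_i/n)^2)`` summarises how close the
curve is to the identity line: at h near 1, almost every individual adds a
new haplotype and the haplotype count nearly equals the individual count.

Binomial coefficients are evaluated with log-gamma for numerical stability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ReferenceFreqs",
    "AbundanceEstimate",
    "OutOfRangeError",
    "haplotype_diversity",
    "rarefy",
    "chao1_unseen",
    "extrapolate",
    "expected_richness",
    "richness_curve",
    "estimate_individuals",
]


class OutOfRangeError(ValueError):
    """The observed haplotype count exceeds the curve's asymptote."""


@dataclass
class ReferenceFreqs:
    """Haplotype frequency counts ``n_i`` over a reference sample of
    ``n = sum(n_i)`` individuals."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.counts = self.counts[self.counts > 0]
        if len(self.counts) == 0:
            raise ValueError("reference frequency distribution is empty")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    def f(self, k: int) -> int:
        """Number of haplotypes observed exactly k times."""
        return int(np.count_nonzero(self.counts == k))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ReferenceFreqs":
        return cls(np.array(list(Counter(seqs).values())))

    @classmethod
    def from_tsv(cls, path) -> "ReferenceFreqs":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError("expected two columns: haplotype_id, count")
        return cls(df.iloc[:, 1].to_numpy())


@dataclass
class AbundanceEstimate:
    h_observed: int
    m_point: int
    m_low: float
    m_high: float
    n_bootstrap: int
    seed: Optional[int]


def haplotype_diversity(freqs: ReferenceFreqs) -> float:
    """Nei's unbiased haplotype diversity ``h = n/(n-1) (1 - sum p_i^2)``."""
    n = freqs.n
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 individuals")
    p = freqs.counts / n
    return n / (n - 1) * (1.0 - float(np.square(p).sum()))


def rarefy(freqs: ReferenceFreqs, m: int) -> float:
    """Expected distinct haplotypes among ``m <= n`` individuals drawn
    without replacement from the reference sample."""
    n = freqs.n
    if not 1 <= m <= n:
        raise ValueError(f"m must be in 1..{n}, got {m}")
    return _rarefy_raw(freqs.counts, n, m)


def _rarefy_raw(counts: np.ndarray, n: int, m: int) -> float:
    # S_obs - sum_i C(n - n_i, m) / C(n, m), via log-gamma
    rem = n - counts
    ok = rem >= m
    log_denom = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    r = rem[ok]
    log_num = gammaln(r + 1) - gammaln(m + 1) - gammaln(r - m + 1)
    missing = float(np.exp(log_num - log_denom).sum())
    return len(counts) - missing


def chao1_unseen(freqs: ReferenceFreqs) -> float:
    """Chao1 estimate of the number of unseen haplotypes, ``f0_hat``."""
    n, f1, f2 = freqs.n, freqs.f(1), freqs.f(2)
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def extrapolate(freqs: ReferenceFreqs, m_star: int) -> float:
    """Expected distinct haplotypes at sample size ``n + m_star``."""
    if m_star < 0:
        raise ValueError("m_star must be non-negative")
    s, f1 = freqs.s_obs, freqs.f(1)
    f0 = chao1_unseen(freqs)
    if f0 == 0.0 or m_star == 0:
        return float(s)
    rate = f1 / (freqs.n * f0 + f1)
    return s + f0 * (1.0 - (1.0 - rate) ** m_star)


def expected_richness(freqs: ReferenceFreqs, m: int) -> float:
    """Combined interpolation/extrapolation curve at integer ``m >= 1``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if m <= freqs.n:
        return rarefy(freqs, m)
    return extrapolate(freqs, m - freqs.n)


def richness_curve(
    freqs: ReferenceFreqs, m_max: int, step: int = 1
) -> pd.DataFrame:
    """The accumulation curve tabulated over ``m = 1..m_max``."""
    ms = np.arange(1, m_max + 1, step)
    return pd.DataFrame(
        {"m": ms, "h_hat": [expected_richness(freqs, int(m)) for m in ms]}
    )


def _invert(freqs: ReferenceFreqs, h: float) -> float:
    """Smallest integer m with H(m) >= h; inf if h exceeds the asymptote."""
    s = freqs.s_obs
    n = freqs.n
    tol = 1e-9 * max(1.0, abs(h))  # absorb log-gamma rounding
    if h <= 1.0:
        return 1
    if h <= s:
        lo, hi = 1, n  # H(hi) = S_obs >= h
        while lo < hi:
            mid = (lo + hi) // 2
            if _rarefy_raw(freqs.counts, n, mid) >= h - tol:
                hi = mid
            else:
                lo = mid + 1
        return lo
    f0 = chao1_unseen(freqs)
    if h >= s + f0:
        return np.inf
    f1 = freqs.f(1)
    rate = f1 / (n * f0 + f1)
    # solve s + f0 (1 - (1-rate)^m*) >= h
    m_star = np.log1p(-(h - s) / f0) / np.log1p(-rate)
    return n + int(np.ceil(m_star - tol))


def _bootstrap_assemblage(freqs: ReferenceFreqs) -> np.ndarray:
    """Coverage-adjusted assemblage probabilities for the bootstrap.

    Resampling the observed counts directly loses singletons, biasing every
    bootstrap curve downward. Instead, the assemblage is augmented with the
    Chao1-estimated unseen haplotypes: detected haplotypes get probabilities
    shrunk to the estimated sample coverage ``C_hat`` and the unseen ones
    share the remaining ``1 - C_hat`` (the Chao-Jost estimator used for
    rarefaction/extrapolation intervals).
    """
    n = freqs.n
    counts = freqs.counts
    f1, f2 = freqs.f(1), freqs.f(2)
    p = counts / n
    f0 = int(np.ceil(chao1_unseen(freqs)))
    if f1 == 0 or f0 == 0:
        return p
    a = (n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2)
    c_hat = 1.0 - f1 / n * a
    denom = float((p * (1.0 - p) ** n).sum())
    lam = (1.0 - c_hat) / denom if denom > 0 else 0.0
    p_adj = p * (1.0 - lam * (1.0 - p) ** n)
    p_unseen = np.full(f0, (1.0 - c_hat) / f0)
    return np.concatenate([p_adj, p_unseen])


def estimate_individuals(
    h_observed: int,
    freqs: ReferenceFreqs,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    z: float = 1.96,
) -> AbundanceEstimate:
    """Invert the accumulation curve at an observed haplotype count.

    The point estimate is the smallest integer ``m`` with ``H(m) >=
    h_observed``. The interval is the set of ``m`` whose 95% predictive
    band for the realized haplotype count contains ``h_observed``:
    ``H(m) +- z * s(m)`` with ``s(m)**2`` the sum of

    * the sampling variance of the distinct-haplotype count among ``m``
      individuals drawn from the coverage-adjusted assemblage (see
      :func:`_bootstrap_assemblage`), via the collision approximation
      ``Var ~= C(m, 2) * sum(p_i**2)`` valid for high-diversity pools, and
    * the reference-curve uncertainty, estimated as the centred variance of
      ``H_b(m_point)`` over ``n_bootstrap`` multinomial resamples of the
      ``n`` reference individuals from that assemblage.

    Raises :class:`OutOfRangeError` when ``h_observed`` exceeds the
    asymptote ``S_obs + f0_hat``.
    """
    if h_observed < 1:
        raise ValueError("h_observed must be >= 1")
    asymptote = freqs.s_obs + chao1_unseen(freqs)
    if h_observed >= asymptote and h_observed > freqs.s_obs:
        raise OutOfRangeError(
            f"h_observed={h_observed} exceeds the curve's asymptote "
            f"{asymptote:.1f}; a larger reference sample is needed"
        )
    h = float(h_observed)
    m_point = _invert(freqs, h)
    assert np.isfinite(m_point)

    rng = np.random.default_rng(seed)
    p_aug = _bootstrap_assemblage(freqs)
    curve_boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boot = ReferenceFreqs(rng.multinomial(freqs.n, p_aug))
        curve_boot[b] = expected_richness(boot, int(min(m_point, boot.n)))
    var_curve = float(curve_boot.var(ddof=1)) if n_bootstrap > 1 else 0.0
    sum_p2 = float(np.square(p_aug).sum())

    def sd(m: int) -> float:
        return float(np.sqrt(m * (m - 1) / 2.0 * sum_p2 + var_curve))

    def upper_band(m: int) -> float:  # H(m) + z*s(m), increasing in m
        return expected_richness(freqs, m) + z * sd(m)

    def lower_band(m: int) -> float:  # H(m) - z*s(m)
        return expected_richness(freqs, m) - z * sd(m)

    # m_low: smallest m whose upper band reaches h
    lo, hi = 1, int(m_point)
    while lo < hi:
        mid = (lo + hi) // 2
        if upper_band(mid) >= h:
            hi = mid
        else:
            lo = mid + 1
    m_low = lo

    # m_high: largest m whose lower band is still at or below h
    # (exponential bracket, then bisection for the first crossing)
    cap = max(100 * freqs.n, 10 * int(m_point))
    lo2, hi2 = int(m_point), int(m_point) + 1
    while hi2 < cap and lower_band(hi2) <= h:
        lo2, hi2 = hi2, min(hi2 * 2, cap)
    if lower_band(min(hi2, cap)) <= h:
        m_high = float("inf")
    else:
        while lo2 + 1 < hi2:
            mid = (lo2 + hi2) // 2
            if lower_band(mid) <= h:
                lo2 = mid
            else:
                hi2 = mid
        m_high = float(lo2)

    m_low = min(m_low, m_point)
    m_high = max(m_high, m_point)
    return AbundanceEstimate(
        h_observed, int(m_point), float(m_low), float(m_high), n_bootstrap, seed
    )
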