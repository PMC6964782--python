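"""Nonparametric statistics for the inter-unit variability analysis.

Two tools, both assumption-free:

* an exact Wilcoxon signed-rank test (full enumeration of the 2^n sign
  assignments for small n, tie- and continuity-corrected normal
  approximation otherwise), used to compare uncorrected detector output
  factors with the corrected field output factors;
* a distribution-free confidence interval for the median built from order
  statistics of the binomial(n, 1/2) distribution, used for the per-field
  size summary tables. A percentile-bootstrap alternative is available
  behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import EmptySampleError, SampleTooSmallError, ValidationError

EXACT_N_MAX = 20  # 2^20 sign assignments is the largest we enumerate


@dataclass(frozen=True)
class PairedSample:
    """Paired (uncorrected, corrected) values keyed by e.g. (institution, side)."""

    keys: tuple
    uncorrected: np.ndarray
    corrected: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.uncorrected, dtype=float)
        c = np.asarray(self.corrected, dtype=float)
        k = tuple(self.keys)
        object.__setattr__(self, "uncorrected", u)
        object.__setattr__(self, "corrected", c)
        object.__setattr__(self, "keys", k)
        if not (len(k) == u.size == c.size):
            raise ValidationError("keys/uncorrected/corrected: unequal lengths")
        if len(set(k)) != len(k):
            raise ValidationError("keys: must be unique")

    @property
    def differences(self) -> np.ndarray:
        return self.uncorrected - self.corrected


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    w_plus: float
    w_minus: float
    n: int  # pairs remaining after zero-difference removal
    p_value: float
    method: str  # 'exact' or 'normal_approx'


@lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign assignments as a (2^n, n) 0/1 matrix."""
    bits = np.arange(2**n, dtype=np.uint32)
    return (bits[:, None] >> np.arange(n, dtype=np.uint32)) & 1


def wilcoxon_signed_rank(
    sample: PairedSample | Sequence[float],
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment, matching common statistical-software defaults); tied
    absolute differences receive mid-ranks. The statistic is
    W = min(W+, W-). The exact p-value enumerates all 2^n sign
    assignments (mid-ranks make this valid under ties as well) and doubles
    the smaller tail of W+, capped at 1. ``mode='auto'`` enumerates for
    n <= 20 and falls back to the tie- and continuity-corrected normal
    approximation above that.
    """
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(sample, PairedSample):
        d = sample.differences
    else:
        d = np.asarray(sample, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise EmptySampleError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX):
        signs = _sign_matrix(n)
        all_w_plus = signs @ ranks  # W+ under every sign assignment
        m = float(all_w_plus.size)
        p_low = np.count_nonzero(all_w_plus <= w_plus + 1e-9) / m
        p_high = np.count_nonzero(all_w_plus >= w_plus - 1e-9) / m
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(w, w_plus, w_minus, n, p, "exact")

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        raise EmptySampleError("zero variance after tie correction")
    z = (w - mu + 0.5) / sigma  # continuity correction toward the mean
    p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
    return WilcoxonResult(w, w_plus, w_minus, n, p, "normal_approx")


@dataclass(frozen=True)
class MedianCI:
    median: float
    low: float
    high: float
    level: float
    achieved_coverage: float
    rank: int | None  # r of the (r, n+1-r) order-statistic pair; None for bootstrap
    method: str


def median_ci(
    values: Sequence[float],
    level: float = 0.95,
    method: str = "order",
    n_boot: int = 2000,
    seed: int = 0,
) -> MedianCI:
    """Confidence interval for the median.

    ``method='order'`` (default) is the distribution-free order-statistic
    interval: the innermost symmetric pair of order statistics
    (x_(r), x_(n+1-r)) whose binomial(n, 1/2) coverage
    1 - 2 P(X <= r-1) still reaches ``level``. The achieved (conservative)
    coverage is reported. ``method='bootstrap'`` is a seeded percentile
    bootstrap of the sample median.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    med = float(np.median(x))
    if method == "bootstrap":
        if n < 2:
            raise SampleTooSmallError("bootstrap CI needs n >= 2")
        rng = np.random.default_rng(seed)
        meds = np.median(rng.choice(x, size=(n_boot, n), replace=True), axis=1)
        lo, hi = np.quantile(meds, [(1 - level) / 2, (1 + level) / 2])
        return MedianCI(med, float(lo), float(hi), level, level, None, "bootstrap")
    if method != "order":
        raise ValueError(f"unknown method {method!r}")

    best_r = None
    for r in range(n // 2, 0, -1):  # innermost pair first
        coverage = 1.0 - 2.0 * float(sps.binom.cdf(r - 1, n, 0.5))
        if coverage >= level:
            best_r = (r, coverage)
            break
    if best_r is None:
        raise SampleTooSmallError(
            f"n={n} cannot reach {level:.0%} coverage with order statistics"
        )
    r, coverage = best_r
    return MedianCI(med, float(x[r - 1]), float(x[n - r]), level, coverage, r, "order")
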