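"""Two-sample tests and summary statistics.

The cohort comparisons use three tests: two-sample Kolmogorov–Smirnov for
distributional differences (filament counts, nearest-neighbour
distances), two-sample t for mean lengths, and Wilcoxon rank-sum for the
proximity/stretch contrasts.  Sample sizes are tiny (5 and 6 sites), so
exact small-sample computations are provided alongside the asymptotic
conventions; both are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ValidationError

__all__ = [
    "TestResult",
    "ks_two_sample",
    "t_two_sample",
    "wilcoxon_rank_sum",
    "summarize",
    "SummaryStats",
]


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    exact: bool

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n1": self.n1,
            "n2": self.n2,
            "exact": self.exact,
        }


def _check(x, y, min_n: int = 1):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < min_n or y.size < min_n:
        raise ValidationError(f"both samples need >= {min_n} observations")
    return x, y


def _ks_asymptotic_p(d: float, n1: int, n2: int) -> float:
    # Kolmogorov tail with Stephens' finite-sample correction of the
    # effective sample size (the convention behind Matlab's kstest2).
    ne = n1 * n2 / (n1 + n2)
    lam = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
    j = np.arange(1, 101)
    p = 2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * j**2 * lam**2))
    return float(np.clip(p, 0.0, 1.0))


def ks_two_sample(x, y, mode: str = "auto") -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_x − ECDF_y|.  ``mode="exact"`` enumerates the exact
    null distribution (valid without ties; a warning is issued when ties
    are present), ``"asymptotic"`` uses the Kolmogorov tail with the
    finite-sample effective-size correction, ``"auto"`` picks exact when
    n1·n2 <= 10^4.
    """
    x, y = _check(x, y, 1)
    n1, n2 = x.size, y.size
    if mode == "auto":
        mode = "exact" if n1 * n2 <= 10_000 else "asymptotic"
    d = float(sps.ks_2samp(x, y, method="asymp").statistic)
    if mode == "exact":
        if np.intersect1d(x, y).size:
            warnings.warn(
                "ties between samples: exact KS p-value is approximate", stacklevel=2
            )
        p = float(sps.ks_2samp(x, y, method="exact").pvalue)
        exact = True
    elif mode == "asymptotic":
        p = _ks_asymptotic_p(d, n1, n2)
        exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult("ks_two_sample", d, p, n1, n2, exact)


def t_two_sample(x, y, equal_var: bool = True) -> TestResult:
    """Two-sample t test (pooled variance by default; Welch optional)."""
    x, y = _check(x, y, 2)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        # zero pooled variance with equal means: no evidence either way
        return TestResult("t_two_sample", 0.0, 1.0, x.size, y.size, False)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValidationError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(
        "t_two_sample", float(res.statistic), float(res.pvalue), x.size, y.size, False
    )


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test with midrank ties.

    ``mode="exact"`` enumerates the exact null (requires no ties);
    ``"asymptotic"`` is the normal approximation with tie correction and
    *no* continuity correction, so identical samples give p = 1 exactly.
    ``"auto"``: exact when min(n1, n2) <= 10 and there are no ties.
    The statistic reported is the Mann–Whitney U of the first sample.
    """
    x, y = _check(x, y, 1)
    n1, n2 = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if mode == "auto":
        mode = "exact" if (min(n1, n2) <= 10 and not has_ties) else "asymptotic"
    if mode == "exact":
        if has_ties:
            raise ValidationError("exact rank-sum enumeration requires tie-free data")
        res = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        return TestResult(
            "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), n1, n2, True
        )
    if mode != "asymptotic":
        raise ValueError(f"unknown mode {mode!r}")
    u = float(
        sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided").statistic
    )
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult("wilcoxon_rank_sum", u, 1.0, n1, n2, False)
    z = (u - mu) / np.sqrt(var)
    p = float(np.clip(2.0 * sps.norm.sf(abs(z)), 0.0, 1.0))
    return TestResult("wilcoxon_rank_sum", u, p, n1, n2, False)


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float  # sample SD (n-1); NaN when n < 2
    min: float
    max: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": float(self.mean),
            "sd": float(self.sd),
            "min": float(self.min),
            "max": float(self.max),
        }


def summarize(values) -> SummaryStats:
    """Mean ± sample SD plus range; SD is NaN (flagged) for n = 1."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return SummaryStats(int(x.size), float(x.mean()), sd, float(x.min()), float(x.max()))
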