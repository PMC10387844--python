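"""Two-sample tests for small replicate groups.

Spectroscopy comparisons here involve very small groups (typically n = 3 per
condition), where the asymptotic Mann-Whitney approximation is unreliable.
The exact test is therefore computed by full enumeration of all
C(n1+n2, n1) group labelings of the pooled ranks whenever the pooled sample
is tie-free and small; ties or larger samples fall back to the normal
approximation with midranks, tie-corrected variance and continuity
correction, and the result is flagged accordingly.

Note that with n = 3 vs 3 the smallest attainable exact two-sided p is
2/C(6,3) = 0.1, so exact significance below 0.1 is impossible at that size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

EXACT_THRESHOLD = 12  # max pooled size for full enumeration


@dataclass
class Summary:
    mean: float
    sd: float  # sample SD (n-1 denominator); NaN for n = 1
    n: int


@dataclass
class TestResult:
    test: str  # mann_whitney_exact | mann_whitney_normal | t_unpaired
    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    note: Optional[str] = None


def summarize(sample: Sequence[float]) -> Summary:
    """Mean and sample standard deviation (n-1 denominator)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValidationError("empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return Summary(mean=float(x.mean()), sd=sd, n=int(x.size))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """U1 from midranks of the pooled sample; second value flags ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    return float(u1), has_ties


def _exact_p(ranks_x_sum: float, n1: int, n2: int) -> float:
    """Two-sided exact p by enumerating every labeling of ranks 1..n1+n2.

    p = P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) under the permutation null.
    Only valid for tie-free pooled samples (integer ranks).
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    u_obs = ranks_x_sum - n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mu)
    count = 0
    for labeling in combinations(range(1, n + 1), n1):
        u = sum(labeling) - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
    return count / comb(n, n1)


def _normal_approx_p(u1: float, n1: int, n2: int,
                     pooled: np.ndarray) -> float:
    """Normal approximation with tie-corrected variance and continuity corr."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # complete ties: no evidence either way
        return 1.0
    diff = u1 - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   mode: str = "auto",
                   exact_threshold: int = EXACT_THRESHOLD) -> TestResult:
    """Two-sided Mann-Whitney U test.

    mode='auto' uses full enumeration when the pooled sample is tie-free and
    has at most ``exact_threshold`` observations, otherwise the tie-corrected
    normal approximation. mode='exact' insists on enumeration (error on
    ties); mode='normal' always approximates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    u1, has_ties = _u_statistic(x, y)
    n1, n2 = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])

    use_exact = (mode == "exact") or (
        mode == "auto" and not has_ties and n1 + n2 <= exact_threshold)
    if use_exact:
        if has_ties:
            if mode == "exact":
                raise ValidationError(
                    "exact enumeration requires a tie-free pooled sample")
            use_exact = False
        elif n1 + n2 > exact_threshold and mode != "exact":
            use_exact = False
    if use_exact:
        ranks_x_sum = u1 + n1 * (n1 + 1) / 2.0
        p = _exact_p(ranks_x_sum, n1, n2)
        return TestResult("mann_whitney_exact", u1, p, n1, n2)
    note = "ties present; midranks + normal approximation" if has_ties else None
    p = _normal_approx_p(u1, n1, n2, pooled)
    return TestResult("mann_whitney_normal", u1, p, n1, n2, note=note)


def t_test_unpaired(x: Sequence[float], y: Sequence[float],
                    equal_var: bool = True) -> TestResult:
    """Classical unpaired two-sided t-test (pooled variance by default).

    At n = 3 vs 3 the pooled-variance Student test is exactly calibrated
    under normality, whereas the Welch variant (``equal_var=False``,
    Welch-Satterthwaite df) is markedly conservative at such sizes; Welch
    remains available for clearly heteroscedastic groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t-test needs at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult("t_unpaired", 0.0, 1.0, x.size, y.size,
                              note="zero variance in both groups")
        return TestResult("t_unpaired", float("inf"), 0.0, x.size, y.size,
                          note="degenerate: zero variance, unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return TestResult("t_unpaired", float(t), float(p), int(x.size),
                      int(y.size),
                      note=None if equal_var else "Welch (unequal variances)")
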