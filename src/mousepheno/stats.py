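"""Nonparametric group comparisons: Mann-Whitney U, Kruskal-Wallis H,
Spearman rank correlation, with Bonferroni correction for declared
comparison families.

All tests are two-tailed at alpha = 0.05.  U is reported as min(U1, U2)
(conventional small-U reporting); exact p-values are used for small
samples without ties (full enumeration for U when n1 + n2 <= 16, all
permutations for Spearman when n <= 7), otherwise the tie-corrected
normal/t approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "kruskal_wallis_h",
    "spearman_rho",
    "bonferroni",
]

EXACT_U_MAX_N = 16
EXACT_RHO_MAX_N = 7


@dataclass
class ComparisonResult:
    """One statistical comparison, optionally Bonferroni-adjusted."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    adjusted_p: Optional[float] = None
    family_size: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
        }
        if self.adjusted_p is not None:
            d["adjusted_p"] = self.adjusted_p
            d["family_size"] = self.family_size
        d.update(self.extra)
        return d


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_if_small: bool = True,
) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test.

    The statistic is min(U1, U2) from midrank sums.  The p-value is exact
    (full enumeration) when ``n1 + n2 <= 16`` with no ties, else the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    small = exact_if_small and len(pooled) <= EXACT_U_MAX_N and not _has_ties(pooled)
    method = "exact" if small else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = len(a) * len(b) - u1
    return ComparisonResult(
        test="mann_whitney_u",
        statistic=min(u1, u2),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        extra={"method": method},
    )


def kruskal_wallis_h(groups: Sequence[Sequence[float]]) -> ComparisonResult:
    """Two-tailed Kruskal-Wallis H test across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) == 0 for g in arrays):
        raise ValueError("need at least two non-empty groups")
    if all(np.array_equal(arrays[0], g) for g in arrays[1:]):
        # identical groups: H = 0 by construction, but scipy rejects the
        # all-ties case outright
        return ComparisonResult(
            test="kruskal_wallis_h", statistic=0.0, p_value=1.0,
            n=tuple(len(g) for g in arrays),
        )
    res = sps.kruskal(*arrays)
    return ComparisonResult(
        test="kruskal_wallis_h",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=tuple(len(g) for g in arrays),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-tailed exact p for |rho| by enumerating all rank permutations."""
    rx = sps.rankdata(x)
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(sps.rankdata(y)):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Spearman rank correlation with a two-tailed p-value.

    Exact enumeration over all n! rank orderings for n <= 7, otherwise the
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if len(x) <= EXACT_RHO_MAX_N:
        p = _exact_spearman_p(x, y, rho)
        method = "exact"
    else:
        p, method = float(p_t), "t-approximation"
    return ComparisonResult(
        test="spearman_rho", statistic=rho, p_value=p, n=(len(x),),
        extra={"method": method},
    )


def bonferroni(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Apply Bonferroni correction across one comparison family (in place).

    adjusted_p = min(1, m * p) with m the family size; never decreases p.
    """
    m = len(results)
    for r in results:
        r.adjusted_p = min(1.0, m * r.p_value)
        r.family_size = m
    return list(results)
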