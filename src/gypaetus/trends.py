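"""Monotone-trend testing for annual breeding series.

Productivity is the number of chicks fledged divided by the number of
breeding pairs in a year; its association with calendar year (and that
of the pair count itself) is measured by Spearman's rank correlation.
Significance comes from permutation inference — exact enumeration for
short series, seeded Monte Carlo with the add-one rule otherwise — so
no distributional assumption is needed. The classic t approximation is
available for comparison. A caveat applies to all three: the series are
temporal and the permutation null ignores autocorrelation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encounter import DataError
from .simulate import TrendSeries

__all__ = [
    "TrendTestResult",
    "productivity",
    "spearman_rho",
    "spearman_test",
]

_EXACT_LIMIT = 8


@dataclass(frozen=True)
class TrendTestResult:
    rho: float
    p_value: float
    n: int
    method: str  # exact | monte_carlo_permutation | t_approximation

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def productivity(
    years, chicks_fledged, pairs
) -> TrendSeries:
    """Chicks fledged per breeding pair, year by year."""
    years = [int(y) for y in years]
    chicks = [float(c) for c in chicks_fledged]
    prs = [float(p) for p in pairs]
    if not (len(years) == len(chicks) == len(prs)):
        raise DataError("years, chicks and pairs must have equal length")
    for y, p in zip(years, prs):
        if p <= 0:
            raise DataError(f"year {y}: pair count must be positive, got {p}")
    return TrendSeries(tuple(years), tuple(c / p for c, p in zip(chicks, prs)))


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise DataError("constant series: Spearman's rho is undefined")
    return float(rx @ ry) / denom


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with midranks for ties.

    Pearson correlation of the average-ranked values; exactly +/-1 for
    perfectly monotone tie-free input. The midrank form remains valid
    under ties, unlike the 6*sum(d^2) shortcut.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise DataError("need at least 3 points")
    return _rank_corr(_ranks(x), _ranks(y))


def spearman_test(
    x,
    y,
    method: str = "monte_carlo_permutation",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> TrendTestResult:
    """Two-sided permutation test of Spearman association.

    ``exact`` enumerates all n! permutations of y (n <= 8 only);
    ``monte_carlo_permutation`` draws ``n_permutations`` seeded random
    permutations and applies the add-one rule (b+1)/(m+1), which cannot
    return zero; ``t_approximation`` uses the classic
    t = rho*sqrt((n-2)/(1-rho^2)) reference distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx, ry = _ranks(x), _ranks(y)
    rho = _rank_corr(rx, ry)
    tol = 1e-12

    if method == "exact":
        if n > _EXACT_LIMIT:
            raise DataError(
                f"exact enumeration of {n}! permutations refused; use "
                "monte_carlo_permutation"
            )
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - tol:
                count += 1
        return TrendTestResult(rho, count / total, n, "exact")

    if method == "monte_carlo_permutation":
        rng = np.random.default_rng(seed)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        perms = rng.permuted(
            np.broadcast_to(ryc, (n_permutations, n)).copy(), axis=1
        )
        r_perm = perms @ rxc / denom
        b = int(np.sum(np.abs(r_perm) >= abs(rho) - tol))
        return TrendTestResult(
            rho, (b + 1) / (n_permutations + 1), n, "monte_carlo_permutation"
        )

    if method == "t_approximation":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return TrendTestResult(rho, min(p, 1.0), n, "t_approximation")

    raise ValueError(f"unknown method {method!r}")


def trend_test(series: TrendSeries, **kwargs) -> TrendTestResult:
    """Spearman test of a series against its own calendar years."""
    return spearman_test(series.years, series.values, **kwargs)
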