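"""Statistical kernels shared by the enrichment and burden tests.

The case-only test compares an observed per-gene de novo mutation (DNM) count
to a model-based expectation under a Poisson law: p = P(X >= observed) for
X ~ Poisson(expected), i.e. the upper tail starting at the observed count.
Evidence across variant classes and cohorts is merged with Fisher's combined
probability test (-2 * sum(ln p) ~ chi-square with 2k df).  Case-control
burden uses one-sided Fisher exact tests on carrier 2x2 tables, with a
Haldane-Anscombe 0.5 correction for odds ratios when a cell is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

#: floor applied to p-values before log transforms
P_FLOOR = 1e-300
#: exome-wide significance threshold for ~20,000 genes (0.05 / 20,000)
BONFERRONI_ALPHA = 2.5e-6
DEFAULT_TEST_UNIVERSE = 20_000


def poisson_case_only(observed: int, expected: float) -> float:
    """Upper-tail Poisson probability P(X >= observed) with mean ``expected``.

    observed = 0 returns 1 by convention (the empty tail).  A positive
    observation against a zero expectation is impossible under the model and
    is clamped to the p-value floor rather than returned as an exact zero.
    """
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be non-negative")
    if observed != int(observed):
        raise ValueError("observed must be an integer count")
    observed = int(observed)
    if observed == 0:
        return 1.0
    if expected == 0:
        return P_FLOOR
    return max(float(sps.poisson.sf(observed - 1, expected)), P_FLOOR)


def fisher_combined(p_values: Sequence[float]) -> float:
    """Fisher's combined probability over k independent p-values (2k df)."""
    if len(p_values) == 0:
        raise ValueError("need at least one p-value")
    ps = np.asarray(p_values, dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        if np.any(ps < 0) or np.any(ps > 1):
            raise ValueError("p-values must lie in (0, 1]")
        ps = np.clip(ps, P_FLOOR, 1.0)
    if len(ps) == 1:
        return float(ps[0])
    x = -2.0 * float(np.sum(np.log(ps)))
    return max(float(sps.chi2.sf(x, 2 * len(ps))), P_FLOOR)


@dataclass(frozen=True)
class BurdenTable2x2:
    """Carrier counts: a/b case carriers/non-carriers, c/d control ditto."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d


def fold_change(x_case: int, n_case: int, x_ctrl: int, n_ctrl: int) -> float:
    """Ratio of case to control carrier fractions; +inf when controls are empty."""
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("cohort sizes must be positive")
    if x_case > n_case or x_ctrl > n_ctrl:
        raise ValueError("carrier count exceeds cohort size")
    if x_ctrl == 0:
        return math.inf if x_case > 0 else math.nan
    return (x_case / n_case) / (x_ctrl / n_ctrl)


def fisher_exact_onesided(table: BurdenTable2x2) -> float:
    """One-sided (case-enrichment) Fisher exact p-value."""
    _, p = sps.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="greater")
    return float(p)


def odds_ratio_corrected(table: BurdenTable2x2) -> float:
    """Cross-product odds ratio; Haldane-Anscombe 0.5 added iff a cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def bonferroni(p_values: Iterable[float], m: int = DEFAULT_TEST_UNIVERSE) -> np.ndarray:
    ps = np.asarray(list(p_values), dtype=float)
    if m < len(ps):
        raise ValueError(f"test universe m={m} smaller than number of tests {len(ps)}")
    return np.minimum(ps * m, 1.0)


def bh_fdr(p_values: Iterable[float], m: int = DEFAULT_TEST_UNIVERSE) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over a declared universe of m tests.

    Tests absent from ``p_values`` are treated as p = 1 (they occupy the top
    ranks and never change the q-values of the supplied tests).
    """
    ps = np.asarray(list(p_values), dtype=float)
    if m < len(ps):
        raise ValueError(f"test universe m={m} smaller than number of tests {len(ps)}")
    order = np.argsort(ps, kind="stable")
    ranked = ps[order]
    q = ranked * m / np.arange(1, len(ps) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def correct_multiple(p_values: Sequence[float], method: str = "bh",
                     m: int = DEFAULT_TEST_UNIVERSE) -> np.ndarray:
    if method == "bonferroni":
        return bonferroni(p_values, m)
    if method == "bh":
        return bh_fdr(p_values, m)
    raise ValueError(f"unknown correction method {method!r}")
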