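"""Generic test statistics implemented from first principles.

Every inferential number the pipeline reports flows through one of the
three procedures here — Spearman rank correlation, chi-square tests, and
one-way ANOVA on a binary indicator — implemented directly from their
defining formulas so results are auditable end to end. Tail probabilities
come from the standard t, chi-square and F distributions via
``scipy.special``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "TestResult",
    "midranks",
    "spearman",
    "chi2_gof",
    "chi2_2x2",
    "anova_binary",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical test.

    ``df`` is an int for one-parameter statistics (rho's t approximation,
    chi-square) and a ``(df_between, df_within)`` pair for the F test.
    ``computable`` is False when the statistic is undefined for the input
    (e.g. a rank correlation of a constant vector); then ``statistic`` and
    ``p_value`` are NaN.
    """

    name: str
    statistic: float
    df: int | tuple[int, int]
    p_value: float
    n: int
    computable: bool = True
    note: str = ""


def _not_computable(name: str, n: int, note: str) -> TestResult:
    return TestResult(name, float("nan"), 0, float("nan"), n, computable=False, note=note)


def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average (mid) rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


def spearman(x, y, *, exact: bool | None = None) -> TestResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    The p-value uses the large-sample t approximation
    ``t = rho * sqrt((n-2) / (1-rho**2))`` on n-2 df. For n <= 10 an exact
    two-sided permutation p-value over all n! rank orders is available
    (``exact=True``; the default picks the approximation unless asked).
    Degenerate input (all values tied in either vector, or n < 3) yields a
    not-computable result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        return _not_computable("spearman", n, "need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _not_computable("spearman", n, "constant vector: ranks degenerate")
    rx, ry = midranks(x), midranks(y)
    rho = _pearson(rx, ry)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        observed = abs(rho)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.array(perm))
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        return TestResult("spearman", rho, n - 2, count / total, n, note="exact permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        # two-sided tail of Student's t with n-2 df
        p = 2.0 * special.stdtr(n - 2, -abs(t))
    return TestResult("spearman", rho, n - 2, p, n)


def chi2_gof(observed, expected_proportions) -> TestResult:
    """Goodness-of-fit chi-square: sum (O-E)^2 / E on k-1 df.

    ``expected_proportions`` must be positive and sum to 1; expected counts
    are ``N * proportion``.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape or obs.ndim != 1:
        raise ValueError("observed and expected_proportions must match in length")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if np.any(props <= 0):
        raise ValueError("expected proportions must be positive")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    total = obs.sum()
    if total == 0:
        raise ValueError("no observations")
    expected = total * props
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return TestResult("chi2_gof", stat, df, float(special.chdtrc(df, stat)), int(total))


def chi2_2x2(table) -> TestResult:
    """Pearson chi-square of independence on a 2x2 table, 1 df, no
    continuity correction.

    A warning note is attached when any expected cell is below 1; a zero
    row or column margin makes the statistic undefined (not computable).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return _not_computable("chi2_2x2", int(n), "zero margin")
    expected = np.outer(rows, cols) / n
    stat = float((((t - expected) ** 2) / expected).sum())
    note = "expected cell < 1" if np.any(expected < 1) else ""
    return TestResult("chi2_2x2", stat, 1, float(special.chdtrc(1, stat)), int(n), note=note)


def anova_binary(indicator, groups) -> TestResult:
    """One-way ANOVA F test applied to a 0/1 indicator.

    ``indicator`` holds the per-record binary outcome (e.g. risk allele is
    minor), ``groups`` the per-record group label. F = between-group mean
    square / within-group mean square with df (k-1, N-k); singleton groups
    contribute no within-group df but stay in the between-group sums.
    """
    y = np.asarray(indicator, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("indicator and groups must be 1-D and equally long")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("indicator must be binary 0/1")
    labels, inverse = np.unique(g, return_inverse=True)
    k = len(labels)
    n = len(y)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inverse, minlength=k).astype(float)
    if n - k <= 0:
        raise ValueError("no within-group degrees of freedom (all groups size 1)")
    grand = y.mean()
    means = np.bincount(inverse, weights=y, minlength=k) / sizes
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((y - means[inverse]) ** 2).sum())
    df_between, df_within = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult("anova_binary", 0.0, (df_between, df_within), 1.0, n)
        return _not_computable("anova_binary", n, "zero within-group variance")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(special.fdtrc(df_between, df_within, f))
    return TestResult("anova_binary", f, (df_between, df_within), p, n)
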