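"""Phenotype-level statistics: Yates-corrected chi-square and Student's t-test.

The chi-square on a 2x2 survival table uses Yates' continuity correction in
its clamped form, chi2 = sum(max(|O - E| - 0.5, 0)^2 / E), with expected
counts from the row/column margins and an upper-tail p-value on 1 degree of
freedom. The t-test is the classic equal-variance two-sample (pooled) test
with df = n_a + n_b - 2 (Welch available behind a flag); significance stars
follow the usual thresholds (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ContingencyTable2x2:
    """Survived/died counts for two groups."""

    groups: tuple[str, str]
    survived: tuple[int, int]
    died: tuple[int, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in (*self.survived, *self.died)):
            raise ValueError("counts must be non-negative")
        if any(s + d == 0 for s, d in zip(self.survived, self.died)):
            raise ValueError("each group needs at least one observation")

    @property
    def observed(self) -> np.ndarray:
        return np.array([self.survived, self.died], dtype=float).T  # rows = groups


@dataclass
class ChiSquareResult:
    chi2: float
    p: float
    df: int = 1


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    stars: str
    degenerate: bool = False


def chi_square_yates(table: ContingencyTable2x2) -> ChiSquareResult:
    """Yates-corrected chi-square on a 2x2 table (clamped correction)."""
    obs = table.observed
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined: a margin is zero")
    expected = np.outer(row, col) / total
    dev = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return ChiSquareResult(chi2=chi2, p=p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def students_t_test(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test (pooled variance by default; Welch with equal_var=False)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if equal_var and pooled == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=na + nb - 2, p=1.0, stars="ns")
        tiny = np.nextafter(0, 1)
        return TTestResult(
            t=float(np.sign(a.mean() - b.mean()) * np.inf),
            df=na + nb - 2,
            p=tiny,
            stars="***",
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = na + nb - 2 if equal_var else float(res.df)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p, stars=significance_stars(p))


def survival_table_from_rates(
    groups: tuple[str, str], n: tuple[int, int], rates: tuple[float, float]
) -> ContingencyTable2x2:
    """Reconstruct survivor counts as round(rate * n) from printed survival rates."""
    survived = tuple(int(round(r * k)) for r, k in zip(rates, n))
    died = tuple(k - s for k, s in zip(n, survived))
    return ContingencyTable2x2(groups=groups, survived=survived, died=died)
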