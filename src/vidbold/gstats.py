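"""Shared group-level statistics: FDR/Bonferroni, t-tests, binomial tests,
ANOVA with Tukey HSD.  Thin, explicit wrappers so every analysis applies
the same conventions (add-one-free exact tests, explicit comparison
counts, pure functions)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p: float
    significant: bool
    correction: str = "none"


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value array")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def bonferroni(pvals: np.ndarray, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if m is None:
        m = pvals.size
    return pvals * m < alpha


def group_ttest(
    values: np.ndarray, mu0: float = 0.0, sides: str = "two", alpha: float = 0.05
) -> TestResult:
    """One-sample t-test of per-subject values against ``mu0``.

    ``sides`` is 'two', 'greater' or 'less'.  Degenerate zero-variance input
    equal to mu0 gives t = 0, p = 1; shifted constant input gives an
    infinite t handled as p -> 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValueError("need >= 2 finite values")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sides]
    if np.allclose(values, values[0]):
        if np.isclose(values[0], mu0):
            t, p = 0.0, 1.0
        else:
            sign = np.sign(values[0] - mu0)
            t = float(np.inf * sign)
            if alternative == "two-sided":
                p = 0.0
            elif alternative == "greater":
                p = 0.0 if sign > 0 else 1.0
            else:
                p = 0.0 if sign < 0 else 1.0
    else:
        res = stats.ttest_1samp(values, mu0, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    return TestResult(statistic=t, p=p, significant=p < alpha)


def binomial_fraction_test(
    k: int, n: int, p0: float, side: str = "greater", alpha: float = 0.05
) -> TestResult:
    """Exact binomial tail probability for k successes out of n."""
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    alternative = {"greater": "greater", "less": "less", "two": "two-sided"}[side]
    res = stats.binomtest(k, n, p0, alternative=alternative)
    return TestResult(statistic=float(k), p=float(res.pvalue), significant=res.pvalue < alpha)


def anova_tukey(
    groups: np.ndarray, group_names: list[str] | None = None, alpha: float = 0.05
) -> tuple[TestResult, pd.DataFrame]:
    """Balanced one-way ANOVA (columns = groups) with Tukey HSD pairs.

    Identical groups give F = 0, p = 1.  Returns the omnibus result plus
    a pairwise table at family-wise error rate ``alpha``.
    """
    groups = np.asarray(groups, dtype=float)
    if groups.ndim != 2 or groups.shape[1] < 2:
        raise ValueError("need a (subjects x >=2 groups) array")
    cols = [groups[:, j] for j in range(groups.shape[1])]
    if group_names is None:
        group_names = [f"g{j}" for j in range(len(cols))]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        omnibus = TestResult(statistic=0.0, p=1.0, significant=False)
        pairs = pd.DataFrame(
            [
                {"a": group_names[a], "b": group_names[b], "p": 1.0, "significant": False}
                for a in range(len(cols))
                for b in range(a + 1, len(cols))
            ]
        )
        return omnibus, pairs
    f_stat, p = stats.f_oneway(*cols)
    omnibus = TestResult(statistic=float(f_stat), p=float(p), significant=p < alpha)
    hsd = stats.tukey_hsd(*cols)
    pairs = pd.DataFrame(
        [
            {
                "a": group_names[a],
                "b": group_names[b],
                "p": float(hsd.pvalue[a, b]),
                "significant": bool(hsd.pvalue[a, b] < alpha),
            }
            for a in range(len(cols))
            for b in range(a + 1, len(cols))
        ]
    )
    return omnibus, pairs
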