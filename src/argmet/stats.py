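"""Univariate two-group and multi-group comparisons with effect sizes.

The comparison rule mirrors common clinical-metabolomics practice: test each
group for normality (Shapiro–Wilk); if both pass, use Student's t-test with
Cohen's d (pooled SD) and a t-based 95% CI of the mean difference; otherwise
use the Mann–Whitney U test with the rank-biserial correlation and a
Hodges–Lehmann interval for the location shift.  Three or more groups go
through one-way ANOVA with Tukey HSD post hoc contrasts.

Sign convention everywhere: differences and effect sizes are
(first group − second group), so swapping the groups negates both.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class DegenerateInputError(ValueError):
    """Input has no variation (constant vector / zero SD)."""


class SampleSizeError(ValueError):
    """Too few observations for the requested procedure."""


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str                 # "t_test" | "mann_whitney" | "anova_posthoc"
    mean_difference: float    # first − second, units of the variable
    ci95_low: float
    ci95_high: float
    effect_size: float
    effect_kind: str          # "cohens_d" | "rank_biserial"
    p_value: float


@dataclass(frozen=True)
class AnovaPosthocResult:
    omnibus_p: float
    comparisons: list[UnivariateResult]


def shapiro_normality(values: Sequence[float]) -> float:
    """Shapiro–Wilk p-value; raises on n < 3 or a constant vector."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise SampleSizeError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant vector: normality is undefined")
    return float(sps.shapiro(x).pvalue)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with pooled SD, sign (x − y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d_from_summaries(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def cohens_d_from_summaries(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """d = (m1 − m2) / pooled SD, from printed group summaries.

    The pooled SD is sqrt(((n1−1)s1² + (n2−1)s2²) / (n1+n2−2)); for equal n
    this reduces to sqrt((s1² + s2²)/2).
    """
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("Cohen's d needs n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise DegenerateInputError("Cohen's d undefined for zero/negative SD")
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / sp)


def rank_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-biserial correlation r = 2·U1/(n1·n2) − 1, sign (x − y).

    r = +1 when every x exceeds every y; −1 for the reverse; 0 under
    stochastic equality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u1 = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    return 2.0 * u1 / (x.size * y.size) - 1.0


def hodges_lehmann_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Hodges–Lehmann CI for the location shift x − y (Moses order-statistic
    method with the normal approximation to the Mann–Whitney null SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    K = diffs.size
    z = sps.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = int(np.floor(K / 2.0 - z * se))
    k = max(k, 0)
    return float(diffs[k]), float(diffs[K - 1 - k])


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    normality_alpha: float = 0.05,
    variable: str = "",
) -> UnivariateResult:
    """Two-group comparison with automatic parametric/non-parametric choice.

    Both groups must pass Shapiro–Wilk at ``normality_alpha`` for the t-test
    branch; a constant group routes to the rank branch (normality cannot be
    assessed).  Mann–Whitney is exact for min(n) <= 25 without ties, else
    uses the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise SampleSizeError("compare_groups needs n >= 3 per group")
    mean_diff = float(x.mean() - y.mean())

    try:
        normal = (
            shapiro_normality(x) > normality_alpha
            and shapiro_normality(y) > normality_alpha
        )
    except DegenerateInputError:
        normal = False

    if normal:
        res = sps.ttest_ind(x, y, equal_var=True)
        ci = res.confidence_interval(0.95)
        return UnivariateResult(
            variable=variable, test="t_test", mean_difference=mean_diff,
            ci95_low=float(ci.low), ci95_high=float(ci.high),
            effect_size=cohens_d(x, y), effect_kind="cohens_d",
            p_value=float(res.pvalue),
        )

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    lo, hi = hodges_lehmann_ci(x, y)
    return UnivariateResult(
        variable=variable, test="mann_whitney", mean_difference=mean_diff,
        ci95_low=lo, ci95_high=hi,
        effect_size=rank_biserial(x, y), effect_kind="rank_biserial",
        p_value=float(res.pvalue),
    )


def anova_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> AnovaPosthocResult:
    """One-way ANOVA omnibus test plus Tukey HSD pairwise contrasts.

    Each pairwise result reports the Tukey-adjusted p, the (first − second)
    mean difference with its simultaneous CI, and pairwise Cohen's d.
    """
    if len(groups) < 3:
        raise ValueError("anova_posthoc needs >= 3 groups; use compare_groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise SampleSizeError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]

    omnibus_p = float(sps.f_oneway(*arrays).pvalue)

    values = np.concatenate(arrays)
    tags = np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, tags, alpha=alpha)
    by_label = dict(zip(labels, arrays))
    comparisons = []
    pairs = list(combinations(tk.groupsunique, 2))
    # statsmodels reports meandiff = mean(group2) − mean(group1); flip to our
    # (first − second) convention for the pair as named.
    for (g1, g2), md, p, lo, hi in zip(
        pairs, tk.meandiffs, tk.pvalues, tk.confint[:, 0], tk.confint[:, 1]
    ):
        comparisons.append(
            UnivariateResult(
                variable=f"{g1} vs {g2}", test="anova_posthoc",
                mean_difference=float(-md), ci95_low=float(-hi),
                ci95_high=float(-lo),
                effect_size=cohens_d(by_label[g1], by_label[g2]),
                effect_kind="cohens_d", p_value=float(p),
            )
        )
    return AnovaPosthocResult(omnibus_p=omnibus_p, comparisons=comparisons)


def results_to_frame(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    """Tidy table: variable, test, mean_diff, ci_low, ci_high, effect_size,
    effect_kind, p."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "test": [r.test for r in results],
            "mean_diff": [r.mean_difference for r in results],
            "ci_low": [r.ci95_low for r in results],
            "ci_high": [r.ci95_high for r in results],
            "effect_size": [r.effect_size for r in results],
            "effect_kind": [r.effect_kind for r in results],
            "p": [r.p_value for r in results],
        }
    )
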