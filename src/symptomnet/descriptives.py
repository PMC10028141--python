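"""Cohort-table descriptive statistics.

Prevalence proportions with normal-approximation (Wald) or Wilson 95%
confidence intervals, Pearson chi-square tests of independence on
contingency tables (no continuity correction), one-way ANOVA F
reconstructed from per-group summary statistics (n, mean, SD), and
Cronbach's alpha for scale internal consistency.

All statistics are returned at full precision; rounding for
publication-style tables (1 decimal for chi-square/F, 2 for
percentages) is the caller's concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import stats

from .datasets import INSTRUMENT_SIZES, SymptomDataset, ValidationError

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "proportion_ci",
    "chi_square_independence",
    "anova_from_summary",
    "cronbach_alpha",
    "describe_dataset",
]


@dataclass
class ContingencyTable:
    """r × c table of non-negative counts with labelled rows and columns."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2 × 2")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValidationError("counts must be non-negative integers")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("labels must match the table shape")
        self.counts = c.astype(np.int64)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n, mean, and SD of a scale total."""

    n: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.n) == len(self.mean) == len(self.sd):
            raise ValidationError("n, mean, sd must have equal length")
        if len(self.n) < 2:
            raise ValidationError("at least 2 groups are required")
        if any(k < 2 for k in self.n):
            raise ValidationError("each group needs n >= 2")
        if any(s < 0 for s in self.sd):
            raise ValidationError("standard deviations must be >= 0")


def proportion_ci(
    count: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float, float]:
    """Binomial proportion with CI, all in percent: (p̂, lower, upper).

    ``method="wald"`` gives p̂ ± z·sqrt(p̂(1−p̂)/n); ``"wilson"`` is the
    score interval.  Rounding is left to the caller.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0 <= count <= n:
        raise ValidationError(f"count {count} outside [0, {n}]")
    from statsmodels.stats.proportion import proportion_confint

    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    phat = count / n
    if phat in (0.0, 1.0):
        warnings.warn("degenerate proportion; Wald interval has zero width", stacklevel=2)
    lo, hi = proportion_confint(count, n, alpha=1.0 - level, method=sm_method)
    return 100.0 * phat, 100.0 * float(lo), 100.0 * float(hi)


def chi_square_independence(
    table: ContingencyTable | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, p).

    Expected counts come from the product of marginals over the total;
    no continuity correction.  A zero marginal is an error.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValidationError("contingency table must be at least 2 × 2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined: a marginal total is zero")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def anova_from_summary(groups: GroupSummary) -> tuple[float, int, int, float]:
    """One-way ANOVA F from per-group (n, mean, sd): (F, df1, df2, p).

    Between/within sums of squares are reconstructed from the summaries
    (sample SDs, denominator n−1), so the result equals a raw-data
    one-way ANOVA whenever the summaries are exact.
    """
    n = np.asarray(groups.n, dtype=float)
    mean = np.asarray(groups.mean, dtype=float)
    sd = np.asarray(groups.sd, dtype=float)
    grand = float((n * mean).sum() / n.sum())
    ss_between = float((n * (mean - grand) ** 2).sum())
    ss_within = float(((n - 1.0) * sd**2).sum())
    df1 = len(groups.n) - 1
    df2 = int(n.sum()) - len(groups.n)
    if ss_within == 0.0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha: k/(k−1) · (1 − Σ item variances / total variance).

    Sample variances use denominator n−1.  Zero total-score variance is
    an error (alpha undefined).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValidationError("cronbach_alpha needs an n × k matrix with n, k >= 2")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def describe_dataset(ds: SymptomDataset, level: float = 0.95) -> dict:
    """Cohort-style summary: per-group scale means/SDs, ANOVA F, alpha."""
    groups = ds.group_labels()
    out: dict = {"groups": groups, "n": {g: int((ds.group == g).sum()) for g in groups}}
    scales = {}
    for inst in sorted({it.instrument for it in ds.items}, key=list(INSTRUMENT_SIZES).index):
        totals = {g: ds.subset(g).scale_total(inst) for g in groups}
        summary = GroupSummary(
            n=tuple(len(totals[g]) for g in groups),
            mean=tuple(float(np.mean(totals[g])) for g in groups),
            sd=tuple(float(np.std(totals[g], ddof=1)) for g in groups),
        )
        f, df1, df2, p = anova_from_summary(summary)
        scales[inst] = {
            "mean": dict(zip(groups, summary.mean)),
            "sd": dict(zip(groups, summary.sd)),
            "anova": {"F": f, "df1": df1, "df2": df2, "p": p},
            "cronbach_alpha": cronbach_alpha(ds.instrument_scores(inst)),
        }
    out["scales"] = scales
    return out
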