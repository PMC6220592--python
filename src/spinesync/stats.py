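"""Statistical test menu applied to pipeline outputs.

Wraps the tests used throughout the analysis — paired/unpaired/one-sample t,
Wilcoxon rank sum, Pearson correlation, one-way ANOVA with Tukey HSD, and
the D'Agostino-Pearson omnibus normality gate — returning a uniform
:class:`StatResult`. All tests are two-sided unless an alternative is
requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import IncompatibleInputsError, InsufficientDataError, InvalidConfigError

__all__ = ["StatResult", "normality_gate", "compare", "one_sample", "anova_tukey"]


@dataclass(frozen=True)
class StatResult:
    """Uniform test result: statistic, p, group sizes, means +/- SEM."""

    test_name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    effect_summary: dict = field(default_factory=dict)
    df: float | tuple | None = None
    pairwise: list | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise InvalidConfigError("p must lie in [0, 1]")


def _summary(name: str, x: np.ndarray) -> dict:
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return {name: (float(x.mean()), sem)}


def normality_gate(sample) -> tuple[bool, float]:
    """D'Agostino-Pearson omnibus normality decision at alpha = 0.05.

    Returns ``(normal, p)``. Requires n >= 8 (the test's own minimum);
    smaller samples raise and callers should fall back to rank tests.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise InsufficientDataError(
            "normality test requires n >= 8; use the rank-test fallback"
        )
    stat, p = sps.normaltest(x)
    return bool(p > 0.05), float(p)


def compare(
    sample_a,
    sample_b,
    design: str = "unpaired",
    family: str = "parametric",
    alternative: str = "two-sided",
) -> StatResult:
    """Two-group comparison: paired/unpaired t or Wilcoxon rank sum.

    ``family='parametric'`` selects the t test matching ``design``;
    ``family='rank'`` selects the Wilcoxon rank-sum (normal-approximation)
    test regardless of design.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidConfigError("both samples must be non-empty")
    if design not in ("paired", "unpaired"):
        raise InvalidConfigError(f"unknown design {design!r}")
    if design == "paired" and a.size != b.size:
        raise IncompatibleInputsError("paired design requires equal-length samples")
    if family == "rank":
        stat, p = sps.ranksums(a, b, alternative=alternative)
        name, df = "wilcoxon_rank_sum", None
    elif family == "parametric":
        if design == "paired":
            if np.array_equal(a, b):
                # zero differences with zero variance: no evidence of effect
                res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
            else:
                res = sps.ttest_rel(a, b, alternative=alternative)
            name, df = "paired_t", float(a.size - 1)
        else:
            res = sps.ttest_ind(a, b, alternative=alternative)
            name, df = "unpaired_t", float(a.size + b.size - 2)
        stat, p = res.statistic, res.pvalue
    else:
        raise InvalidConfigError(f"unknown family {family!r}")
    summary = {**_summary("a", a), **_summary("b", b)}
    return StatResult(
        test_name=name, statistic=float(stat), p=float(p),
        n=(a.size, b.size), effect_summary=summary, df=df,
    )


def one_sample(sample, popmean: float = 0.0, alternative: str = "two-sided") -> StatResult:
    """One-sample t test against ``popmean``."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("one-sample t test requires n >= 2")
    res = sps.ttest_1samp(x, popmean, alternative=alternative)
    return StatResult(
        test_name="one_sample_t", statistic=float(res.statistic), p=float(res.pvalue),
        n=(x.size,), effect_summary=_summary("sample", x), df=float(x.size - 1),
    )


def anova_tukey(groups, labels: list[str] | None = None) -> StatResult:
    """One-way ANOVA with Tukey HSD pairwise adjusted p-values.

    ``pairwise`` on the result lists ``(label_a, label_b, mean_diff, p_adj,
    reject)`` for every group pair.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise InvalidConfigError("ANOVA+Tukey expects at least 3 groups")
    if any(g.size < 2 for g in arrays):
        raise InvalidConfigError("every group needs at least 2 observations")
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise InvalidConfigError("one label per group is required")
    f_stat, p = sps.f_oneway(*arrays)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    group_ids = np.concatenate([[lab] * g.size for lab, g in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, group_ids, alpha=0.05)
    pairwise = [
        (str(row[0]), str(row[1]), float(row[2]), float(row[3]), bool(row[6]))
        for row in tukey.summary().data[1:]
    ]
    summary = {}
    for lab, g in zip(labels, arrays):
        summary.update(_summary(lab, g))
    k, n_total = len(arrays), values.size
    return StatResult(
        test_name="anova_tukey", statistic=float(f_stat), p=float(p),
        n=tuple(g.size for g in arrays), effect_summary=summary,
        df=(float(k - 1), float(n_total - k)), pairwise=pairwise,
    )
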