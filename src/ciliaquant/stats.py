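"""Group-level summaries and hypothesis tests for the cilia phenotypes.

The assay's statistical surface: mean ± SEM per group, one-way ANOVA across
groups, Dunnett's post hoc comparisons of each treatment against a named
control (family-wise error controlled via the equicorrelated multivariate-t
null), a two-sided two-sample t test for pairwise designs, and the
minimum-count quality rules (cilia per sample, cells per sample, cells per
population, fields of view).

All tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "QCThresholds",
    "group_summary",
    "anova_oneway",
    "dunnett_vs_control",
    "t_test_two_group",
    "qc_flags",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and SEM (sample sd / √n; NaN when n = 1) of one group."""

    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a group comparison.

    ``statistic`` is F for ANOVA or t for a t test; ``comparisons`` maps each
    treatment group index (or label) to ``(t, p_raw, p_adjusted)`` for
    Dunnett-style results and is empty otherwise.
    """

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparisons: dict[str, tuple[float, float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class QCThresholds:
    """Minimum-count rules; violations annotate outputs, never block them."""

    min_cilia_per_sample: int = 150
    min_cells_per_sample: int = 300
    min_cells_per_population: int = 100
    min_fields: int = 10

    def __post_init__(self) -> None:
        for v in (
            self.min_cilia_per_sample,
            self.min_cells_per_sample,
            self.min_cells_per_population,
            self.min_fields,
        ):
            if v < 0:
                raise ValueError("thresholds must be >= 0")


def group_summary(values, group: str = "") -> GroupSummary:
    """Mean and standard error of the mean of one group of observations."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return GroupSummary(group=group, n=int(arr.size), mean=float(arr.mean()), sem=sem)


def _pooled_anova(groups: list[np.ndarray]):
    """Classical one-way ANOVA decomposition; returns (F, df1, df2, ssw)."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, N - k
    return ssb, ssw, df1, df2


def anova_oneway(groups) -> ComparisonResult:
    """One-way fixed-effects ANOVA.

    F = between-group mean square / within-group mean square, with p from
    the F(k−1, N−k) distribution. Degenerate data with zero variance both
    between and within groups returns F = 0, p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    ssb, ssw, df1, df2 = _pooled_anova(arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return ComparisonResult("one-way ANOVA", 0.0, (df1, df2), 1.0)
        return ComparisonResult("one-way ANOVA", float("inf"), (df1, df2), 0.0)
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return ComparisonResult("one-way ANOVA", float(f), (df1, df2), p)


def dunnett_vs_control(groups, control: int = 0, seed: int = 0) -> ComparisonResult:
    """Dunnett's many-to-one comparisons against a control group.

    Each treatment group is compared to the control with a t statistic using
    the pooled within-group variance; adjusted p values come from the
    equicorrelated multivariate-t null (correlation ½ in the balanced case,
    group-size-derived otherwise), evaluated numerically. With a single
    treatment the adjustment is vacuous and the adjusted p equals the pooled
    two-sided t-test p exactly. Adjusted p values are never reported below
    the raw pairwise p.

    ``seed`` fixes the quasi-random integration of the multivariate-t
    probability so repeated calls are deterministic.

    The overall ``statistic``/``p_value`` carry the ANOVA F for context;
    per-treatment results are in ``comparisons`` keyed by group index.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    if not 0 <= control < len(arrs):
        raise ValueError(f"control index {control} out of range")

    ssb, ssw, df1, df2 = _pooled_anova(arrs)
    s2 = ssw / df2 if df2 > 0 else 0.0
    ctrl = arrs[control]
    treatments = [(i, a) for i, a in enumerate(arrs) if i != control]

    tstats = {}
    for i, a in treatments:
        se = math.sqrt(s2 * (1 / a.size + 1 / ctrl.size)) if s2 > 0 else 0.0
        t = (a.mean() - ctrl.mean()) / se if se > 0 else 0.0
        p_raw = 2.0 * float(sps.t.sf(abs(t), df2)) if se > 0 else 1.0
        tstats[i] = (t, p_raw)

    k = len(treatments)
    comparisons: dict[str, tuple[float, float, float]] = {}
    if k == 1:
        idx, (t, p_raw) = next(iter(tstats.items()))
        comparisons[str(idx)] = (t, p_raw, p_raw)
    else:
        res = sps.dunnett(
            *[a for _, a in treatments],
            control=ctrl,
            rng=np.random.default_rng(seed),
        )
        for j, (i, _) in enumerate(treatments):
            t, p_raw = tstats[i]
            p_adj = min(1.0, max(float(res.pvalue[j]), p_raw))
            comparisons[str(i)] = (t, p_raw, p_adj)

    anova = anova_oneway(arrs)
    return ComparisonResult(
        test="Dunnett vs control",
        statistic=anova.statistic,
        df=(df1, df2),
        p_value=anova.p_value,
        comparisons=comparisons,
    )


def t_test_two_group(a, b, paired: bool = False) -> ComparisonResult:
    """Two-sided Student's t test (pooled-variance unpaired, or paired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        res = sps.ttest_rel(a, b)
        df = (float(a.size - 1),)
        name = "paired t test"
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        df = (float(a.size + b.size - 2),)
        name = "two-sample t test"
    return ComparisonResult(name, float(res.statistic), df, float(res.pvalue))


def qc_flags(
    counts: dict,
    thresholds: QCThresholds = QCThresholds(),
) -> list[str]:
    """Evaluate the minimum-count rules against observed counts.

    ``counts`` may hold any of the keys ``n_cilia``, ``n_cells``,
    ``n_cells_population``, ``n_fields``; absent keys are not checked.
    Returns the identifiers of violated rules.
    """
    flags = []
    checks = (
        ("n_cilia", thresholds.min_cilia_per_sample, "min_cilia_not_met"),
        ("n_cells", thresholds.min_cells_per_sample, "min_cells_not_met"),
        (
            "n_cells_population",
            thresholds.min_cells_per_population,
            "min_cells_population_not_met",
        ),
        ("n_fields", thresholds.min_fields, "min_fields_not_met"),
    )
    for key, minimum, flag in checks:
        if key in counts:
            if counts[key] < 0:
                raise ValueError(f"{key} must be >= 0")
            if counts[key] < minimum:
                flags.append(flag)
    return flags


def significance_stars(p: float) -> str:
    """Map a p value to the conventional star annotation."""
    if math.isnan(p):
        return "n.a."
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
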