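"""Normality-routed hypothesis testing for cohort, paired, and factorial designs.

The routing rule mirrors common clinical-statistics practice: a variable is
treated as parametric when the D'Agostino & Pearson omnibus test does not
reject at 0.05 AND both the skewness and kurtosis z-statistics lie within
(-1.96, 1.96).  Group comparisons then run one-way ANOVA with Tukey's HSD
(parametric) or Kruskal-Wallis with Dunn's test (non-parametric); paired
comparisons run the paired t-test or the Wilcoxon signed-rank test.
Factorial treatment designs always use two-way ANOVA with Tukey post-hocs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ALPHA",
    "StatResult",
    "assess_normality",
    "normality_zscores",
    "compare_groups",
    "compare_two_groups",
    "compare_paired",
    "two_way_anova",
    "dunn_posthoc",
]

ALPHA = 0.05

_Z_BOUND = 1.96
_MIN_N_OMNIBUS = 8


@dataclass
class StatResult:
    """Outcome of one routed hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    branch: str  # "parametric" | "nonparametric"
    posthoc: list[dict] = field(default_factory=list)
    effects: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": self.n_per_group,
            "branch": self.branch,
            "posthoc": self.posthoc,
            "effects": self.effects,
            "warnings": self.warnings,
        }


def normality_zscores(values: np.ndarray) -> tuple[float, float, float]:
    """Skewness z, kurtosis z, and the D'Agostino-Pearson omnibus p-value."""
    values = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        # small-sample approximation warnings from kurtosistest
        warnings.simplefilter("ignore")
        z_skew = stats.skewtest(values).statistic
        z_kurt = stats.kurtosistest(values).statistic
        p_omnibus = stats.normaltest(values).pvalue
    return float(z_skew), float(z_kurt), float(p_omnibus)


def assess_normality(values, warn_list: list[str] | None = None) -> str:
    """Route a sample to the parametric or non-parametric branch.

    Returns ``"parametric"`` iff the D'Agostino-Pearson omnibus p >= 0.05
    and both the skewness and kurtosis z-values lie in (-1.96, 1.96).
    Samples too small for the omnibus test (n < 8) or constant samples are
    routed non-parametric with a warning rather than an exception.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]

    def _warn(msg: str) -> None:
        warnings.warn(msg, stacklevel=2)
        if warn_list is not None:
            warn_list.append(msg)

    if values.size < _MIN_N_OMNIBUS:
        _warn(
            f"n={values.size} too small for the normality omnibus test; "
            "routing non-parametric"
        )
        return "nonparametric"
    if np.ptp(values) == 0:
        _warn("constant sample; routing non-parametric")
        return "nonparametric"
    z_skew, z_kurt, p_omnibus = normality_zscores(values)
    ok = (
        p_omnibus >= ALPHA
        and -_Z_BOUND < z_skew < _Z_BOUND
        and -_Z_BOUND < z_kurt < _Z_BOUND
    )
    return "parametric" if ok else "nonparametric"


def _as_group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must have equal length")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        arr = values[groups == g]
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
        out[str(g)] = arr
    return out


def dunn_posthoc(samples: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based multiple-comparison test after Kruskal-Wallis.

    Pairwise z-statistics use the pooled-rank means with the standard tie
    correction; both unadjusted and Bonferroni-adjusted two-sided p-values
    are reported (the adjusted value is the headline ``p``).
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    rank_means: dict[str, float] = {}
    start = 0
    for g in names:
        n_g = samples[g].size
        rank_means[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    results = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / samples[a].size + 1.0 / samples[b].size))
        z = (rank_means[a] - rank_means[b]) / se
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            {
                "pair": (a, b),
                "statistic": float(z),
                "p": min(1.0, p_raw * n_pairs),
                "p_unadjusted": p_raw,
            }
        )
    return results


def _tukey_posthoc(values: np.ndarray, labels: np.ndarray) -> list[dict]:
    res = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return [
        {
            "pair": (str(row["group1"]), str(row["group2"])),
            "statistic": float(row["meandiff"]),
            "p": float(row["p-adj"]),
        }
        for _, row in frame.iterrows()
    ]


def compare_two_groups(values, groups) -> StatResult:
    """Two-group comparison: Welch-free pooled t-test or Mann-Whitney U."""
    samples = _as_group_arrays(values, groups)
    if len(samples) != 2:
        raise ValueError(f"expected 2 groups, got {len(samples)}")
    warn_list: list[str] = []
    arrays = list(samples.values())
    residuals = np.concatenate([a - a.mean() for a in arrays])
    branch = assess_normality(residuals, warn_list)
    if branch == "parametric":
        stat, p = stats.ttest_ind(*arrays)
        name = "t-test"
    else:
        stat, p = stats.mannwhitneyu(*arrays, alternative="two-sided")
        name = "mann-whitney"
    return StatResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n_per_group={g: int(a.size) for g, a in samples.items()},
        branch=branch,
        warnings=warn_list,
    )


def compare_groups(values, groups) -> StatResult:
    """Routed omnibus comparison across >=3 groups with matched post-hocs.

    Normality is assessed on pooled within-group residuals.  Parametric:
    one-way ANOVA followed by Tukey's HSD.  Non-parametric: Kruskal-Wallis
    followed by Dunn's test.  Two-level designs are delegated to
    :func:`compare_two_groups`.
    """
    samples = _as_group_arrays(values, groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if len(samples) == 2:
        return compare_two_groups(values, groups)
    for g, arr in samples.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    warn_list: list[str] = []
    residuals = np.concatenate([a - a.mean() for a in samples.values()])
    branch = assess_normality(residuals, warn_list)
    values_arr = np.asarray(values, dtype=float)
    labels_arr = np.asarray(groups).astype(str)
    if branch == "parametric":
        stat, p = stats.f_oneway(*samples.values())
        posthoc = _tukey_posthoc(values_arr, labels_arr)
        name = "one-way-anova"
    else:
        stat, p = stats.kruskal(*samples.values())
        posthoc = dunn_posthoc(samples)
        name = "kruskal-wallis"
    return StatResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n_per_group={g: int(a.size) for g, a in samples.items()},
        branch=branch,
        posthoc=posthoc,
        warnings=warn_list,
    )


def compare_paired(pre, post) -> StatResult:
    """Paired pre/post comparison routed on the distribution of differences.

    Parametric branch: paired two-tailed t-test.  Non-parametric branch:
    Wilcoxon signed-rank test.  All-zero differences return p = 1 with a
    warning (no evidence of change, no variability to test).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = post - pre
    warn_list: list[str] = []
    if np.all(diffs == 0):
        msg = "all paired differences are zero; returning p = 1"
        warnings.warn(msg, stacklevel=2)
        return StatResult(
            test_name="paired-t",
            statistic=0.0,
            p_value=1.0,
            n_per_group={"pairs": int(pre.size)},
            branch="parametric",
            warnings=[msg],
        )
    branch = assess_normality(diffs, warn_list)
    if branch == "parametric":
        stat, p = stats.ttest_rel(post, pre)
        name = "paired-t"
    else:
        stat, p = stats.wilcoxon(post, pre)
        name = "wilcoxon-signed-rank"
    return StatResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n_per_group={"pairs": int(pre.size)},
        branch=branch,
        warnings=warn_list,
    )


def two_way_anova(values, factor_a, factor_b) -> StatResult:
    """Two-way ANOVA (type-II sums of squares) with Tukey post-hoc on cells.

    Applied unconditionally on the parametric branch, as is conventional for
    factorial cell-culture treatment designs.  Every design cell must be
    non-empty and each factor needs at least two levels.
    """
    frame = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a).astype(str),
            "b": np.asarray(factor_b).astype(str),
        }
    )
    levels_a = sorted(frame["a"].unique())
    levels_b = sorted(frame["b"].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least two levels")
    cells = frame.groupby(["a", "b"], sort=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in cells.index:
                raise ValueError(f"empty design cell: ({la!r}, {lb!r})")
    model = smf.ols("value ~ C(a) * C(b)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {
        "factor_a": {
            "F": float(table.loc["C(a)", "F"]),
            "p": float(table.loc["C(a)", "PR(>F)"]),
        },
        "factor_b": {
            "F": float(table.loc["C(b)", "F"]),
            "p": float(table.loc["C(b)", "PR(>F)"]),
        },
        "interaction": {
            "F": float(table.loc["C(a):C(b)", "F"]),
            "p": float(table.loc["C(a):C(b)", "PR(>F)"]),
        },
    }
    cell_labels = (frame["a"] + ":" + frame["b"]).to_numpy()
    posthoc = _tukey_posthoc(frame["value"].to_numpy(), cell_labels)
    return StatResult(
        test_name="two-way-anova",
        statistic=effects["interaction"]["F"],
        p_value=effects["interaction"]["p"],
        n_per_group={f"{a}:{b}": int(n) for (a, b), n in cells.items()},
        branch="parametric",
        posthoc=posthoc,
        effects=effects,
    )
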