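"""Pearson correlation with per-variable log routing and paired-delta designs.

Variables failing the normality screen are natural-log-transformed before
Pearson's r is computed (positive-valued variables only); delta analyses
correlate post-minus-pre changes directly and never log them, since changes
may legitimately be negative.  Two-tailed p-values come from the usual
t transform t = r * sqrt((n-2)/(1-r^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import assess_normality

__all__ = [
    "CorrelationResult",
    "significance_stars",
    "pearson_with_log_routing",
    "delta_correlation",
    "correlation_matrix",
    "correlation_matrix_to_frame",
]

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Star notation: * <0.05, ** <0.01, *** <0.001, **** <0.0001, else ns."""
    for cutoff, stars in _STAR_LEVELS:
        if p < cutoff:
            return stars
    return "ns"


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    p_value: float
    n: int
    log_x: bool
    log_y: bool

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {
            "variable_x": self.variable_x,
            "variable_y": self.variable_y,
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
            "log_x": self.log_x,
            "log_y": self.log_y,
            "stars": self.stars,
        }


def _route_log(values: np.ndarray, name: str) -> tuple[np.ndarray, bool]:
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        branch = assess_normality(values)
    if branch == "parametric":
        return values, False
    if np.any(values <= 0):
        raise ValueError(
            f"variable {name!r} is non-normal and requires a log transform, "
            "but contains non-positive values"
        )
    return np.log(values), True


def pearson_with_log_routing(
    x,
    y,
    name_x: str = "x",
    name_y: str = "y",
    log_routing: bool = True,
) -> CorrelationResult:
    """Pearson correlation with independent per-variable log routing.

    Each variable is screened for normality; a non-normal variable is
    natural-log-transformed (it must then be strictly positive).  Pairs with
    a missing value in either variable are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    complete = np.isfinite(x) & np.isfinite(y)
    x, y = x[complete], y[complete]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        zero = name_x if np.ptp(x) == 0 else name_y
        raise ValueError(f"variable {zero!r} has zero variance")
    log_x = log_y = False
    if log_routing:
        x, log_x = _route_log(x, name_x)
        y, log_y = _route_log(y, name_y)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        variable_x=name_x,
        variable_y=name_y,
        r=float(r),
        p_value=float(p),
        n=n,
        log_x=log_x,
        log_y=log_y,
    )


def delta_correlation(
    paired: pd.DataFrame,
    var_x: str,
    var_y: str,
    subject_col: str = "subject_id",
    timepoint_col: str = "timepoint",
) -> CorrelationResult:
    """Correlate per-subject post-minus-pre changes of two variables.

    ``paired`` holds one row per subject x timepoint with timepoints
    labelled ``pre`` and ``post``.  Subjects missing either timepoint or
    either variable are excluded; log routing is disabled on deltas.
    """
    for col in (subject_col, timepoint_col, var_x, var_y):
        if col not in paired.columns:
            raise ValueError(f"paired table missing column {col!r}")
    wide = paired.pivot_table(
        index=subject_col, columns=timepoint_col, values=[var_x, var_y]
    )
    needed = [(var_x, "pre"), (var_x, "post"), (var_y, "pre"), (var_y, "post")]
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise ValueError(f"paired table missing timepoint data: {missing}")
    complete = wide.loc[:, needed].dropna()
    n_excluded = len(wide) - len(complete)
    if len(complete) < 3:
        raise ValueError(
            f"only {len(complete)} subjects with both timepoints "
            f"({n_excluded} excluded); need at least 3"
        )
    dx = complete[(var_x, "post")] - complete[(var_x, "pre")]
    dy = complete[(var_y, "post")] - complete[(var_y, "pre")]
    return pearson_with_log_routing(
        dx.to_numpy(),
        dy.to_numpy(),
        name_x=f"delta_{var_x}",
        name_y=f"delta_{var_y}",
        log_routing=False,
    )


def correlation_matrix(
    expression: pd.DataFrame,
    panel_x: list[str],
    panel_y: list[str],
    log_routing: bool = True,
) -> dict[tuple[str, str], CorrelationResult]:
    """All pairwise correlations between two variable panels.

    Returns a dict keyed by (x, y); r(x, y) equals r(y, x) by symmetry of
    the Pearson coefficient, so cell order only affects labelling.
    """
    unknown = [g for g in panel_x + panel_y if g not in expression.columns]
    if unknown:
        raise ValueError(f"unknown variables: {sorted(set(unknown))}")
    out: dict[tuple[str, str], CorrelationResult] = {}
    for gx in panel_x:
        for gy in panel_y:
            if gx == gy:
                vals = expression[gx].to_numpy(dtype=float)
                n = int(np.isfinite(vals).sum())
                out[(gx, gy)] = CorrelationResult(gx, gy, 1.0, 0.0, n, False, False)
                continue
            out[(gx, gy)] = pearson_with_log_routing(
                expression[gx].to_numpy(dtype=float),
                expression[gy].to_numpy(dtype=float),
                name_x=gx,
                name_y=gy,
                log_routing=log_routing,
            )
    return out


def correlation_matrix_to_frame(
    results: dict[tuple[str, str], CorrelationResult]
) -> pd.DataFrame:
    """Flatten a correlation matrix into a long table (r, p, n, stars)."""
    rows = [res.to_dict() for res in results.values()]
    return pd.DataFrame(rows)
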