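"""Group-comparison statistics and shared linear trend fitting.

Comparisons mirror the study design: one-way ANOVA with Tukey-Kramer
post-hoc tests (summarized as a compact letter display: groups sharing no
letter differ at alpha) across ages, and pooled-variance Student's t-tests
between two conditions at a single time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError, InsufficientDataError


@dataclass(frozen=True)
class GroupTable:
    """Per-group scalar measurements (modulus, slope, fraction, ratio...)."""

    values: Mapping[str, np.ndarray]
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "values",
            {str(g): np.asarray(v, dtype=float) for g, v in self.values.items()},
        )

    def require_variance_tests(self) -> None:
        if len(self.values) < 2:
            raise InsufficientDataError("need at least 2 groups")
        for g, v in self.values.items():
            if len(v) < 2:
                raise InsufficientDataError(f"group {g!r} has fewer than 2 values")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_col: str, value_col: str, units: str = "") -> "GroupTable":
        vals = {g: sub[value_col].to_numpy(dtype=float) for g, sub in frame.groupby(group_col, sort=True)}
        return cls(values=vals, units=units)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a group comparison.

    ``letters`` is the compact letter display for Tukey post-hoc results
    (groups sharing no letter differ at ``alpha``); ``significant`` is the
    pair flag for two-sample tests.  ``pairwise_p`` holds adjusted p-values
    for every group pair where applicable.
    """

    test: str
    statistic: float
    p_value: float
    alpha: float
    df: float | None = None
    letters: dict[str, str] | None = None
    significant: bool | None = None
    degenerate_variance: bool = False
    pairwise_p: pd.DataFrame | None = None
    group_means: dict[str, float] = field(default_factory=dict)


def linear_trend(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: returns (slope, intercept, r_squared).

    Exact on affine data; a constant ``y`` gives slope 0 with r_squared 1
    (the fit reproduces the data perfectly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all x values equal: slope is undefined")
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    slope = float(dx @ (y - ym) / (dx @ dx))
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, float(max(min(r2, 1.0), 0.0))


def _compact_letter_display(
    groups: list[str], means: dict[str, float], sig_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are processed in descending mean (ties by label) so letter
    assignment is deterministic.  Two groups share a letter iff they are not
    a significant pair.
    """
    ordered = sorted(groups, key=lambda g: (-means[g], g))
    columns: list[set[str]] = [set(ordered)]
    for a, b in combinations(ordered, 2):
        if frozenset((a, b)) not in sig_pairs:
            continue
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb columns that are subsets of another
        columns = []
        for col in sorted(new_columns, key=len, reverse=True):
            if col and not any(col <= kept for kept in columns):
                columns.append(col)
    # order columns by the best-ranked member for stable letter naming
    rank = {g: i for i, g in enumerate(ordered)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i) if i < 26 else f"z{i}"
        for g in sorted(col, key=lambda g: rank[g]):
            letters[g] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def one_way_anova_tukey(
    table: GroupTable, alpha: float = 0.05, log_transform: bool = False
) -> ComparisonResult:
    """One-way ANOVA with Tukey-Kramer all-pairs post-hoc comparisons.

    Reports the F statistic and p-value, the adjusted p-value for every group
    pair, and a compact letter display (descending-mean order; groups sharing
    no letter differ at ``alpha``).  ``log_transform`` applies a natural log
    to all values first (variance stabilization for right-skewed measures).
    """
    table.require_variance_tests()
    names = sorted(table.values)
    samples = [table.values[g] for g in names]
    if log_transform:
        samples = [np.log(s) for s in samples]
    f_stat, p_val = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    pairwise = pd.DataFrame(np.asarray(tukey.pvalue), index=names, columns=names)
    means = {g: float(np.mean(s)) for g, s in zip(names, samples)}
    sig_pairs = {
        frozenset((a, b))
        for i, a in enumerate(names)
        for j, b in enumerate(names)
        if i < j and pairwise.iloc[i, j] < alpha
    }
    letters = _compact_letter_display(names, means, sig_pairs)
    n_total = sum(len(s) for s in samples)
    return ComparisonResult(
        test="one-way ANOVA + Tukey HSD",
        statistic=float(f_stat),
        p_value=float(p_val),
        alpha=alpha,
        df=float(n_total - len(samples)),
        letters=letters,
        pairwise_p=pairwise,
        group_means=means,
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05, welch: bool = False
) -> ComparisonResult:
    """Two-sided Student's t-test (pooled variance by default; Welch by flag).

    Degenerate inputs with zero pooled variance yield t = 0, p = 1 when the
    means are equal, and an infinite statistic with the
    ``degenerate_variance`` flag set when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    df = float(len(a) + len(b) - 2)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return ComparisonResult("Student's t", 0.0, 1.0, alpha, df=df, significant=False)
        stat = math_inf_signed(a[0] - b[0])
        return ComparisonResult(
            "Student's t", stat, 0.0, alpha, df=df, significant=True, degenerate_variance=True
        )
    stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = float(sps.ttest_ind(a, b, equal_var=False).df)
    return ComparisonResult(
        "Welch's t" if welch else "Student's t",
        float(stat),
        float(p),
        alpha,
        df=df,
        significant=bool(p < alpha),
        group_means={"a": float(a.mean()), "b": float(b.mean())},
    )


def math_inf_signed(diff: float) -> float:
    return float(np.inf) if diff > 0 else float(-np.inf)


def comparison_frame(result: ComparisonResult, measure: str = "") -> pd.DataFrame:
    """One-row tidy summary of a comparison, for the pipeline report CSVs."""
    row = {
        "measure": measure,
        "test": result.test,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "alpha": result.alpha,
        "df": result.df,
        "significant": result.significant,
        "letters": ";".join(f"{g}:{s}" for g, s in sorted(result.letters.items()))
        if result.letters
        else "",
    }
    return pd.DataFrame([row])
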