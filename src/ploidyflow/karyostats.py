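"""Karyological statistics.

Pearson correlation/regression between ploidy level and chromosome number
or monoploid genome size, one-way ANOVA across taxonomic series with a
Tukey-Kramer post hoc (unequal group sizes) and compact letter display,
and the fixed-constant Box-Cox style normalising transform used for
chromosome counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class CorrelationResult:
    """Pearson r with the OLS line of y on x."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


@dataclass
class AnovaResult:
    """Classical one-way between/within decomposition."""

    f: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ss_total: float
    degenerate: bool = False  # within-group variance exactly zero


@dataclass
class TukeyGrouping:
    """Pairwise Tukey-Kramer comparisons with a compact letter display."""

    group_means: dict[str, float]
    group_sems: dict[str, float]
    comparisons: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    alpha: float


def pearson_with_regression(
    x_values: Sequence[float], y_values: Sequence[float]
) -> CorrelationResult:
    """Product-moment correlation with two-sided p and the OLS line."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )


def boxcox_chromosome_transform(n_chromosomes: float) -> float:
    """Fixed-constant normalising transform for chromosome counts.

    ``x = (2 * N**-0.4 * -1) / -0.0013246`` — a positive, strictly
    decreasing function of N.  The constants are the software-fitted
    Box-Cox parameters taken as given; no lambda search is performed.
    """
    n = np.asarray(n_chromosomes, dtype=float)
    if np.any(n <= 0):
        raise ValueError("chromosome count must be positive")
    out = (2.0 * n**-0.4 * -1.0) / -0.0013246
    return float(out) if out.ndim == 0 else out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over labeled groups.

    Degrees of freedom are ``(k - 1, N - k)``.  When the within-group sum
    of squares is exactly zero and means differ, F is infinite and the
    result is flagged degenerate rather than raising.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 1 for a in arrays.values()):
        raise ValueError("every group needs at least one value")
    n_total = sum(len(a) for a in arrays.values())
    k = len(arrays)
    if n_total - k < 1:
        raise ValueError("need at least one group with >= 2 values")
    grand = math.fsum(float(a.sum()) for a in arrays.values()) / n_total
    ss_between = math.fsum(
        len(a) * (a.mean() - grand) ** 2 for a in arrays.values()
    )
    ss_within = math.fsum(
        float(((a - a.mean()) ** 2).sum()) for a in arrays.values()
    )
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        degenerate = ss_between > 0
        f = math.inf if degenerate else 0.0
        p = 0.0 if degenerate else 1.0
        return AnovaResult(
            f, df_b, df_w, p, ss_between, ss_within,
            ss_between + ss_within, degenerate=degenerate,
        )
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_between + ss_within),
    )


def _compact_letter_display(
    names: list[str],
    means: Mapping[str, float],
    nonsignificant: set[frozenset],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are processed in descending mean order; each significantly
    different pair must share no letter, each non-significant pair at
    least one.
    """
    order = sorted(names, key=lambda g: -means[g])
    # columns: each a set of groups sharing one letter
    columns: list[set[str]] = [set(order)]
    for g1 in order:
        for g2 in order:
            if g1 >= g2 or frozenset((g1, g2)) in nonsignificant:
                continue
            # significant pair: split every column containing both
            new_columns: list[set[str]] = []
            for col in columns:
                if g1 in col and g2 in col:
                    new_columns.append(col - {g1})
                    new_columns.append(col - {g2})
                else:
                    new_columns.append(col)
            # absorb: drop columns contained in another
            columns = [
                c
                for i, c in enumerate(new_columns)
                if c
                and not any(
                    c < other or (c == other and i > j)
                    for j, other in enumerate(new_columns)
                )
            ]
    # letter columns ordered by the best (largest-mean) member
    columns.sort(key=lambda col: min(order.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in names}
    for i, col in enumerate(columns):
        for g in col:
            letters[g].append(alphabet[i])
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_kramer(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyGrouping:
    """All-pairs Tukey-Kramer comparison with compact letters.

    Uses the studentized-range critical value with the Kramer adjustment
    for unequal group sizes (reducing to Tukey's HSD when sizes are
    equal), then derives one or more letters per group such that two
    groups share a letter iff their adjusted p exceeds ``alpha``.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate(
        [np.full(len(a), name, dtype=object) for name, a in arrays.items()]
    )
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    comparisons = pd.DataFrame(
        {
            "group1": table["group1"].astype(str),
            "group2": table["group2"].astype(str),
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    means = {k: float(a.mean()) for k, a in arrays.items()}
    sems = {
        k: (
            float(a.std(ddof=1) / math.sqrt(len(a))) if len(a) > 1 else 0.0
        )
        for k, a in arrays.items()
    }
    nonsig = {
        frozenset((row.group1, row.group2))
        for row in comparisons.itertuples()
        if not row.reject
    }
    letters = _compact_letter_display(list(arrays), means, nonsig)
    return TukeyGrouping(
        group_means=means,
        group_sems=sems,
        comparisons=comparisons,
        letters=letters,
        alpha=alpha,
    )


def series_group_means(
    table: pd.DataFrame,
    series_column: str = "series",
    value_column: str = "two_n",
) -> dict[str, float]:
    """Arithmetic mean of ``value_column`` per taxonomic series.

    Each population is one unit: two populations of the same species count
    separately.
    """
    if table.empty:
        raise ValueError("empty table")
    grouped = table.groupby(series_column)[value_column].mean()
    return {str(k): float(v) for k, v in grouped.items()}


def plot_correlation(result: CorrelationResult, x, y, xlabel, ylabel, path):
    """Scatter plot with the fitted line, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=25, color="tab:blue")
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="tab:red")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"r = {result.r:.2f}, p = {result.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
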