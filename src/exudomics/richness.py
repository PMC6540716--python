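"""Chemical richness statistics: per-sample compound counts, one-way ANOVA
over species, and the Scheffé post hoc test with a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PresenceAbsenceMatrix

__all__ = [
    "AnovaResult",
    "ScheffeResult",
    "chemical_richness",
    "group_summary",
    "one_way_anova",
    "scheffe_posthoc",
]


def chemical_richness(pa: PresenceAbsenceMatrix | pd.DataFrame) -> pd.Series:
    """Number of compounds present per sample (binary row sum)."""
    values = pa.values if isinstance(pa, PresenceAbsenceMatrix) else pa
    return values.sum(axis=1).rename("chemical_richness")


def group_summary(values: pd.Series, groups: Sequence) -> pd.DataFrame:
    """Per-group mean, median, quartiles and size of a per-sample statistic."""
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "group": list(groups)})
    agg = df.groupby("group")["value"].agg(
        n="count",
        mean="mean",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    return agg


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = np.unique(groups)
    return values, groups, labels


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical between/within decomposition with an F-distribution p-value.

    Degenerate contracts: no between-group variance gives F = 0, p = 1;
    perfect separation (within-SS = 0 with distinct means) gives F = inf,
    p = 0.
    """
    values, groups, labels = _group_arrays(values, groups)
    k = len(labels)
    n = len(values)
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    if n <= k:
        raise ValueError("ANOVA requires more observations than groups")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in labels:
        sub = values[groups == g]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
        ss_within += ((sub - sub.mean()) ** 2).sum()
    df1, df2 = k - 1, n - k
    scale = max(ss_between + ss_within, 1.0)
    if ss_between / scale < 1e-14:
        return AnovaResult(0.0, df1, df2, 1.0)
    if ss_within / scale < 1e-14:
        return AnovaResult(float("inf"), df1, df2, 0.0)
    F = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(float(F), df1, df2, float(stats.f.sf(F, df1, df2)))


@dataclass(frozen=True)
class ScheffeResult:
    """All-pairs Scheffé comparisons and their compact letter display.

    Two groups share a letter exactly when their contrast is non-significant
    at ``alpha``.
    """

    pairs: pd.DataFrame
    letters: dict
    alpha: float
    anova: AnovaResult


def scheffe_posthoc(
    values: Sequence[float], groups: Sequence, alpha: float = 0.05
) -> ScheffeResult:
    """Scheffé all-pairs test with insert-and-absorb letter assignment.

    A pair (i, j) is significant when
    ``|mean_i - mean_j| > sqrt((k-1) * F_crit * MSE * (1/n_i + 1/n_j))``
    with ``F_crit`` the upper-alpha F quantile on (k-1, N-k) degrees of
    freedom.  Letters are assigned to groups ordered by descending mean,
    which makes the display deterministic.
    """
    values, groups, labels = _group_arrays(values, groups)
    anova = one_way_anova(values, groups)
    k = len(labels)
    n = len(values)
    means = {g: values[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    mse = (
        sum(
            ((values[groups == g] - means[g]) ** 2).sum() for g in labels
        )
        / (n - k)
    )
    f_crit = stats.f.ppf(1.0 - alpha, k - 1, n - k)
    rows = []
    significant_pairs = []
    for a, b in combinations(sorted(labels.tolist()), 2):
        diff = abs(means[a] - means[b])
        crit = np.sqrt(
            (k - 1) * f_crit * mse * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        sig = bool(diff > crit)
        rows.append(
            {"group_a": a, "group_b": b, "diff": diff,
             "critical": crit, "significant": sig}
        )
        if sig:
            significant_pairs.append((a, b))
    order = sorted(labels.tolist(), key=lambda g: -means[g])
    letters = _compact_letters(order, significant_pairs)
    return ScheffeResult(
        pairs=pd.DataFrame(rows), letters=letters, alpha=alpha, anova=anova
    )


def _compact_letters(order, significant_pairs):
    """Insert-and-absorb compact letter display (groups in display order)."""
    columns: list[set] = [set(order)]
    for a, b in significant_pairs:
        new_columns: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = [
            c
            for i, c in enumerate(new_columns)
            if not any(
                c < other or (c == other and i > j)
                for j, other in enumerate(new_columns)
            )
        ]
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters
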