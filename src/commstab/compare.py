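"""One-way ANOVA with Tukey HSD letters across disturbance levels.

Any per-sample metric (stability, a cohesion score, a diversity index)
can be compared across the gradient: an omnibus F test, Tukey-Kramer
adjusted pairwise p-values, and a compact letter display in which levels
sharing a letter are not significantly different.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tables import SampleMeta, ValidationError

__all__ = ["GroupComparison", "anova_tukey", "compact_letter_display"]


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    #: per-level summary: level, n, mean, sd, letter (gradient order)
    summary: pd.DataFrame
    f_statistic: float
    p_value: float
    #: long pairwise table: level_a, level_b, p_adj, significant
    pairwise: pd.DataFrame
    alpha: float


def compact_letter_display(
    levels: list[str],
    means: dict[str, float],
    significant_pairs: set[frozenset],
    declared_order: list[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Levels are processed in descending mean order (ties broken by the
    declared gradient order), so the output is deterministic and
    independent of input sample order.
    """
    if declared_order is None:
        declared_order = list(levels)
    rank = {lv: i for i, lv in enumerate(declared_order)}
    ordered = sorted(levels, key=lambda lv: (-means[lv], rank[lv]))

    columns: list[set[str]] = [set(ordered)]
    pairs = [
        (a, b)
        for i, a in enumerate(ordered)
        for b in ordered[i + 1:]
        if frozenset((a, b)) in significant_pairs
    ]
    for a, b in pairs:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(i != j and c < d or (c == d and j < i) for j, d in enumerate(new_cols))
        ]

    # letter columns ordered by their best (highest-mean) member
    def col_key(col: set[str]) -> tuple:
        idx = min(ordered.index(lv) for lv in col)
        return (idx, tuple(sorted(ordered.index(lv) for lv in col)))

    columns = sorted(columns, key=col_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for letter, col in zip(alphabet, columns):
        for lv in col:
            letters[lv] += letter
    return {lv: "".join(sorted(letters[lv])) for lv in levels}


def anova_tukey(
    values: pd.Series,
    m: SampleMeta,
    alpha: float = 0.05,
    metric: str = "metric",
) -> GroupComparison:
    """One-way ANOVA across levels plus Tukey HSD letters.

    Requires at least two levels with two finite values each.  When all
    observations are identical the F statistic is 0 and every level
    shares the letter ``a``; when groups are internally constant but
    differ, every unequal pair is significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    vals = values.dropna()
    if not np.isfinite(vals.to_numpy()).all():
        raise ValidationError("non-finite metric values")
    lv = m.level_of(vals.index)
    levels = [l for l in m.levels_present() if (lv == l).sum() > 0]
    groups = {l: vals[lv == l].to_numpy() for l in levels}
    if len(groups) < 2:
        raise ValidationError("need >= 2 levels to compare")
    for l, g in groups.items():
        if g.size < 2:
            raise ValidationError(f"level {l!r} has {g.size} value(s); need >= 2")

    means = {l: float(g.mean()) for l, g in groups.items()}
    grand = vals.to_numpy()
    pooled_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())

    if np.ptp(grand) == 0:  # all observations identical
        f_stat, p_val = 0.0, 1.0
        sig_pairs: set[frozenset] = set()
        pair_rows = [
            (a, b, 1.0, False)
            for i, a in enumerate(levels)
            for b in levels[i + 1:]
        ]
    elif pooled_within == 0:  # groups constant but not all equal
        f_stat, p_val = float("inf"), 0.0
        pair_rows = []
        sig_pairs = set()
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                diff = means[a] != means[b]
                pair_rows.append((a, b, 0.0 if diff else 1.0, diff))
                if diff:
                    sig_pairs.add(frozenset((a, b)))
    else:
        f_stat, p_val = stats.f_oneway(*groups.values())
        f_stat, p_val = float(f_stat), float(p_val)
        tk = pairwise_tukeyhsd(
            vals.to_numpy(), lv.to_numpy(), alpha=alpha
        )
        tk_df = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        pair_rows = []
        sig_pairs = set()
        for _, row in tk_df.iterrows():
            a, b, p_adj = str(row["group1"]), str(row["group2"]), float(row["p-adj"])
            sig = p_adj < alpha
            pair_rows.append((a, b, p_adj, sig))
            if sig:
                sig_pairs.add(frozenset((a, b)))

    letters = compact_letter_display(levels, means, sig_pairs, list(m.levels))
    summary = pd.DataFrame(
        {
            "level": levels,
            "n": [groups[l].size for l in levels],
            "mean": [means[l] for l in levels],
            "sd": [float(groups[l].std(ddof=1)) for l in levels],
            "letter": [letters[l] for l in levels],
        }
    )
    pairwise = pd.DataFrame(
        pair_rows, columns=["level_a", "level_b", "p_adj", "significant"]
    )
    return GroupComparison(
        metric=metric,
        summary=summary,
        f_statistic=f_stat,
        p_value=p_val,
        pairwise=pairwise,
        alpha=alpha,
    )
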