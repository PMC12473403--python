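"""Specificity-occupancy (SPEC-OCCU) indicator species analysis.

Specificity of species S at disturbance level H is the share of its
across-level mean abundance concentrated at H::

    specificity(S, H) = mean_H(S) / sum_L mean_L(S)

where the per-level mean includes zero-abundance quadrats, so the values
sum to one over levels for every species with positive total abundance.
Occupancy is the fraction of the level's quadrats where the species
occurs.  A species is an indicator of a level when both values reach the
dual threshold (0.4 by default, inclusive).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMeta, ValidationError

__all__ = [
    "SpecOccuTable",
    "specificity",
    "occupancy",
    "spec_occu_table",
    "identify_indicators",
]

DEFAULT_INDICATOR_THRESHOLD = 0.4


@dataclass(frozen=True)
class SpecOccuTable:
    """Long-format per (species, level) specificity/occupancy table."""

    #: columns: species, level, specificity, occupancy, indicator
    data: pd.DataFrame
    threshold: float = DEFAULT_INDICATOR_THRESHOLD

    def flagged(self) -> pd.DataFrame:
        """The indicator subset (species, level, specificity, occupancy)."""
        return self.data[self.data["indicator"]].reset_index(drop=True)

    def coordinates(self, level: str) -> pd.DataFrame:
        """(occupancy, specificity) plot coordinates for one level
        (occupancy on the x-axis)."""
        sub = self.data[self.data["level"] == level]
        return sub[["species", "occupancy", "specificity", "indicator"]].reset_index(drop=True)


def _level_blocks(t: AbundanceTable, m: SampleMeta):
    m.check_covers(t)
    lv = m.level_of(t.sample_ids)
    for level in m.levels_present():
        samples = [s for s in t.sample_ids if lv[s] == level]
        if len(samples) == 0:
            raise ValidationError(f"level {level!r} has no samples")
        yield level, t.data.loc[samples]


def _drop_zero_total(t: AbundanceTable) -> AbundanceTable:
    totals = t.data.sum(axis=0)
    empty = totals.index[totals == 0]
    if len(empty):
        warnings.warn(
            f"excluding {len(empty)} zero-abundance species from "
            f"specificity: {list(empty)}",
            stacklevel=3,
        )
        t = replace(t, data=t.data.drop(columns=empty))
    return t


def specificity(t: AbundanceTable, m: SampleMeta) -> pd.DataFrame:
    """Species x level specificity matrix; rows sum to one."""
    t = _drop_zero_total(t)
    means = {}
    for level, block in _level_blocks(t, m):
        means[level] = block.mean(axis=0)
    mat = pd.DataFrame(means)  # species x level
    return mat.div(mat.sum(axis=1), axis=0)


def occupancy(t: AbundanceTable, m: SampleMeta) -> pd.DataFrame:
    """Species x level occupancy: fraction of the level's quadrats where
    the species is present."""
    occ = {}
    for level, block in _level_blocks(t, m):
        occ[level] = (block > 0).mean(axis=0)
    return pd.DataFrame(occ)


def spec_occu_table(
    t: AbundanceTable,
    m: SampleMeta,
    threshold: float = DEFAULT_INDICATOR_THRESHOLD,
) -> SpecOccuTable:
    """Combine specificity and occupancy into the long indicator table."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    spec = specificity(t, m)
    occ = occupancy(t, m).reindex(index=spec.index)
    rows = []
    for level in spec.columns:
        for sp in spec.index:
            s, o = spec.at[sp, level], occ.at[sp, level]
            rows.append((sp, level, s, o, bool(s >= threshold and o >= threshold)))
    df = pd.DataFrame(
        rows, columns=["species", "level", "specificity", "occupancy", "indicator"]
    )
    return SpecOccuTable(df, threshold=threshold)


def identify_indicators(
    s: SpecOccuTable, threshold: float | None = None
) -> SpecOccuTable:
    """Re-apply the dual threshold (inclusive ``>=`` on both axes).

    Raising the threshold never enlarges the flagged set.
    """
    if threshold is None:
        threshold = s.threshold
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    df = s.data.copy()
    df["indicator"] = (df["specificity"] >= threshold) & (df["occupancy"] >= threshold)
    return SpecOccuTable(df, threshold=threshold)
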