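"""Co-occurrence cohesion: abundance-weighted mean significant correlations.

Each species *i* receives a connectedness pair (rbar_i+, rbar_i-): the
mean of its statistically significant positive (negative) Pearson
correlations with all other species, computed once on the pooled dataset.
Sample-level cohesion then weights these by relative abundance::

    C+_j = sum_i p_ij * rbar_i+        C-_j = sum_i p_ij * rbar_i-

On row-proportion abundances C+ lies in [0, 1] and C- in [-1, 0].  Two
derived quantities summarise the association structure per sample: total
cohesion |C+| + |C-| and the network-stability ratio |C-| / C+ (higher
ratios indicate a larger share of segregating associations, read as less
stochastic assembly).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, SampleMeta, ValidationError

__all__ = [
    "CorrelationStructure",
    "CohesionResult",
    "correlation_structure",
    "sample_cohesion",
    "cohesion_by_level",
]


@dataclass(frozen=True)
class CorrelationStructure:
    """Pairwise Pearson structure with a significance mask at ``alpha``."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    #: per-species mean significant positive correlation (0 if none)
    r_pos_mean: pd.Series
    #: per-species mean significant negative correlation (0 if none)
    r_neg_mean: pd.Series
    n_samples: int
    alpha: float


@dataclass(frozen=True)
class CohesionResult:
    """Per-sample cohesion metrics.

    ``per_sample`` columns: positive, negative, total, neg_pos_ratio
    (NaN where positive cohesion is zero) and network_stability (the
    signed ratio, ``-|C-|/C+``).
    """

    per_sample: pd.DataFrame
    structure: CorrelationStructure


def correlation_structure(t: AbundanceTable, alpha: float = 0.05) -> CorrelationStructure:
    """All-pairs Pearson r with two-sided t-test p-values.

    Computed on the pooled dataset (all levels together).  Pairs where
    either species has zero variance are excluded from the means; a
    species with no significant partner of a given sign gets 0 for that
    mean.  No multiple-testing correction is applied: the mask is the
    plain ``p < alpha`` rule.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    x = t.data.to_numpy()
    n, s = x.shape
    if n < 3:
        raise ValidationError(f"need >= 3 samples for correlations, got {n}")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise ValidationError("all species have zero variance")
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance species excluded from "
            "correlation means",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, np.nan)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[np.abs(r) == 1.0] = 0.0  # exact collinearity
    p[np.isnan(r)] = np.nan

    sig = (p < alpha) & ~np.isnan(r)
    if alpha == 1.0:  # degenerate screen: every finite pair passes
        sig = ~np.isnan(r)

    pos = np.where(sig & (r > 0), r, np.nan)
    neg = np.where(sig & (r < 0), r, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        r_pos = np.nan_to_num(np.nanmean(pos, axis=1))
        r_neg = np.nan_to_num(np.nanmean(neg, axis=1))

    sp = t.species_ids
    return CorrelationStructure(
        r=pd.DataFrame(r, index=sp, columns=sp),
        p=pd.DataFrame(p, index=sp, columns=sp),
        significant=pd.DataFrame(sig, index=sp, columns=sp),
        r_pos_mean=pd.Series(r_pos, index=sp, name="r_pos_mean"),
        r_neg_mean=pd.Series(r_neg, index=sp, name="r_neg_mean"),
        n_samples=n,
        alpha=alpha,
    )


def sample_cohesion(t: AbundanceTable, c: CorrelationStructure) -> CohesionResult:
    """Cohesion scores for every sample of a row-proportion table.

    ``t`` must hold relative abundances (rows summing to one); this is
    what guarantees the documented bounds C+ in [0, 1], C- in [-1, 0].
    Use :func:`commstab.tables.to_relative` first.
    """
    rowsum = t.data.sum(axis=1).to_numpy()
    if not np.allclose(rowsum, 1.0, atol=1e-8):
        raise ValidationError(
            "sample_cohesion expects row-proportion abundances; "
            "apply to_relative() first"
        )
    missing = set(t.species_ids) - set(c.r_pos_mean.index)
    if missing:
        raise ValidationError(f"species absent from correlation structure: {sorted(map(str, missing))}")

    p = t.data.to_numpy()
    rpos = c.r_pos_mean.reindex(t.species_ids).to_numpy()
    rneg = c.r_neg_mean.reindex(t.species_ids).to_numpy()
    cpos = p @ rpos
    cneg = p @ rneg
    total = np.abs(cpos) + np.abs(cneg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cpos > 0, np.abs(cneg) / cpos, np.nan)

    out = pd.DataFrame(
        {
            "positive": cpos,
            "negative": cneg,
            "total": total,
            "neg_pos_ratio": ratio,
            "network_stability": -ratio,
        },
        index=t.data.index,
    )
    return CohesionResult(per_sample=out, structure=c)


def cohesion_by_level(r: CohesionResult, m: SampleMeta) -> pd.DataFrame:
    """Per-level summary (n, mean, sd, median) of the four cohesion
    metrics; grouping only, no recomputation."""
    df = r.per_sample.copy()
    missing = set(df.index) - set(m.data.index)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(map(str, missing))}")
    df["level"] = m.level_of(df.index).to_numpy()
    metrics = ["positive", "negative", "total", "neg_pos_ratio"]
    pieces = []
    for metric in metrics:
        g = df.groupby("level", sort=False)[metric].agg(["count", "mean", "std", "median"])
        g.insert(0, "metric", metric)
        pieces.append(g)
    out = pd.concat(pieces).reset_index().rename(columns={"count": "n"})
    order = {lv: i for i, lv in enumerate(m.levels)}
    return out.sort_values(["metric", "level"], key=lambda s: s.map(order) if s.name == "level" else s).reset_index(drop=True)
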