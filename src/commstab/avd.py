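"""Average variation degree (AVD) compositional stability.

For each disturbance level the variation degree of species *i* in sample
*j* is the standardized absolute deviation

    a_ij = |x_ij - xbar_i| / delta_i

where the mean and standard deviation are taken over the samples of that
level only.  The level AVD averages ``a`` over the K samples and the n
species scoped to the level (species with positive total abundance
there), and stability is reported as ``1 - AVD``: a community whose
species abundances fluctuate little around their within-level means is
compositionally stable.

A per-sample stability (one minus the sample's mean variation degree) is
also exposed as the replicate unit for group comparisons; its across-
sample mean within a level equals the level value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMeta, ValidationError

__all__ = ["VariationDegreeResult", "variation_degree", "level_avd", "sample_stability"]


@dataclass(frozen=True)
class VariationDegreeResult:
    """Variation degrees with their per-sample and per-level aggregates."""

    #: long table: sample, level, species, a
    per_sample_species: pd.DataFrame
    #: per-sample mean variation degree (over the level's species scope)
    sample_mean: pd.Series
    #: per-sample stability, 1 - mean variation degree
    per_sample_stability: pd.Series
    #: per-level AVD = sum(a) / (K * n)
    per_level_avd: pd.Series
    #: per-level stability, 1 - AVD
    per_level_stability: pd.Series
    #: per-level species scope size n and sample count K
    level_n_species: pd.Series
    level_n_samples: pd.Series


def variation_degree(t: AbundanceTable, m: SampleMeta) -> VariationDegreeResult:
    """Compute variation degrees and AVD stability per level.

    Species are scoped per level to those with positive total abundance at
    that level, so species absent from a level do not dilute its species
    count.  The standard deviation uses the n-1 denominator; a species
    that is constant within a level has zero deviation for every sample
    (``a = 0``), which is the only value consistent with ``x = xbar``.

    Raises
    ------
    ValidationError
        If any level has fewer than two samples.
    """
    m.check_covers(t)
    sample_level = m.level_of(t.sample_ids)
    rows = []
    level_avd_, level_stab, level_ns, level_ks = {}, {}, {}, {}
    sample_means = {}

    for level in m.levels_present():
        samples = [s for s in t.sample_ids if sample_level[s] == level]
        if len(samples) < 2:
            raise ValidationError(
                f"level {level!r} has {len(samples)} sample(s); need >= 2"
            )
        block = t.data.loc[samples]
        scope = block.columns[block.sum(axis=0) > 0]
        if len(scope) == 0:
            raise ValidationError(f"level {level!r} has no species present")
        x = block[scope].to_numpy()
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.abs(x - mean) / sd
        a[:, sd == 0] = 0.0

        for si, sample in enumerate(samples):
            sample_means[sample] = a[si].mean()
            for sj, sp in enumerate(scope):
                rows.append((sample, level, sp, a[si, sj]))

        avd = a.sum() / (len(samples) * len(scope))
        level_avd_[level] = avd
        level_stab[level] = 1.0 - avd
        level_ns[level] = len(scope)
        level_ks[level] = len(samples)

    long = pd.DataFrame(rows, columns=["sample", "level", "species", "a"])
    order = m.levels_present()
    sample_mean = pd.Series(sample_means).reindex(t.sample_ids).rename("mean_a")
    return VariationDegreeResult(
        per_sample_species=long,
        sample_mean=sample_mean,
        per_sample_stability=(1.0 - sample_mean).rename("stability"),
        per_level_avd=pd.Series(level_avd_).reindex(order).rename("AVD"),
        per_level_stability=pd.Series(level_stab).reindex(order).rename("stability"),
        level_n_species=pd.Series(level_ns).reindex(order).rename("n_species"),
        level_n_samples=pd.Series(level_ks).reindex(order).rename("n_samples"),
    )


def level_avd(v: VariationDegreeResult) -> pd.Series:
    """Per-level AVD (lower = more stable)."""
    return v.per_level_avd


def sample_stability(v: VariationDegreeResult) -> pd.Series:
    """Per-sample stability ``1 - mean_i(a_ij)``, the replicate unit for
    across-level comparisons."""
    return v.per_sample_stability
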