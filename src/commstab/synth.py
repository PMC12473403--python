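"""Synthetic relevé generator with retrievable ground truth.

Emulates a five-level disturbance-gradient study: each level holds
``plots_per_level x points_per_plot`` quadrats (3 x 5 = 15 by default, 75
samples in all) sampled from a regional pool whose expected abundances
follow a lognormal rank-abundance curve.

Two per-level dispersion components define the stability gradient and
are the ground truth the AVD analysis should recover:

* **patchiness** -- the probability that a species which belongs to a
  level is nevertheless absent from a given quadrat.  Presence
  instability is the dominant driver of compositional variation degree:
  a species blinking in and out of quadrats has a large standardized
  absolute deviation, whereas pure multiplicative noise changes the
  spread and the standard deviation together and so moves the
  standardized deviation only weakly.
* **sigma** -- the lognormal sd of quadrat-to-quadrat abundance noise,
  which controls the coefficient of variation of counts and, near full
  occupancy, the residual variation degree.

Both decrease monotonically from no disturbance to extreme disturbance
in the default scenario, so true compositional stability increases
strictly along the gradient.

On top of this baseline the scenario plants indicator species (target
specificity/occupancy at one level), injects correlated species pairs
through a shared latent Gaussian factor, and generates environmental
covariates with level-dependent means, of which a chosen subset is
causally linked to the latent stability axis.  Everything is a
deterministic function of (scenario, seed): each (level, species) pair
draws from its own seeded stream, so adding species to the pool does not
perturb existing draws.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import (
    DEFAULT_LEVELS,
    DEFAULT_QUADRAT_AREA,
    AbundanceTable,
    EnvTable,
    SampleMeta,
    vegetation_covariates,
)

__all__ = [
    "PlantedIndicator",
    "CorrelatedPair",
    "EnvEffect",
    "SyntheticScenario",
    "GroundTruth",
    "default_scenario",
    "simulate",
]


class ScenarioError(ValueError):
    """The scenario is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class PlantedIndicator:
    """A species engineered to be an indicator of one level.

    ``specificity``/``occupancy`` are the targets the realized tables
    should meet; with both equal to 1 the species is forced to occur in
    every quadrat of its level and nowhere else, so the realized values
    are exact.
    """

    species: str
    level: str
    specificity: float = 0.85
    occupancy: float = 0.93
    mean_abundance: float = 8.0


@dataclass(frozen=True)
class CorrelatedPair:
    """Two species coupled through a shared latent Gaussian factor.

    ``sign`` is +1 or -1; ``strength`` is the latent correlation (|rho|
    < 1).  ``levels`` optionally restricts both species to a subset of
    levels (absent elsewhere); ``sigma`` optionally overrides the level
    abundance-noise scale -- negative pairs use a large value so the
    within-level anticorrelation dominates the joint-presence (positive)
    component of the pooled correlation.
    """

    species_a: str
    species_b: str
    sign: int
    strength: float = 0.7
    levels: tuple[str, ...] | None = None
    sigma: float | None = None
    mean_abundance: float = 6.0


@dataclass(frozen=True)
class EnvEffect:
    """How one covariate is generated.

    ``level_shifts`` adds a per-level mean offset; ``stability_link``
    couples the covariate to the standardized latent stability axis
    (level stability plus per-sample jitter), giving driver analyses an
    unambiguous causal ground truth; ``noise_sd`` is i.i.d. Gaussian.
    """

    base: float
    level_shifts: tuple[float, ...] | None = None
    stability_link: float = 0.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class SyntheticScenario:
    levels: tuple[str, ...] = DEFAULT_LEVELS
    plots_per_level: int = 3
    points_per_plot: int = 5
    n_species: int = 40
    #: lognormal rank-abundance baseline: log-mean and log-sd of expected
    #: per-quadrat abundance across ranks
    sad_meanlog: float = 1.0
    sad_sdlog: float = 1.1
    #: per-level lognormal abundance-noise sd (decreasing = stabler)
    level_sigma: tuple[float, ...] = (0.35, 0.33, 0.30, 0.22, 0.10)
    #: per-level probability that a member species misses a quadrat
    level_patchiness: tuple[float, ...] = (0.44, 0.32, 0.20, 0.10, 0.02)
    planted_indicators: tuple[PlantedIndicator, ...] = ()
    correlated_pairs: tuple[CorrelatedPair, ...] = ()
    env_effects: Mapping[str, EnvEffect] = field(default_factory=dict)
    #: sd of the per-sample jitter on the latent stability axis
    axis_jitter: float = 0.3
    quadrat_area: float = DEFAULT_QUADRAT_AREA
    seed: int = 0

    @property
    def samples_per_level(self) -> int:
        return self.plots_per_level * self.points_per_plot

    @property
    def n_samples(self) -> int:
        return self.samples_per_level * len(self.levels)

    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def validate(self) -> None:
        L = len(self.levels)
        if L < 2 or len(set(self.levels)) != L:
            raise ScenarioError("levels must be >= 2 unique labels")
        if self.plots_per_level < 1 or self.points_per_plot < 1:
            raise ScenarioError("plots_per_level and points_per_plot must be >= 1")
        if len(self.level_sigma) != L or len(self.level_patchiness) != L:
            raise ScenarioError("level_sigma/level_patchiness must match levels")
        if any(s <= 0 for s in self.level_sigma):
            raise ScenarioError("level_sigma values must be > 0")
        if any(not 0 <= p < 1 for p in self.level_patchiness):
            raise ScenarioError("level_patchiness values must be in [0, 1)")
        pool = set(self.species_ids())
        planted = [pi.species for pi in self.planted_indicators]
        if len(set(planted)) != len(planted):
            raise ScenarioError("a species may be planted as indicator once only")
        for pi in self.planted_indicators:
            if pi.species not in pool:
                raise ScenarioError(f"indicator species {pi.species!r} not in pool")
            if pi.level not in self.levels:
                raise ScenarioError(f"indicator level {pi.level!r} unknown")
            if not 0 < pi.specificity <= 1 or not 0 < pi.occupancy <= 1:
                raise ScenarioError(
                    f"indicator {pi.species!r}: targets must be in (0, 1]"
                )
            if pi.mean_abundance < 1:
                raise ScenarioError("indicator mean_abundance must be >= 1")
        paired: list[str] = []
        for cp in self.correlated_pairs:
            if cp.sign not in (-1, 1):
                raise ScenarioError("pair sign must be +1 or -1")
            if not 0 < cp.strength < 1:
                raise ScenarioError("pair strength must satisfy 0 < |rho| < 1")
            if cp.species_a == cp.species_b:
                raise ScenarioError("a pair needs two distinct species")
            for sp in (cp.species_a, cp.species_b):
                if sp not in pool:
                    raise ScenarioError(f"pair species {sp!r} not in pool")
                if sp in planted:
                    raise ScenarioError(
                        f"species {sp!r} cannot be both indicator and pair member"
                    )
                paired.append(sp)
            if cp.levels is not None:
                unknown = set(cp.levels) - set(self.levels)
                if unknown:
                    raise ScenarioError(f"pair levels {sorted(unknown)} unknown")
                if len(cp.levels) == 0:
                    raise ScenarioError("pair levels may not be empty")
        if len(set(paired)) != len(paired):
            raise ScenarioError("a species may belong to one correlated pair only")
        for name, eff in self.env_effects.items():
            if eff.level_shifts is not None and len(eff.level_shifts) != L:
                raise ScenarioError(f"covariate {name!r}: level_shifts length != levels")
            if eff.noise_sd < 0:
                raise ScenarioError(f"covariate {name!r}: noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    #: levels ordered from most to least dispersed (true stability
    #: increases along this order)
    dispersion_order: tuple[str, ...]
    planted_indicators: tuple[PlantedIndicator, ...]
    correlated_pairs: tuple[CorrelatedPair, ...]
    #: covariates causally linked to the stability axis
    linked_covariates: tuple[str, ...]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The reference study design: 5 levels x 3 plots x 5 points,
    a 40-species pool, dispersion strictly decreasing toward extreme
    disturbance, two planted indicators per level, three positive and
    three negative correlated pairs (the negative pairs expressed only
    in disturbed levels), and SBD/SW linked to the stability axis."""
    levels = DEFAULT_LEVELS
    species = [f"sp{i + 1:02d}" for i in range(40)]
    # roles by abundance rank: correlated pairs and indicators occupy
    # middle ranks so the community keeps both its dominant species and
    # its rare tail (rare members of stable levels are the strongest
    # carriers of the compositional-stability gradient)
    indicators = tuple(
        PlantedIndicator(species=species[20 + 2 * li + k], level=lv)
        for li, lv in enumerate(levels)
        for k in range(2)
    )
    disturbed = tuple(levels[1:])
    pairs = (
        CorrelatedPair("sp09", "sp10", +1, sigma=0.5),
        CorrelatedPair("sp11", "sp12", +1, sigma=0.5),
        CorrelatedPair("sp13", "sp14", +1, sigma=0.5),
        CorrelatedPair("sp15", "sp16", -1, levels=disturbed, sigma=0.8),
        CorrelatedPair("sp17", "sp18", -1, levels=disturbed, sigma=0.8),
        CorrelatedPair("sp19", "sp20", -1, levels=disturbed, sigma=0.8),
    )
    env = {
        # linked covariates: bulk density rises, moisture falls with the
        # stability axis
        "SBD": EnvEffect(1.10, (0.00, 0.04, 0.08, 0.12, 0.16), stability_link=0.08, noise_sd=0.05),
        "SW": EnvEffect(24.0, (0.0, -1.0, -2.0, -3.0, -4.0), stability_link=-1.5, noise_sd=1.2),
        "ST": EnvEffect(8.5, (0.0, 0.3, 0.6, 0.9, 1.2), noise_sd=0.8),
        "SC": EnvEffect(380.0, (0.0, 30.0, 60.0, 90.0, 120.0), noise_sd=40.0),
        "SOC": EnvEffect(42.0, (0.0, -2.0, -4.0, -6.0, -8.0), noise_sd=4.0),
        "TN": EnvEffect(3.8, (0.0, -0.2, -0.4, -0.6, -0.8), noise_sd=0.4),
        "TP": EnvEffect(0.80, None, noise_sd=0.08),
        "TK": EnvEffect(18.0, None, noise_sd=1.5),
        "pH": EnvEffect(7.2, (0.0, 0.05, 0.10, 0.15, 0.20), noise_sd=0.15),
        "AP": EnvEffect(6.5, None, noise_sd=0.9),
        "NON": EnvEffect(12.0, (0.0, 1.0, 2.0, 3.0, 4.0), noise_sd=1.8),
        "NHN": EnvEffect(8.0, None, noise_sd=1.2),
        "AGB": EnvEffect(220.0, (0.0, -25.0, -50.0, -75.0, -100.0), noise_sd=25.0),
        "BGB": EnvEffect(1600.0, (0.0, -150.0, -300.0, -450.0, -600.0), noise_sd=180.0),
    }
    return SyntheticScenario(
        planted_indicators=indicators,
        correlated_pairs=pairs,
        env_effects=env,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation machinery


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _rank_abundance_means(s: SyntheticScenario) -> np.ndarray:
    """Deterministic lognormal rank-abundance curve (quantile-spaced)."""
    from scipy.stats import norm

    ranks = np.arange(s.n_species)
    z = norm.ppf(1.0 - (ranks + 0.5) / s.n_species)  # descending
    return np.exp(s.sad_meanlog + s.sad_sdlog * z)


def _presence_and_conditional(
    s: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (level, species) presence probability and conditional mean.

    Every species has a membership mean ``mu`` per level: the
    rank-abundance value for ordinary pool species, the pair abundance on
    a pair's allowed levels (zero elsewhere), and for planted indicators
    the target abundance at the planted level plus the cross-level leak
    that realizes the target specificity in expectation.

    Community members (ordinary and pair species) occur with the level
    occupancy ``q = 1 - patchiness`` and conditional count ``max(1, mu)``:
    presence consistency is a property of the level, so rare members of a
    stable level are consistent singletons.  This presence structure, not
    the multiplicative noise, is the dominant control of the variation
    degree.  Indicator leak outside the planted level is instead thinned
    (``p = q * min(1, mu)``) because it must stay rare to honor the
    specificity target; a planted indicator's own level uses the
    occupancy target directly.
    """
    levels, species = list(s.levels), s.species_ids()
    q = np.array([1.0 - s.level_patchiness[i] for i in range(len(levels))])
    mu = pd.DataFrame(
        np.tile(_rank_abundance_means(s), (len(levels), 1)),
        index=levels,
        columns=species,
    )
    for cp in s.correlated_pairs:
        for sp in (cp.species_a, cp.species_b):
            for lv in levels:
                allowed = cp.levels is None or lv in cp.levels
                mu.at[lv, sp] = cp.mean_abundance if allowed else 0.0
    for pi in s.planted_indicators:
        own_w = pi.occupancy * pi.mean_abundance
        others = [lv for lv in levels if lv != pi.level]
        leak_w = own_w * (1.0 - pi.specificity) / pi.specificity / len(others)
        for lv in levels:
            if lv == pi.level:
                mu.at[lv, pi.species] = pi.mean_abundance
            else:
                qi = q[levels.index(lv)]
                mu.at[lv, pi.species] = leak_w / qi if qi > 0 else 0.0

    leak_cells = {
        (lv, pi.species)
        for pi in s.planted_indicators
        for lv in levels
        if lv != pi.level
    }
    p = mu.copy()
    c = mu.copy()
    for i, lv in enumerate(levels):
        mv = mu.loc[lv].to_numpy()
        thin = np.array([(lv, sp) in leak_cells for sp in species])
        pv = np.where(thin, q[i] * np.minimum(1.0, mv), q[i] * (mv > 0))
        p.loc[lv] = pv
        c.loc[lv] = np.maximum(1.0, mv) * (mv > 0)
    for pi in s.planted_indicators:
        p.at[pi.level, pi.species] = pi.occupancy
        c.at[pi.level, pi.species] = pi.mean_abundance
    return p, c


def _species_sigma(s: SyntheticScenario) -> dict[str, float | None]:
    """Per-species noise-scale override (pairs use their own sigma)."""
    out: dict[str, float | None] = {sp: None for sp in s.species_ids()}
    for cp in s.correlated_pairs:
        out[cp.species_a] = cp.sigma
        out[cp.species_b] = cp.sigma
    return out


def simulate(
    s: SyntheticScenario, seed: int | None = None
) -> tuple[AbundanceTable, SampleMeta, EnvTable, GroundTruth]:
    """Draw one realization of the scenario.

    Counts are ``round(lognormal(log c, sigma))`` with a floor of one,
    multiplied by a Bernoulli presence mask, so the presence mask is the
    only source of zeros.  Correlated pairs share a per-sample latent
    factor entering their log-abundance with loadings of the requested
    signs.  Returns the abundance, metadata and environment tables plus
    the planted :class:`GroundTruth`.
    """
    s.validate()
    if seed is None:
        seed = s.seed
    levels, species = list(s.levels), s.species_ids()
    nl, ns, k = len(levels), len(species), s.samples_per_level

    sample_ids, plot_ids, point_ids, level_col = [], [], [], []
    for lv in levels:
        for plot in range(1, s.plots_per_level + 1):
            for point in range(1, s.points_per_plot + 1):
                sample_ids.append(f"{lv}-p{plot}-q{point}")
                plot_ids.append(f"{lv}-p{plot}")
                point_ids.append(f"q{point}")
                level_col.append(lv)

    pres, cond = _presence_and_conditional(s)
    sp_sigma = _species_sigma(s)

    # latent factors for correlated pairs: one stream per pair over all samples
    pair_latent = {
        idx: _rng(seed, 1, idx).standard_normal(s.n_samples)
        for idx in range(len(s.correlated_pairs))
    }
    pair_role: dict[str, tuple[int, int]] = {}
    for idx, cp in enumerate(s.correlated_pairs):
        pair_role[cp.species_a] = (idx, +1)
        pair_role[cp.species_b] = (idx, cp.sign)

    counts = np.zeros((s.n_samples, ns))
    for li, lv in enumerate(levels):
        sigma_lv = s.level_sigma[li]
        row0 = li * k
        for si, sp in enumerate(species):
            p = pres.at[lv, sp]
            if p == 0:
                continue
            rng = _rng(seed, 0, li, si)
            mask = rng.random(k) < p
            z = rng.standard_normal(k)
            sigma = sp_sigma[sp] or sigma_lv
            if sp in pair_role:
                idx, sign = pair_role[sp]
                g = pair_latent[idx][row0:row0 + k]
                rho = s.correlated_pairs[idx].strength
                z = sign * np.sqrt(rho) * g + np.sqrt(1.0 - rho) * z
            raw = np.exp(np.log(cond.at[lv, sp]) + sigma * z)
            counts[row0:row0 + k, si] = np.maximum(1.0, np.round(raw)) * mask

    abundance = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=species),
        quadrat_area=s.quadrat_area,
    )
    meta = SampleMeta(
        pd.DataFrame(
            {"level": level_col, "plot": plot_ids, "point": point_ids},
            index=sample_ids,
        ),
        levels=tuple(levels),
    )

    # latent stability axis: z-scored total dispersion per level + jitter
    disp = np.asarray(s.level_patchiness) + np.asarray(s.level_sigma)
    axis_level = -(disp - disp.mean()) / (disp.std() if disp.std() > 0 else 1.0)
    axis = np.repeat(axis_level, k) + s.axis_jitter * _rng(seed, 3).standard_normal(
        s.n_samples
    )

    env_cols = {}
    for ci, (name, eff) in enumerate(s.env_effects.items()):
        noise = _rng(seed, 2, ci).standard_normal(s.n_samples)
        shifts = (
            np.repeat(np.asarray(eff.level_shifts, dtype=float), k)
            if eff.level_shifts is not None
            else 0.0
        )
        env_cols[name] = eff.base + shifts + eff.stability_link * axis + eff.noise_sd * noise
    env_df = pd.DataFrame(env_cols, index=sample_ids)
    env_df = pd.concat([env_df, vegetation_covariates(abundance)], axis=1)
    env = EnvTable(env_df, derived=("SR", "PD", "EVEN"))

    by_dispersion = sorted(range(nl), key=lambda i: (-disp[i], i))
    truth = GroundTruth(
        dispersion_order=tuple(levels[i] for i in by_dispersion),
        planted_indicators=s.planted_indicators,
        correlated_pairs=s.correlated_pairs,
        linked_covariates=tuple(
            n for n, e in s.env_effects.items() if e.stability_link != 0
        ),
        seed=seed,
    )
    return abundance, meta, env, truth
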