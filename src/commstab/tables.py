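"""Data containers, delimited-text I/O and derived vegetation metrics.

The central object is the :class:`AbundanceTable`, a samples x species
matrix of non-negative counts (individuals per quadrat).  Samples are
grouped by an ordered disturbance level through :class:`SampleMeta`, and
per-sample environmental covariates live in :class:`EnvTable`.  All three
are thin, validated wrappers around :class:`pandas.DataFrame` and
round-trip losslessly through delimited text.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LEVELS",
    "DEFAULT_QUADRAT_AREA",
    "SOIL_VARIABLES",
    "VEGETATION_VARIABLES",
    "DERIVED_VARIABLES",
    "ENV_ALIASES",
    "ValidationError",
    "AbundanceTable",
    "SampleMeta",
    "EnvTable",
    "read_abundance",
    "write_abundance",
    "read_sample_meta",
    "write_sample_meta",
    "read_env",
    "write_env",
    "to_relative",
    "species_richness",
    "plant_density",
    "camargo_evenness",
    "vegetation_covariates",
]

#: Ordered disturbance levels: no / light / moderate / heavy / extreme.
DEFAULT_LEVELS: tuple[str, ...] = ("ND", "LD", "MD", "HD", "ED")

#: Quadrat area in m^2 (a 0.5 m x 0.5 m sampling frame).
DEFAULT_QUADRAT_AREA: float = 0.25

#: Canonical soil covariate names (bulk density, temperature, water,
#: compaction, organic carbon, total N/P/K, pH, available P, nitrate N,
#: ammonium N).
SOIL_VARIABLES: tuple[str, ...] = (
    "SBD", "ST", "SW", "SC", "SOC", "TN", "TP", "TK", "pH", "AP", "NON", "NHN",
)

#: Vegetation covariates: above/belowground biomass, species richness,
#: plant density, Camargo evenness.
VEGETATION_VARIABLES: tuple[str, ...] = ("AGB", "BGB", "SR", "PD", "EVEN")

#: Covariates recomputable from the abundance table itself.
DERIVED_VARIABLES: tuple[str, ...] = ("SR", "PD", "EVEN")

#: Accepted label aliases -> canonical names.
ENV_ALIASES: dict[str, str] = {"MHN": "NHN", "RGB": "BGB"}


class ValidationError(ValueError):
    """A table violates a structural invariant (ids, signs, shapes)."""


def _check_unique(ids: Iterable, what: str) -> None:
    ids = list(ids)
    seen: set = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise ValidationError(f"duplicate {what} ids: {sorted(set(map(str, dups)))}")


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x species matrix of non-negative abundances.

    Parameters
    ----------
    data
        DataFrame with one row per sample and one column per species;
        values are individuals per quadrat (non-negative, finite).
    quadrat_area
        Quadrat area in m^2 used by :func:`plant_density`.
    """

    data: pd.DataFrame
    quadrat_area: float = DEFAULT_QUADRAT_AREA

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ValidationError(
                f"need >= 2 samples and >= 1 species, got {df.shape}"
            )
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "species")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundances must be numeric")
        if not np.isfinite(values).all():
            bad = df.columns[np.argwhere(~np.isfinite(values))[0][1]]
            raise ValidationError(f"non-finite abundance (e.g. species {bad!r})")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[i]!r}, "
                f"species {df.columns[j]!r}"
            )
        if self.quadrat_area <= 0:
            raise ValidationError("quadrat_area must be > 0")
        # normalize dtype so round-trips are stable
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def drop_empty_species(self, strict: bool = False) -> "AbundanceTable":
        """Remove all-zero species columns (``strict=True`` rejects instead).

        Empty columns are undefined for correlation and specificity and are
        dropped with a warning by default.
        """
        empty = self.data.columns[(self.data.sum(axis=0) == 0)]
        if len(empty) == 0:
            return self
        if strict:
            raise ValidationError(f"all-zero species columns: {list(empty)}")
        warnings.warn(
            f"dropping {len(empty)} all-zero species column(s): {list(empty)}",
            stacklevel=2,
        )
        return replace(self, data=self.data.drop(columns=empty))

    def subset_samples(self, sample_ids: Sequence) -> "AbundanceTable":
        return replace(self, data=self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class SampleMeta:
    """Sample -> (disturbance level, plot, point) mapping.

    ``levels`` declares the total order of the disturbance gradient; every
    level appearing in ``data`` must be listed.
    """

    data: pd.DataFrame  # index: sample_id; columns: level, plot, point
    levels: tuple[str, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        df = self.data
        for col in ("level", "plot", "point"):
            if col not in df.columns:
                raise ValidationError(f"sample metadata missing column {col!r}")
        _check_unique(df.index, "sample")
        unknown = set(df["level"]) - set(self.levels)
        if unknown:
            raise ValidationError(
                f"levels {sorted(unknown)} not in declared order {self.levels}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def level_of(self, sample_ids: Sequence | None = None) -> pd.Series:
        s = self.data["level"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def samples_at(self, level: str) -> list:
        return list(self.data.index[self.data["level"] == level])

    def check_covers(self, table: AbundanceTable) -> None:
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(map(str, missing))}")

    def levels_present(self) -> list[str]:
        present = set(self.data["level"])
        return [lv for lv in self.levels if lv in present]


@dataclass(frozen=True)
class EnvTable:
    """Per-sample numeric covariates (soil and vegetation attributes).

    ``derived`` names columns that are recomputable from the abundance
    table (SR, PD, EVEN); :func:`vegetation_covariates` produces them.
    """

    data: pd.DataFrame
    derived: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.data.rename(columns=ENV_ALIASES)
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "covariate")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
            raise ValidationError(f"non-numeric covariates: {bad}")
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"missing/non-finite value for covariate {df.columns[j]!r} "
                f"at sample {df.index[i]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def covariates(self) -> list:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _read_delim(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index.name = None
    return df


def read_abundance(
    path: str | Path,
    orientation: str = "samples",
    quadrat_area: float = DEFAULT_QUADRAT_AREA,
    drop_empty_species: bool = True,
    strict: bool = False,
) -> AbundanceTable:
    """Read a delimited abundance table.

    ``orientation`` is ``"samples"`` when rows are samples (the native
    layout) or ``"species"`` when rows are species (transposed on read).
    """
    if orientation not in {"samples", "species"}:
        raise ValueError("orientation must be 'samples' or 'species'")
    df = _read_delim(path)
    if df.size == 0:
        raise ValidationError(f"empty abundance table: {path}")
    if orientation == "species":
        df = df.T
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    t = AbundanceTable(df, quadrat_area=quadrat_area)
    if drop_empty_species or strict:
        t = t.drop_empty_species(strict=strict)
    return t


def write_abundance(t: AbundanceTable, path: str | Path, sep: str = ",") -> None:
    t.data.to_csv(path, sep=sep, index_label="sample")


def read_sample_meta(
    path: str | Path, levels: Sequence[str] | None = None
) -> SampleMeta:
    """Read sample metadata; ``levels`` fixes the gradient order (defaults
    to the standard five-level order when all observed levels belong to it,
    otherwise to first-appearance order)."""
    df = _read_delim(path)
    df.columns = [c.lower() for c in df.columns]
    if levels is None:
        observed = list(dict.fromkeys(df["level"]))
        if set(observed) <= set(DEFAULT_LEVELS):
            levels = DEFAULT_LEVELS
        else:
            levels = tuple(observed)
    return SampleMeta(df, levels=tuple(levels))


def write_sample_meta(m: SampleMeta, path: str | Path, sep: str = ",") -> None:
    m.data.to_csv(path, sep=sep, index_label="sample")


def read_env(path: str | Path, derived: Sequence[str] = ()) -> EnvTable:
    df = _read_delim(path)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric covariate cell in {path}: {exc}") from exc
    return EnvTable(df, derived=tuple(derived))


def write_env(e: EnvTable, path: str | Path, sep: str = ",") -> None:
    e.data.to_csv(path, sep=sep, index_label="sample")


# ---------------------------------------------------------------------------
# derived per-sample vegetation metrics


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Row-proportion abundances; every sample row sums to one."""
    totals = t.data.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample row(s): {list(zero)}")
    return replace(t, data=t.data.div(totals, axis=0))


def species_richness(t: AbundanceTable) -> pd.Series:
    """Number of species with positive abundance in each sample."""
    return (t.data > 0).sum(axis=1).rename("SR")


def plant_density(t: AbundanceTable) -> pd.Series:
    """Total individuals per m^2 (row total / quadrat area)."""
    return (t.data.sum(axis=1) / t.quadrat_area).rename("PD")


def camargo_evenness(t: AbundanceTable) -> pd.Series:
    """Camargo's pairwise evenness, restricted to species present in the
    sample::

        E = 1 - sum_{i<j} |p_i - p_j| / S

    where ``p`` are the relative abundances of the ``S`` present species.
    ``E`` is 1 exactly when all present species are equally abundant and
    lies in (0, 1]; a sample with no individuals is an error.
    """
    out = {}
    for sample, row in t.data.iterrows():
        x = row.to_numpy()
        x = x[x > 0]
        if x.size == 0:
            raise ValidationError(f"sample {sample!r} has no individuals")
        p = x / x.sum()
        s = p.size
        pair_sum = np.abs(p[:, None] - p[None, :]).sum() / 2.0
        out[sample] = 1.0 - pair_sum / s
    return pd.Series(out, name="EVEN").reindex(t.data.index)


def vegetation_covariates(t: AbundanceTable) -> pd.DataFrame:
    """SR, PD and EVEN for every sample, as an env-table block."""
    return pd.concat(
        [species_richness(t), plant_density(t), camargo_evenness(t)], axis=1
    )
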