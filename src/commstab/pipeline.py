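"""Orchestrate the full analysis as one reproducible run.

``run_all`` executes simulate/load -> AVD stability -> cohesion ->
SPEC-OCCU indicators -> ANOVA/Tukey comparisons -> driver screens and
BRT influence, writing every stage table as delimited text into a fixed
output layout.  A manifest (plain YAML) fully parameterizes the run;
repeating a run with the same manifest reproduces every output
byte-for-byte, because all randomness is re-seeded from the manifest and
no output embeds a timestamp.
"""
from __future__ import annotations

import hashlib
import io
import traceback
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import avd as avd_mod
from . import cohesion as coh_mod
from . import specoccu as so_mod
from .compare import anova_tukey
from .drivers import BRTParams, brt_influence, driver_screen, transition_drivers
from .synth import SyntheticScenario, default_scenario, simulate
from .tables import (
    AbundanceTable,
    EnvTable,
    SampleMeta,
    read_abundance,
    read_env,
    read_sample_meta,
    to_relative,
    vegetation_covariates,
    write_abundance,
    write_env,
    write_sample_meta,
)

__all__ = ["RunManifest", "RunResult", "load_manifest", "run_all"]

TOOL = "commstab"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run.

    Either ``scenario`` (synthetic data, seeded) or the three input
    paths must be provided.  ``seed`` drives both simulation and the
    stochastic parts of the BRT stage.
    """

    output_dir: str = "commstab_run"
    scenario: SyntheticScenario | None = None
    abundance_path: str | None = None
    meta_path: str | None = None
    env_path: str | None = None
    levels: tuple[str, ...] | None = None
    alpha: float = 0.05
    indicator_threshold: float = 0.4
    brt: BRTParams = field(default_factory=BRTParams)
    cohesion_metric: str = "total"  # metric modelled in transition BRTs
    export_matrices: bool = False
    seed: int = 0


@dataclass
class RunResult:
    outputs: dict[str, Path]
    errors: dict[str, str]
    log: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def load_manifest(path: str | Path) -> RunManifest:
    raw = yaml.safe_load(Path(path).read_text())
    brt = BRTParams(**raw.pop("brt", {}))
    scenario = None
    if "scenario" in raw:
        sc = raw.pop("scenario")
        if sc == "default" or sc is None:
            scenario = default_scenario(seed=raw.get("seed", 0))
        else:
            from .synth import CorrelatedPair, EnvEffect, PlantedIndicator

            sc = dict(sc)
            sc["planted_indicators"] = tuple(
                PlantedIndicator(**d) for d in sc.get("planted_indicators", ())
            )
            sc["correlated_pairs"] = tuple(
                CorrelatedPair(**d) for d in sc.get("correlated_pairs", ())
            )
            sc["env_effects"] = {
                k: EnvEffect(**v) for k, v in sc.get("env_effects", {}).items()
            }
            for key in ("levels", "level_sigma", "level_patchiness"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            scenario = SyntheticScenario(**sc)
    if "levels" in raw and raw["levels"] is not None:
        raw["levels"] = tuple(raw["levels"])
    return RunManifest(scenario=scenario, brt=brt, **raw)


def _sha(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, stage: str, params: str, inputs: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL} stage={stage} {params} inputs=sha256:{inputs}\n")
        df.to_csv(fh, index=False)


def run_all(manifest: RunManifest) -> RunResult:
    """Execute every stage in dependency order.

    A failing stage is recorded and skipped; independent stages still
    run.  The result lists outputs, per-stage errors, and a plain-text
    log (counts per stage, no timestamps).
    """
    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    errors: dict[str, str] = {}
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    # ---- inputs ----------------------------------------------------------
    env: EnvTable | None = None
    if manifest.scenario is not None:
        table, meta, env, truth = simulate(manifest.scenario, seed=manifest.seed)
        write_abundance(table, out / "abundance.csv")
        write_sample_meta(meta, out / "sample_meta.csv")
        write_env(env, out / "env.csv")
        (out / "ground_truth.json").write_text(truth.to_json() + "\n")
        outputs["abundance"] = out / "abundance.csv"
        outputs["sample_meta"] = out / "sample_meta.csv"
        outputs["env"] = out / "env.csv"
        outputs["ground_truth"] = out / "ground_truth.json"
        note(f"simulate: {table.data.shape[0]} samples x {table.data.shape[1]} species, seed={manifest.seed}")
    else:
        if manifest.abundance_path is None or manifest.meta_path is None:
            raise ValueError("manifest needs a scenario or abundance/meta paths")
        table = read_abundance(manifest.abundance_path)
        meta = read_sample_meta(manifest.meta_path, levels=manifest.levels)
        if manifest.env_path is not None:
            env = read_env(manifest.env_path)
        note(f"load: {table.data.shape[0]} samples x {table.data.shape[1]} species")
    table = table.drop_empty_species()
    in_hash = _sha(table.data)

    if env is not None:
        derived = vegetation_covariates(table)
        missing = [c for c in derived.columns if c not in env.data.columns]
        if missing:
            env = EnvTable(
                pd.concat([env.data, derived[missing]], axis=1),
                derived=tuple(set(env.derived) | set(missing)),
            )
            note(f"env: derived columns added {missing}")

    # ---- stability (AVD) -------------------------------------------------
    stability = None
    try:
        v = avd_mod.variation_degree(table, meta)
        stability = v.per_sample_stability
        samp = pd.DataFrame(
            {
                "sample": stability.index,
                "level": meta.level_of(stability.index).to_numpy(),
                "stability": stability.to_numpy(),
                "mean_variation_degree": v.sample_mean.to_numpy(),
            }
        )
        lvl = pd.DataFrame(
            {
                "level": v.per_level_avd.index,
                "AVD": v.per_level_avd.to_numpy(),
                "stability": v.per_level_stability.to_numpy(),
                "n_samples": v.level_n_samples.to_numpy(),
                "n_species": v.level_n_species.to_numpy(),
            }
        )
        _write(samp, out / "stability_samples.csv", "avd", "", in_hash)
        _write(lvl, out / "stability_levels.csv", "avd", "", in_hash)
        outputs["stability_samples"] = out / "stability_samples.csv"
        outputs["stability_levels"] = out / "stability_levels.csv"
        cmp_ = anova_tukey(stability, meta, alpha=manifest.alpha, metric="stability")
        _write(
            cmp_.summary.assign(metric="stability", F=cmp_.f_statistic, p=cmp_.p_value),
            out / "stability_anova.csv",
            "compare",
            f"alpha={manifest.alpha}",
            in_hash,
        )
        outputs["stability_anova"] = out / "stability_anova.csv"
        note(f"avd: per-level AVD over {len(lvl)} levels")
    except Exception as exc:  # noqa: BLE001 - stage isolation
        errors["avd"] = f"{exc}\n{traceback.format_exc(limit=2)}"
        note(f"avd: FAILED ({exc})")

    # ---- cohesion --------------------------------------------------------
    cohesion_samples = None
    try:
        rel = to_relative(table)
        structure = coh_mod.correlation_structure(table, alpha=manifest.alpha)
        res = coh_mod.sample_cohesion(rel, structure)
        cohesion_samples = res.per_sample
        df = res.per_sample.reset_index(names="sample")
        df.insert(1, "level", meta.level_of(res.per_sample.index).to_numpy())
        _write(df, out / "cohesion_samples.csv", "cohesion", f"alpha={manifest.alpha}", in_hash)
        lvl = coh_mod.cohesion_by_level(res, meta)
        _write(lvl, out / "cohesion_levels.csv", "cohesion", f"alpha={manifest.alpha}", in_hash)
        outputs["cohesion_samples"] = out / "cohesion_samples.csv"
        outputs["cohesion_levels"] = out / "cohesion_levels.csv"
        if manifest.export_matrices:
            structure.r.to_csv(out / "correlation_r.csv")
            structure.p.to_csv(out / "correlation_p.csv")
            outputs["correlation_r"] = out / "correlation_r.csv"
            outputs["correlation_p"] = out / "correlation_p.csv"
        rows = []
        for metric in ("positive", "negative", "total", "neg_pos_ratio"):
            vals = res.per_sample[metric].dropna()
            if vals.groupby(meta.level_of(vals.index).to_numpy()).size().min() >= 2:
                c = anova_tukey(vals, meta, alpha=manifest.alpha, metric=metric)
                rows.append(c.summary.assign(metric=metric, F=c.f_statistic, p=c.p_value))
        if rows:
            _write(
                pd.concat(rows, ignore_index=True),
                out / "cohesion_anova.csv",
                "compare",
                f"alpha={manifest.alpha}",
                in_hash,
            )
            outputs["cohesion_anova"] = out / "cohesion_anova.csv"
        n_sig = int(structure.significant.to_numpy().sum() // 2)
        note(f"cohesion: {n_sig} significant pairs at alpha={manifest.alpha}")
    except Exception as exc:  # noqa: BLE001
        errors["cohesion"] = f"{exc}\n{traceback.format_exc(limit=2)}"
        note(f"cohesion: FAILED ({exc})")

    # ---- indicators ------------------------------------------------------
    try:
        st = so_mod.spec_occu_table(table, meta, threshold=manifest.indicator_threshold)
        _write(
            st.data,
            out / "spec_occu.csv",
            "indicators",
            f"threshold={manifest.indicator_threshold}",
            in_hash,
        )
        _write(
            st.flagged(),
            out / "indicators.csv",
            "indicators",
            f"threshold={manifest.indicator_threshold}",
            in_hash,
        )
        outputs["spec_occu"] = out / "spec_occu.csv"
        outputs["indicators"] = out / "indicators.csv"
        note(f"indicators: {len(st.flagged())} flagged at threshold {manifest.indicator_threshold}")
    except Exception as exc:  # noqa: BLE001
        errors["indicators"] = f"{exc}\n{traceback.format_exc(limit=2)}"
        note(f"indicators: FAILED ({exc})")

    # ---- drivers ---------------------------------------------------------
    if env is None:
        note("drivers: skipped (no environmental table)")
    elif stability is None or cohesion_samples is None:
        errors["drivers"] = "upstream stability/cohesion unavailable"
        note("drivers: FAILED (missing upstream metrics)")
    else:
        try:
            metrics = pd.DataFrame(
                {
                    "stability": stability,
                    "total_cohesion": cohesion_samples["total"],
                    "neg_pos_ratio": cohesion_samples["neg_pos_ratio"],
                }
            ).dropna(axis=1, how="all")
            screens = [driver_screen(metrics, env, meta, alpha=manifest.alpha, scope="all").data]
            for lv in meta.levels_present():
                screens.append(
                    driver_screen(metrics, env, meta, alpha=manifest.alpha, scope=("level", lv)).data
                )
            _write(
                pd.concat(screens, ignore_index=True),
                out / "driver_screen.csv",
                "drivers",
                f"alpha={manifest.alpha}",
                in_hash,
            )
            outputs["driver_screen"] = out / "driver_screen.csv"

            coh_metric = {"total": "total_cohesion", "ratio": "neg_pos_ratio"}.get(
                manifest.cohesion_metric, "total_cohesion"
            )
            fits = []
            for name in ("stability", coh_metric):
                y = metrics[name].dropna()
                res = brt_influence(
                    y, env, meta, scope="all", params=manifest.brt, seed=manifest.seed
                )
                fits.append((name, res))
                present = meta.levels_present()
                for a, b in zip(present[:-1], present[1:]):
                    res = transition_drivers(
                        y, env, meta, (a, b), params=manifest.brt, seed=manifest.seed
                    )
                    fits.append((name, res))
            rows = []
            for name, res in fits:
                for cov, val in res.influence.items():
                    rows.append((name, res.scope, cov, val, res.n_trees_used, res.n_samples))
            _write(
                pd.DataFrame(
                    rows,
                    columns=["metric", "scope", "covariate", "influence_pct", "n_trees", "n"],
                ),
                out / "brt_influence.csv",
                "drivers",
                f"seed={manifest.seed}",
                in_hash,
            )
            outputs["brt_influence"] = out / "brt_influence.csv"
            note(f"drivers: {len(fits)} BRT fits")
        except Exception as exc:  # noqa: BLE001
            errors["drivers"] = f"{exc}\n{traceback.format_exc(limit=2)}"
            note(f"drivers: FAILED ({exc})")

    # ---- bundle ----------------------------------------------------------
    echo = {
        "tool": TOOL,
        "alpha": manifest.alpha,
        "indicator_threshold": manifest.indicator_threshold,
        "seed": manifest.seed,
        "input_hash": in_hash,
        "scenario": "synthetic" if manifest.scenario is not None else "files",
    }
    (out / "manifest_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    outputs["manifest_echo"] = out / "manifest_echo.yaml"
    outputs["run_log"] = out / "run_log.txt"
    return RunResult(outputs=outputs, errors=errors, log=log)
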