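"""Driver attribution: Pearson screens and boosted-tree relative influence.

Two complementary views of what moves a stability metric along the
gradient: (1) per-scope Pearson correlation screens between the metric
and each covariate, flagged at ``p < alpha``; (2) gradient-boosted
regression trees (BRT) whose relative influence attributes the metric's
variance to covariates, including nonlinear and interactive effects.
Relative influence follows Friedman's definition: each covariate's
summed squared-error reduction over all of its splits in all trees,
normalized to percentages.

Scopes select samples: the pooled dataset, a single level, or a pooled
pair of adjacent levels (the "transition" models).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .tables import EnvTable, SampleMeta, ValidationError

__all__ = [
    "BRTParams",
    "DriverScreen",
    "InfluenceResult",
    "driver_screen",
    "brt_influence",
    "transition_drivers",
    "relative_influence_from_trees",
]


@dataclass(frozen=True)
class BRTParams:
    """Boosted-tree hyperparameters (squared-error loss throughout).

    Defaults follow common ecological BRT practice: slow learning
    (0.01), interaction depth 3, stochastic bagging at 0.75, up to 2000
    trees with early stopping.  ``early_stopping`` is ``"holdout"`` (a
    20% validation split, stop after ``patience`` non-improving rounds),
    ``"cv"`` (k-fold staged cross-validation pick of the tree count,
    then a refit on all data) or ``None`` (use all trees).
    """

    n_trees: int = 2000
    learning_rate: float = 0.01
    max_depth: int = 3
    bag_fraction: float = 0.75
    early_stopping: str | None = "holdout"
    validation_fraction: float = 0.2
    patience: int = 100
    cv_folds: int = 5


@dataclass(frozen=True)
class DriverScreen:
    """Long Pearson-screen table: metric, covariate, scope, n, r, p,
    significant."""

    data: pd.DataFrame
    alpha: float


@dataclass(frozen=True)
class InfluenceResult:
    """Relative influence (%) per covariate for one metric and scope."""

    metric: str
    scope: str
    influence: pd.Series  # percentages, sum to 100
    n_samples: int
    n_trees_used: int
    params: BRTParams
    seed: int
    train_loss: np.ndarray = field(repr=False, default=None)


def _scope_samples(m: SampleMeta | None, sample_ids, scope) -> tuple[list, str]:
    """Resolve a scope spec to a sample list and a printable name.

    ``scope``: ``"all"``; ``"level:MD"`` / ``("level", "MD")``;
    ``"pair:ND,LD"`` / ``("pair", ("ND", "LD"))``.
    """
    if scope in (None, "all"):
        return list(sample_ids), "all"
    if m is None:
        raise ValidationError("sample metadata required for level/pair scopes")
    if isinstance(scope, str):
        kind, _, rest = scope.partition(":")
        payload = tuple(x.strip() for x in rest.split(",")) if kind == "pair" else rest.strip()
    else:
        kind, payload = scope
    if kind == "level":
        ids = [s for s in sample_ids if s in m.data.index and m.data.at[s, "level"] == payload]
        return ids, f"level:{payload}"
    if kind == "pair":
        a, b = payload
        keep = {a, b}
        ids = [s for s in sample_ids if s in m.data.index and m.data.at[s, "level"] in keep]
        return ids, f"pair:{a},{b}"
    raise ValueError(f"unknown scope {scope!r}")


def driver_screen(
    metrics: pd.DataFrame | pd.Series,
    env: EnvTable | pd.DataFrame,
    m: SampleMeta | None = None,
    alpha: float = 0.05,
    scope="all",
) -> DriverScreen:
    """Pearson r and two-sided p between each metric and each covariate.

    A zero-variance covariate within the scope yields missing r/p with a
    warning and is never flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(metrics, pd.Series):
        metrics = metrics.to_frame(metrics.name or "metric")
    env_df = env.data if isinstance(env, EnvTable) else env
    common = [s for s in metrics.index if s in env_df.index]
    ids, scope_name = _scope_samples(m, common, scope)
    if len(ids) < 3:
        raise ValidationError(f"scope {scope_name!r} has {len(ids)} samples; need >= 3")

    rows = []
    for metric in metrics.columns:
        y = metrics.loc[ids, metric].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise ValidationError(f"non-finite values in metric {metric!r}")
        for cov in env_df.columns:
            x = env_df.loc[ids, cov].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                if np.std(x) == 0:
                    warnings.warn(
                        f"covariate {cov!r} has zero variance in scope "
                        f"{scope_name!r}; correlation undefined",
                        stacklevel=2,
                    )
                rows.append((metric, cov, scope_name, len(ids), np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((metric, cov, scope_name, len(ids), float(r), float(p), bool(p < alpha)))
    return DriverScreen(
        data=pd.DataFrame(
            rows,
            columns=["metric", "covariate", "scope", "n", "r", "p", "significant"],
        ),
        alpha=alpha,
    )


def relative_influence_from_trees(estimators, n_features: int) -> np.ndarray:
    """Friedman relative influence from fitted regression trees.

    For every internal node the squared-error reduction
    ``N*I - N_l*I_l - N_r*I_r`` (node count times impurity) is credited
    to the split variable; credits are summed over all trees and
    normalized to percentages.
    """
    total = np.zeros(n_features)
    for stage in estimators:
        for est in np.ravel(stage):
            t = est.tree_
            internal = t.children_left >= 0
            for node in np.flatnonzero(internal):
                left, right = t.children_left[node], t.children_right[node]
                reduction = (
                    t.weighted_n_node_samples[node] * t.impurity[node]
                    - t.weighted_n_node_samples[left] * t.impurity[left]
                    - t.weighted_n_node_samples[right] * t.impurity[right]
                )
                total[t.feature[node]] += max(reduction, 0.0)
    s = total.sum()
    if s == 0:
        return np.full(n_features, 100.0 / n_features)
    return 100.0 * total / s


def _fit_brt(X: np.ndarray, y: np.ndarray, params: BRTParams, seed: int):
    common = dict(
        loss="squared_error",
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        subsample=params.bag_fraction,
        random_state=seed,
    )
    if params.early_stopping == "holdout":
        model = GradientBoostingRegressor(
            n_estimators=params.n_trees,
            n_iter_no_change=params.patience,
            validation_fraction=params.validation_fraction,
            tol=1e-7,
            **common,
        )
        model.fit(X, y)
        return model
    if params.early_stopping == "cv":
        folds = KFold(params.cv_folds, shuffle=True, random_state=seed)
        cv_err = np.zeros(params.n_trees)
        for train, test in folds.split(X):
            mdl = GradientBoostingRegressor(n_estimators=params.n_trees, **common)
            mdl.fit(X[train], y[train])
            err = np.full(params.n_trees, np.nan)
            for i, pred in enumerate(mdl.staged_predict(X[test])):
                err[i] = np.mean((pred - y[test]) ** 2)
            cv_err += err
        best = int(np.nanargmin(cv_err)) + 1
        model = GradientBoostingRegressor(n_estimators=best, **common)
        model.fit(X, y)
        return model
    if params.early_stopping is None:
        model = GradientBoostingRegressor(n_estimators=params.n_trees, **common)
        model.fit(X, y)
        return model
    raise ValueError(f"unknown early_stopping mode {params.early_stopping!r}")


def brt_influence(
    metric: pd.Series,
    env: EnvTable | pd.DataFrame,
    m: SampleMeta | None = None,
    scope="all",
    params: BRTParams | None = None,
    seed: int = 0,
) -> InfluenceResult:
    """Fit a BRT of the metric on all covariates and report relative
    influence percentages (deterministic for a fixed seed)."""
    params = params or BRTParams()
    env_df = env.data if isinstance(env, EnvTable) else env
    if env_df.shape[1] < 2:
        raise ValidationError("need >= 2 covariates for influence attribution")
    common = [s for s in metric.index if s in env_df.index]
    ids, scope_name = _scope_samples(m, common, scope)
    y = metric.loc[ids].to_numpy(dtype=float)
    X = env_df.loc[ids].to_numpy(dtype=float)
    if y.size < 20:
        warnings.warn(
            f"scope {scope_name!r} has only {y.size} samples; BRT influence "
            "may be unstable below ~20",
            stacklevel=2,
        )
    if np.std(y) == 0:
        raise ValidationError("metric has no variance to explain")
    if not np.isfinite(X).all():
        raise ValidationError("missing values in covariates are not allowed")

    model = _fit_brt(X, y, params, seed)
    infl = relative_influence_from_trees(model.estimators_, X.shape[1])
    return InfluenceResult(
        metric=str(metric.name or "metric"),
        scope=scope_name,
        influence=pd.Series(infl, index=env_df.columns, name="influence_pct"),
        n_samples=int(y.size),
        n_trees_used=int(model.n_estimators_),
        params=params,
        seed=seed,
        train_loss=np.asarray(model.train_score_),
    )


def transition_drivers(
    metric: pd.Series,
    env: EnvTable | pd.DataFrame,
    m: SampleMeta,
    level_pair: tuple[str, str],
    params: BRTParams | None = None,
    seed: int = 0,
    allow_nonadjacent: bool = False,
) -> InfluenceResult:
    """BRT influence on the pooled samples of two (normally adjacent)
    levels, modelling which covariates govern the metric across that
    step of the gradient."""
    a, b = level_pair
    order = list(m.levels)
    for lv in (a, b):
        if lv not in order:
            raise ValidationError(f"unknown level {lv!r}")
    if abs(order.index(a) - order.index(b)) != 1:
        if not allow_nonadjacent:
            raise ValidationError(
                f"levels {a!r} and {b!r} are not adjacent; pass "
                "allow_nonadjacent=True to model them anyway"
            )
        warnings.warn(f"modelling non-adjacent pair {a}-{b}", stacklevel=2)
    return brt_influence(
        metric, env, m, scope=("pair", (a, b)), params=params, seed=seed
    )
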