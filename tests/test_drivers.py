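import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from commstab import (
    BRTParams,
    SampleMeta,
    brt_influence,
    driver_screen,
    relative_influence_from_trees,
    transition_drivers,
)


def make_meta(n_per, levels=("ND", "LD", "MD")):
    labels = [lv for lv in levels for _ in range(n_per)]
    idx = [f"s{i}" for i in range(len(labels))]
    return (
        SampleMeta(
            pd.DataFrame({"level": labels, "plot": "p", "point": "q"}, index=idx),
            levels=tuple(levels),
        ),
        idx,
    )


class TestScreen:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        m, idx = make_meta(5)
        y = pd.Series(rng.normal(size=15), index=idx, name="met")
        env = pd.DataFrame({"same": y, "noise": rng.normal(size=15)}, index=idx)
        s = driver_screen(y, env, m).data.set_index("covariate")
        assert s.at["same", "r"] == pytest.approx(1.0)
        assert s.at["same", "significant"]

    def test_matches_closed_form(self):
        rng = np.random.default_rng(4)
        m, idx = make_meta(7, levels=("ND", "LD"))
        y = pd.Series(rng.normal(size=14), index=idx, name="met")
        env = pd.DataFrame(rng.normal(size=(14, 3)), index=idx, columns=list("abc"))
        s = driver_screen(y, env, m).data.set_index("covariate")
        for cov in "abc":
            x = env[cov].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt((14 - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), 14 - 2)
            assert s.at[cov, "r"] == pytest.approx(r, abs=1e-10)
            assert s.at[cov, "p"] == pytest.approx(p, abs=1e-10)

    def test_scope_filters_samples(self):
        rng = np.random.default_rng(5)
        m, idx = make_meta(5)
        y = pd.Series(rng.normal(size=15), index=idx, name="met")
        env = pd.DataFrame({"x": rng.normal(size=15)}, index=idx)
        s = driver_screen(y, env, m, scope="level:LD").data
        assert (s["n"] == 5).all()
        assert (s["scope"] == "level:LD").all()

    def test_zero_variance_covariate_missing_with_warning(self):
        rng = np.random.default_rng(6)
        m, idx = make_meta(4, levels=("ND", "LD"))
        y = pd.Series(rng.normal(size=8), index=idx, name="met")
        env = pd.DataFrame({"flat": 1.0, "x": rng.normal(size=8)}, index=idx)
        with pytest.warns(UserWarning, match="zero variance"):
            s = driver_screen(y, env, m).data.set_index("covariate")
        assert np.isnan(s.at["flat", "r"])
        assert not s.at["flat", "significant"]


class TestRelativeInfluence:
    def test_hand_built_single_tree(self):
        """One depth-1 tree splitting feature 0 perfectly: its SSE
        reduction is the total SS, so influence is 100/0."""
        X = np.array([[0.0, 5.0], [0.0, 5.0], [1.0, 5.0], [1.0, 5.0]])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        tree = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        infl = relative_influence_from_trees([np.array([tree])], 2)
        assert infl.tolist() == [100.0, 0.0]

    def test_hand_built_two_trees_credit_split(self):
        """Tree 1 removes SS 4 via feature 0; tree 2 removes SS 1 via
        feature 1 -> influence 80/20."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        t1 = DecisionTreeRegressor(max_depth=1).fit(X, np.array([0, 0, 2, 2.0]))
        t2 = DecisionTreeRegressor(max_depth=1).fit(X, np.array([0.0, 1.0, 0.001, 1.001]))
        infl = relative_influence_from_trees([np.array([t1]), np.array([t2])], 2)
        # t1 reduction: 4.0 on f0; t2 reduction: ~1.0 on f1
        assert infl[0] == pytest.approx(80.0, abs=0.5)
        assert infl[1] == pytest.approx(20.0, abs=0.5)

    def test_single_covariate_full_credit(self):
        rng = np.random.default_rng(1)
        m, idx = make_meta(10, levels=("ND", "LD"))
        y = pd.Series(rng.normal(size=20), index=idx, name="met")
        env = pd.DataFrame({"x": y + rng.normal(0, 0.1, 20), "flat": np.linspace(0, 1, 20)}, index=idx)
        res = brt_influence(y, env[["x", "flat"]], m, seed=0)
        assert res.influence.sum() == pytest.approx(100.0, abs=1e-6)
        assert res.influence["x"] > 90


class TestBRT:
    def test_informative_covariate_dominates(self):
        rng = np.random.default_rng(2)
        m, idx = make_meta(25, levels=("ND", "LD"))
        x = rng.normal(size=50)
        y = pd.Series(2 * x + rng.normal(0, 0.3, 50), index=idx, name="met")
        env = pd.DataFrame(
            {"driver": x, **{f"n{i}": rng.normal(size=50) for i in range(5)}},
            index=idx,
        )
        res = brt_influence(y, env, m, seed=0)
        assert res.influence.idxmax() == "driver"

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        m, idx = make_meta(15, levels=("ND", "LD"))
        y = pd.Series(rng.normal(size=30), index=idx, name="met")
        env = pd.DataFrame(rng.normal(size=(30, 4)), index=idx, columns=list("abcd"))
        r1 = brt_influence(y, env, m, seed=11)
        r2 = brt_influence(y, env, m, seed=11)
        assert (r1.influence == r2.influence).all()

    def test_covariate_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        m, idx = make_meta(20, levels=("ND", "LD"))
        y = pd.Series(rng.normal(size=40), index=idx, name="met")
        env = pd.DataFrame(rng.normal(size=(40, 4)), index=idx, columns=list("abcd"))
        r1 = brt_influence(y, env, m, seed=5)
        r2 = brt_influence(y, env[list("dcba")], m, seed=5)
        # equivariant up to split-gain tie-breaking, which follows
        # column order inside the tree builder
        assert np.allclose(
            r1.influence.sort_index().to_numpy(),
            r2.influence.sort_index().to_numpy(),
            atol=1.0,
        )

    def test_constant_metric_rejected(self):
        m, idx = make_meta(5, levels=("ND", "LD"))
        y = pd.Series(1.0, index=idx, name="met")
        env = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)), index=idx)
        with pytest.raises(Exception, match="no variance"):
            brt_influence(y, env, m, seed=0)


class TestTransitions:
    def test_nonadjacent_needs_flag(self):
        rng = np.random.default_rng(9)
        m, idx = make_meta(12)
        y = pd.Series(rng.normal(size=36), index=idx, name="met")
        env = pd.DataFrame(rng.normal(size=(36, 3)), index=idx, columns=list("abc"))
        with pytest.raises(Exception, match="not adjacent"):
            transition_drivers(y, env, m, ("ND", "MD"), seed=0)
        with pytest.warns(UserWarning, match="non-adjacent"):
            res = transition_drivers(y, env, m, ("ND", "MD"), seed=0, allow_nonadjacent=True)
        assert res.influence.sum() == pytest.approx(100.0, abs=1e-6)

    def test_adjacent_pair_scope(self):
        rng = np.random.default_rng(10)
        m, idx = make_meta(12)
        y = pd.Series(rng.normal(size=36), index=idx, name="met")
        env = pd.DataFrame(rng.normal(size=(36, 3)), index=idx, columns=list("abc"))
        res = transition_drivers(y, env, m, ("ND", "LD"), seed=0)
        assert res.n_samples == 24
        assert res.scope == "pair:ND,LD"
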