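import numpy as np
import pandas as pd
import pytest
from scipy import stats

from commstab import (
    AbundanceTable,
    CorrelationStructure,
    correlation_structure,
    sample_cohesion,
    to_relative,
)
from commstab.cohesion import cohesion_by_level
from commstab import SampleMeta

from conftest import random_table


def naive_r_means(x: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Loop over every pair with scipy.stats.pearsonr, then average the
    significant r of each sign per species (0 if none)."""
    n, s = x.shape
    rpos = np.zeros(s)
    rneg = np.zeros(s)
    for i in range(s):
        pos, neg = [], []
        for j in range(s):
            if i == j:
                continue
            if x[:, i].std() == 0 or x[:, j].std() == 0:
                continue
            r, p = stats.pearsonr(x[:, i], x[:, j])
            if alpha == 1.0 or p < alpha:
                (pos if r > 0 else neg if r < 0 else []).append(r)
        rpos[i] = np.mean(pos) if pos else 0.0
        rneg[i] = np.mean(neg) if neg else 0.0
    return rpos, rneg


class TestCorrelationStructure:
    def test_duplicated_column_perfect_positive(self):
        rng = np.random.default_rng(0)
        x = rng.random(10) * 5 + 1
        t = AbundanceTable(pd.DataFrame({"a": x, "b": x, "c": rng.random(10)}))
        c = correlation_structure(t, alpha=0.05)
        assert c.r.at["a", "b"] == pytest.approx(1.0)
        assert c.significant.at["a", "b"]
        assert c.r_pos_mean["a"] >= 0.999 or c.r_pos_mean["a"] == pytest.approx(
            np.mean([1.0, c.r.at["a", "c"]]) if c.significant.at["a", "c"] and c.r.at["a", "c"] > 0 else 1.0
        )

    def test_reversed_column_perfect_negative(self):
        t = AbundanceTable(
            pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 3.0, 2.0, 1.0]})
        )
        c = correlation_structure(t, alpha=0.05)
        assert c.r.at["a", "b"] == pytest.approx(-1.0)
        assert c.r_neg_mean["a"] == pytest.approx(-1.0)
        assert c.r_pos_mean["a"] == 0.0

    @pytest.mark.parametrize("alpha", [0.05, 0.2, 1.0])
    def test_matches_pairwise_loop(self, alpha):
        rng = np.random.default_rng(3)
        t = random_table(rng, 20, 5)
        c = correlation_structure(t, alpha=alpha)
        rpos, rneg = naive_r_means(t.data.to_numpy(), alpha)
        assert np.allclose(c.r_pos_mean.to_numpy(), rpos, atol=1e-12)
        assert np.allclose(c.r_neg_mean.to_numpy(), rneg, atol=1e-12)

    def test_zero_variance_species_excluded(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"a": rng.random(8), "const": np.full(8, 3.0), "b": rng.random(8)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            c = correlation_structure(AbundanceTable(df), alpha=1.0)
        assert np.isnan(c.r.at["a", "const"])
        assert c.r_pos_mean["const"] == 0.0
        assert c.r_neg_mean["const"] == 0.0

    def test_too_few_samples_rejected(self):
        t = AbundanceTable(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))
        with pytest.raises(Exception, match="3 samples"):
            correlation_structure(t)


class TestSampleCohesion:
    def test_hand_example(self):
        """Proportions (0.5, 0.5), rbar+ = (0.8, 0.4), rbar- = (0, -0.6)
        -> C+ = 0.6, C- = -0.3, total 0.9, ratio 0.5."""
        t = AbundanceTable(
            pd.DataFrame({"a": [0.5, 0.5], "b": [0.5, 0.5]}, index=["s1", "s2"])
        )
        c = CorrelationStructure(
            r=pd.DataFrame(),
            p=pd.DataFrame(),
            significant=pd.DataFrame(),
            r_pos_mean=pd.Series({"a": 0.8, "b": 0.4}),
            r_neg_mean=pd.Series({"a": 0.0, "b": -0.6}),
            n_samples=2,
            alpha=0.05,
        )
        res = sample_cohesion(t, c)
        row = res.per_sample.loc["s1"]
        assert row["positive"] == pytest.approx(0.6, abs=1e-12)
        assert row["negative"] == pytest.approx(-0.3, abs=1e-12)
        assert row["total"] == pytest.approx(0.9, abs=1e-12)
        assert row["neg_pos_ratio"] == pytest.approx(0.5, abs=1e-12)
        assert row["network_stability"] == pytest.approx(-0.5, abs=1e-12)

    def test_no_significant_pairs_all_zero(self):
        t = AbundanceTable(
            pd.DataFrame({"a": [0.5, 0.4], "b": [0.5, 0.6]}, index=["s1", "s2"])
        )
        c = CorrelationStructure(
            r=pd.DataFrame(),
            p=pd.DataFrame(),
            significant=pd.DataFrame(),
            r_pos_mean=pd.Series({"a": 0.0, "b": 0.0}),
            r_neg_mean=pd.Series({"a": 0.0, "b": 0.0}),
            n_samples=2,
            alpha=0.05,
        )
        res = sample_cohesion(t, c)
        assert (res.per_sample["positive"] == 0).all()
        assert (res.per_sample["total"] == 0).all()
        assert res.per_sample["neg_pos_ratio"].isna().all()

    def test_raw_counts_rejected(self):
        t = AbundanceTable(pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [2.0, 2.0, 1.0]}))
        c = correlation_structure(t, alpha=1.0)
        with pytest.raises(Exception, match="row-proportion"):
            sample_cohesion(t, c)

    def test_bounds_on_simulated_data(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 30, 12)
        c = correlation_structure(t, alpha=0.05)
        res = sample_cohesion(to_relative(t), c)
        assert (res.per_sample["positive"] >= 0).all()
        assert (res.per_sample["positive"] <= 1).all()
        assert (res.per_sample["negative"] <= 0).all()
        assert (res.per_sample["negative"] >= -1).all()
        assert (res.per_sample["total"] <= 2).all()

    def test_invariant_to_species_order(self):
        rng = np.random.default_rng(11)
        t = random_table(rng, 15, 6)
        perm = list(rng.permutation(t.data.columns))
        tp = AbundanceTable(t.data[perm])
        r1 = sample_cohesion(to_relative(t), correlation_structure(t))
        r2 = sample_cohesion(to_relative(tp), correlation_structure(tp))
        assert np.allclose(
            r1.per_sample["positive"], r2.per_sample["positive"], atol=1e-12
        )
        assert np.allclose(
            r1.per_sample["negative"], r2.per_sample["negative"], atol=1e-12
        )


class TestByLevel:
    def test_grouping_counts(self, tiny_table, tiny_meta):
        c = correlation_structure(tiny_table, alpha=1.0)
        res = sample_cohesion(to_relative(tiny_table), c)
        summary = cohesion_by_level(res, tiny_meta)
        n = summary.query("metric == 'positive'").set_index("level")["n"]
        assert n["ND"] == 3 and n["ED"] == 3
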