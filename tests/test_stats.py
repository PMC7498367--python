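import numpy as np
import pandas as pd
import pytest

from digiwest.peaks import SignalMatrix
from digiwest.stats import (correlation_distances, count_significant,
                            hierarchical_cluster, log2_transform,
                            pairwise_ttests, pooled_sd_ttest)

from .oracles import naive_average_linkage, pooled_ttest_formula


def matrix_of(values: pd.DataFrame, log2=True) -> SignalMatrix:
    info = pd.DataFrame({"antibody_id": [str(s) for s in values.index],
                         "rank": 1, "apex_mw": 50.0, "relative_shift": 0.0,
                         "shift_flag": False, "n_detected": 1}, index=values.index)
    return SignalMatrix(values, info, log2=log2)


class TestLog2Transform:
    def test_examples_and_missingness(self):
        m = matrix_of(pd.DataFrame([[1.0, 8.0, np.nan]], index=["a"],
                                   columns=["s1", "s2", "s3"]), log2=False)
        out = log2_transform(m, floor=1.0)
        assert out.values.loc["a", "s1"] == 0.0
        assert out.values.loc["a", "s2"] == 3.0
        assert np.isnan(out.values.loc["a", "s3"])
        assert out.log2

    def test_floor_applied_and_validated(self):
        m = matrix_of(pd.DataFrame([[0.25]], index=["a"], columns=["s"]),
                      log2=False)
        assert log2_transform(m, floor=1.0).values.iloc[0, 0] == 0.0
        with pytest.raises(ValueError):
            log2_transform(m, floor=0.0)


class TestHierarchicalCluster:
    def test_identical_columns_merge_at_zero(self, rng):
        base = rng.normal(size=10)
        vals = pd.DataFrame({"s1": base, "s2": base,
                             "s3": rng.normal(size=10)},
                            index=[f"a{i}" for i in range(10)])
        tree = hierarchical_cluster(matrix_of(vals))
        assert tree.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_block_structure(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        vals = pd.DataFrame({"a1": a, "a2": a + 1.0, "b1": b, "b2": 2 * b + 3})
        tree = hierarchical_cluster(matrix_of(vals))
        # within-block merges are exact (r = 1), the between-block merge is last
        assert tree.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        assert tree.merge_heights[1] == pytest.approx(0.0, abs=1e-12)
        leaves = tree.leaf_order
        assert {tuple(sorted(leaves[:2])), tuple(sorted(leaves[2:]))} == \
            {("a1", "a2"), ("b1", "b2")}

    def test_merge_heights_match_naive_oracle(self, rng):
        for _ in range(20):
            vals = pd.DataFrame(rng.normal(size=(15, 6)),
                                columns=[f"s{i}" for i in range(6)])
            m = matrix_of(vals)
            tree = hierarchical_cluster(m)
            dist = correlation_distances(m).to_numpy()
            np.testing.assert_allclose(sorted(tree.merge_heights),
                                       sorted(naive_average_linkage(dist)),
                                       atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        # Pearson distance between sample profiles is invariant to an
        # affine map with positive slope applied to each sample column
        vals = pd.DataFrame(rng.normal(size=(20, 5)),
                            columns=[f"s{i}" for i in range(5)])
        scaled = vals.mul(rng.uniform(0.5, 4.0, size=5), axis=1) \
                     .add(rng.normal(size=5), axis=1)
        t1 = hierarchical_cluster(matrix_of(vals))
        t2 = hierarchical_cluster(matrix_of(scaled))
        np.testing.assert_allclose(t1.merge_heights, t2.merge_heights, atol=1e-10)
        assert t1.leaf_order == t2.leaf_order

    def test_zero_variance_profile_warns_max_distance(self, rng):
        vals = pd.DataFrame({"flat": np.full(10, 3.0),
                             "s1": rng.normal(size=10), "s2": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            d = correlation_distances(matrix_of(vals))
        assert d.loc["flat", "s1"] == 2.0

    def test_newick_contains_all_leaves(self, rng):
        vals = pd.DataFrame(rng.normal(size=(10, 4)),
                            columns=["s1", "s2", "s3", "s4"])
        nwk = hierarchical_cluster(matrix_of(vals)).to_newick()
        assert all(s in nwk for s in vals.columns)


class TestPooledTtest:
    def test_identical_groups_t_zero_p_one(self):
        vals = np.array([1.0, 2.0, 1.0, 2.0, 5.0, 9.0])
        groups = np.array(["A", "A", "B", "B", "C", "C"])
        t, p = pooled_sd_ttest(vals, groups, ("A", "B"))
        assert t == 0.0 and p == 1.0

    def test_matches_explicit_formula(self, rng):
        for _ in range(50):
            groups = {g: rng.normal(rng.uniform(-2, 2), 1.0, size=rng.integers(2, 7))
                      for g in ("A", "B", "C")}
            vals = np.concatenate(list(groups.values()))
            labs = np.concatenate([[g] * len(v) for g, v in groups.items()])
            t, p = pooled_sd_ttest(vals, labs, ("A", "B"))
            t0, p0 = pooled_ttest_formula(groups, ("A", "B"))
            assert t == pytest.approx(t0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_label_swap_flips_t_keeps_p(self, rng):
        vals = rng.normal(size=12)
        labs = np.repeat(["A", "B", "C"], 4)
        t_ab, p_ab = pooled_sd_ttest(vals, labs, ("A", "B"))
        t_ba, p_ba = pooled_sd_ttest(vals, labs, ("B", "A"))
        assert t_ab == pytest.approx(-t_ba) and p_ab == pytest.approx(p_ba)

    def test_small_group_reported_missing(self):
        vals = np.array([1.0, np.nan, 3.0, 4.0])
        labs = np.array(["A", "A", "B", "B"])
        t, p = pooled_sd_ttest(vals, labs, ("A", "B"))
        assert np.isnan(t) and np.isnan(p)


class TestPairwiseTtests:
    def meta(self, samples, types):
        return pd.DataFrame({"sample_id": samples, "tumor_type": types})

    def test_planted_effect_detected_nulls_quiet(self):
        rng = np.random.default_rng(17)
        samples = [f"s{i}" for i in range(15)]
        types = np.repeat(["A", "B", "C"], 5)
        vals = pd.DataFrame(rng.normal(size=(30, 15)), columns=samples,
                            index=[f"ab{i}" for i in range(30)])
        vals.loc["ab0", np.array(types) == "A"] += 5.0  # large planted effect
        table = pairwise_ttests(matrix_of(vals), self.meta(samples, types))
        assert table.p_bh.loc["A|B", "ab0"] < 0.05
        assert table.p_bh.loc["A|C", "ab0"] < 0.05
        nulls = table.p_bh.drop(columns="ab0")
        assert float(np.nanmedian(nulls.to_numpy())) > 0.2

    def test_counts_match_set_oracle(self, rng):
        samples = [f"s{i}" for i in range(20)]
        types = np.repeat(["A", "B", "C", "D"], 5)
        t1 = pairwise_ttests(matrix_of(pd.DataFrame(
            rng.normal(size=(25, 20)), columns=samples)), self.meta(samples, types))
        t2 = pairwise_ttests(matrix_of(pd.DataFrame(
            rng.normal(size=(25, 20)), columns=samples)), self.meta(samples, types))
        counts = count_significant(t1, t2)
        s1, s2 = t1.significant_sets(), t2.significant_sets()
        for pair in counts.index:
            assert counts.loc[pair, "n_ff"] == len(s1[pair])
            assert counts.loc[pair, "n_ffpe"] == len(s2[pair])
            assert counts.loc[pair, "n_overlap"] == len(s1[pair] & s2[pair])

    def test_mismatched_panels_rejected(self, rng):
        samples = [f"s{i}" for i in range(10)]
        types = np.repeat(["A", "B"], 5)
        t1 = pairwise_ttests(matrix_of(pd.DataFrame(
            rng.normal(size=(5, 10)), columns=samples,
            index=[f"x{i}" for i in range(5)])), self.meta(samples, types))
        t2 = pairwise_ttests(matrix_of(pd.DataFrame(
            rng.normal(size=(5, 10)), columns=samples,
            index=[f"y{i}" for i in range(5)])), self.meta(samples, types))
        with pytest.raises(ValueError):
            count_significant(t1, t2)

    def test_ff_regime_richer_than_ffpe(self, small_log2, small_cohort):
        """With planted attenuation/missingness, FF finds at least as many
        discriminating antibodies as FFPE overall."""
        l_ff, l_ffpe = small_log2
        _, _, meta, _ = small_cohort
        shared = [s for s in l_ff.values.index if s in set(l_ffpe.values.index)]
        t_ff = pairwise_ttests(l_ff.subset_signals(shared), meta)
        t_ffpe = pairwise_ttests(l_ffpe.subset_signals(shared), meta)
        assert t_ff.significant_counts.sum() >= t_ffpe.significant_counts.sum()
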