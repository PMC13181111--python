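import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from symptomnet import (
    BinaryMatrix,
    ItemResponseTable,
    cohens_d,
    cronbach_alpha,
    descriptive_stats,
    dichotomize,
    generate_cohort,
    mann_whitney_u,
    read_item_table,
    write_item_table,
)
from symptomnet.synthetic import (
    GROUP_B_PREVALENCE,
    PHQ_ITEMS,
    paper_like_scenario,
)


def _table(scores, group=None):
    scores = np.asarray(scores)
    if group is None:
        group = np.repeat("g", scores.shape[0])
    items = tuple(f"I{j}" for j in range(scores.shape[1]))
    return ItemResponseTable(scores=scores, items=items, group=group)


class TestReadItemTable:
    def test_all_zero_csv(self, tmp_path):
        path = tmp_path / "t.csv"
        cols = [f"PHQ.{i}" for i in range(1, 10)]
        pd.DataFrame(
            {**{c: [0, 0, 0] for c in cols}, "group": ["a", "a", "b"]}
        ).to_csv(path, index=False)
        table = read_item_table(path, cols, "group")
        assert table.scores.shape == (3, 9)
        assert np.all(table.scores == 0)

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame({"A": [0, 4], "B": [1, 2], "group": ["x", "y"]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="row"):
            read_item_table(path, ["A", "B"], "group")

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame({"A": [0], "group": ["x"]}).to_csv(path, index=False)
        with pytest.raises(KeyError, match="not found"):
            read_item_table(path, ["A", "B"], "group")

    def test_incomplete_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(
            {"A": [0, None, 2], "B": [1, 2, 3], "group": ["x", "x", "y"]}
        ).to_csv(path, index=False)
        table = read_item_table(path, ["A", "B"], "group")
        assert table.n_subjects == 2
        assert table.n_dropped == 1

    def test_synthetic_cohort_round_trips(self, tmp_path):
        spec = paper_like_scenario(seed=3)
        table = generate_cohort(spec, seed=11)
        path = tmp_path / "cohort.csv"
        write_item_table(table, path)
        back = read_item_table(path, list(PHQ_ITEMS), "group")
        assert np.array_equal(back.scores, table.scores)
        assert np.array_equal(back.group, table.group)
        assert back.items == table.items


class TestDichotomize:
    def test_recoding_rule(self):
        table = _table([[0, 1, 2, 3]])
        assert dichotomize(table).values.tolist() == [[0, 1, 1, 1]]

    def test_all_zero(self):
        assert np.all(dichotomize(_table(np.zeros((3, 4)))).values == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        table = _table(rng.integers(0, 4, (50, 5)))
        once = dichotomize(table)
        twice = dichotomize(once)
        assert np.array_equal(once.values, twice.values)

    @given(st.integers(0, 2))
    @hyp_settings(max_examples=10, deadline=None)
    def test_monotone_in_score(self, s):
        # raising any score never turns a present symptom absent
        lo = dichotomize(_table([[s]])).values[0, 0]
        hi = dichotomize(_table([[s + 1]])).values[0, 0]
        assert hi >= lo


class TestDescriptiveStats:
    def test_published_prevalences_give_published_total_mean(self):
        # exact presence proportions of the smaller group at n = 1000
        n = 1000
        cols = []
        for prev in GROUP_B_PREVALENCE:
            k = int(round(prev * n))
            col = np.zeros(n, dtype=int)
            col[:k] = 1
            cols.append(col)
        values = np.column_stack(cols)
        m = BinaryMatrix(values, PHQ_ITEMS, np.repeat("sm", n))
        stats = descriptive_stats(m)
        assert stats["per_group"].loc["sm", "total_mean"] == pytest.approx(
            5.98, abs=0.02
        )

    def test_constant_present_items(self):
        m = BinaryMatrix(np.ones((10, 3), dtype=int), ("a", "b", "c"),
                         np.repeat("g", 10))
        stats = descriptive_stats(m)
        per = stats["per_item"]
        assert np.allclose(per["mean"], 1.0)
        assert np.allclose(per["sd"], 0.0)
        assert np.allclose(per["presence_pct"], 100.0)

    def test_total_mean_equals_sum_of_item_means(self):
        rng = np.random.default_rng(1)
        values = (rng.random((200, 5)) < 0.4).astype(int)
        group = np.where(rng.random(200) < 0.3, "a", "b")
        m = BinaryMatrix(values, tuple("abcde"), group)
        stats = descriptive_stats(m)
        for lvl in ("a", "b"):
            item_sum = stats["per_item"].loc[lvl]["mean"].sum()
            assert stats["per_group"].loc[lvl, "total_mean"] == pytest.approx(
                item_sum, abs=1e-12
            )

    def test_absence_presence_sum_to_100(self):
        rng = np.random.default_rng(2)
        values = (rng.random((100, 4)) < 0.5).astype(int)
        m = BinaryMatrix(values, tuple("wxyz"), np.repeat("g", 100))
        per = descriptive_stats(m)["per_item"]
        assert np.allclose(per["absence_pct"] + per["presence_pct"], 100.0)

    def test_bernoulli_half_means(self):
        rng = np.random.default_rng(3)
        values = (rng.random((10_000, 3)) < 0.5).astype(int)
        m = BinaryMatrix(values, ("a", "b", "c"), np.repeat("g", 10_000))
        per = descriptive_stats(m)["per_item"]
        assert np.all(np.abs(per["mean"] - 0.5) < 0.02)

    def test_two_groups_include_between_stats(self):
        rng = np.random.default_rng(4)
        values = (rng.random((120, 3)) < 0.5).astype(int)
        group = np.repeat(["a", "b"], 60)
        stats = descriptive_stats(BinaryMatrix(values, ("x", "y", "z"), group))
        assert {"mann_whitney_u", "p_value", "cohens_d"} <= set(
            stats["between"]
        )


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_not_significant(self):
        x = np.arange(30.0)
        _, p = mann_whitney_u(x, x)
        assert p > 0.95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=5),
        st.lists(st.integers(0, 5), min_size=1, max_size=5),
    )
    @hyp_settings(max_examples=60, deadline=None)
    def test_statistic_matches_pair_count(self, a, b):
        # U of the first sample = #{a_i > b_j} + 0.5 * #{a_i == b_j}
        u, _ = mann_whitney_u(a, b)
        brute = sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
        )
        assert u == pytest.approx(brute)


class TestCohensD:
    def test_identical_samples(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        a = np.array([0.0, 2.0])  # mean 1, var 2
        b = np.array([1.0, 3.0])  # mean 2, var 2
        assert cohens_d(a, b) == pytest.approx(-1.0 / np.sqrt(2.0))

    def test_simulation_recovery(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.5, 1.0, 50_000)
        b = rng.normal(0.0, 1.0, 50_000)
        assert cohens_d(a, b) == pytest.approx(0.5, abs=0.02)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestCronbachAlpha:
    def test_duplicated_item_gives_one(self):
        col = np.array([0, 1, 0, 1, 1, 0])
        m = BinaryMatrix(
            np.column_stack([col] * 4), tuple("abcd"), np.repeat("g", 6)
        )
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(6)
        values = (rng.random((20_000, 6)) < 0.5).astype(int)
        m = BinaryMatrix(values, tuple("abcdef"), np.repeat("g", 20_000))
        assert abs(cronbach_alpha(m)) < 0.05

    def test_two_item_hand_computation(self):
        x = np.array([[0, 0], [0, 1], [1, 1], [1, 1]])
        m = BinaryMatrix(x, ("a", "b"), np.repeat("g", 4))
        var_a = np.var(x[:, 0], ddof=1)
        var_b = np.var(x[:, 1], ddof=1)
        var_t = np.var(x.sum(axis=1), ddof=1)
        expected = 2.0 * (1.0 - (var_a + var_b) / var_t)
        assert cronbach_alpha(m) == pytest.approx(expected)

    def test_zero_total_variance_rejected(self):
        m = BinaryMatrix(np.ones((5, 3), dtype=int), ("a", "b", "c"),
                         np.repeat("g", 5))
        with pytest.raises(ValueError):
            cronbach_alpha(m)
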