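"""CFS internals: discretization, information measures, merit, greedy
search against exhaustive oracles, and the study-level summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emoeeg import cfs
from emoeeg.reference import (
    REPORTED_CHOSEN_TIMES,
    REPORTED_MEAN_SU,
    REPORTED_SELECTED_SET,
)


class TestDiscretize:
    def test_equal_frequency_bins(self):
        table = cfs.discretize(np.arange(1, 11, dtype=float)[:, None], 5)
        _, counts = np.unique(table.bins[:, 0], return_counts=True)
        assert list(counts) == [2, 2, 2, 2, 2]

    def test_constant_column_flagged(self):
        table = cfs.discretize(np.ones((20, 1)), 5)
        assert table.bins[:, 0].max() == 0
        assert table.flags

    def test_quantile_proportions_on_normal_sample(self):
        x = np.random.default_rng(0).normal(size=1000)[:, None]
        table = cfs.discretize(x, 5)
        _, counts = np.unique(table.bins[:, 0], return_counts=True)
        np.testing.assert_allclose(counts / 1000, 0.2, atol=0.01)

    def test_too_few_bins_rejected(self):
        with pytest.raises(cfs.CfsError):
            cfs.discretize(np.ones((5, 1)), 1)


class TestInformationMeasures:
    def test_entropy_examples(self):
        assert cfs.entropy([0, 1, 2, 3]) == pytest.approx(2.0)
        assert cfs.entropy([7] * 10) == 0.0
        assert cfs.entropy([0, 0, 0, 1]) == pytest.approx(
            -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)), abs=1e-12)

    def test_perfect_predictor(self):
        y = np.array([0, 1, 2, 3] * 5)
        assert cfs.conditional_entropy(y, y) == pytest.approx(0.0, abs=1e-12)
        assert cfs.info_gain(y, y) == pytest.approx(cfs.entropy(y), abs=1e-12)

    def test_constructed_independence(self):
        # product table: every (x, y) combination equally often
        x = np.repeat([0, 1], 10)
        y = np.tile([0, 1], 10)
        assert cfs.info_gain(y, x) == pytest.approx(0.0, abs=1e-12)
        assert cfs.symmetric_uncertainty(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2_table(self):
        # joint counts ((2,1),(1,2)): H(X)=H(Y)=1, H(X,Y) by plug-in
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        h_joint = -(2 / 6 * np.log2(2 / 6) * 2 + 1 / 6 * np.log2(1 / 6) * 2)
        gain = 1.0 + 1.0 - h_joint
        assert cfs.info_gain(y, x) == pytest.approx(gain, abs=1e-12)
        assert cfs.symmetric_uncertainty(x, y) == pytest.approx(gain, abs=1e-12)

    def test_gain_symmetry_and_length_check(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 100)
        y = rng.integers(0, 3, 100)
        assert cfs.info_gain(y, x) == pytest.approx(cfs.info_gain(x, y), abs=1e-12)
        with pytest.raises(cfs.CfsError):
            cfs.conditional_entropy(x, y[:-1])

    def test_su_bounds_and_symmetry_bulk(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            x = rng.integers(0, rng.integers(2, 6), 40)
            y = rng.integers(0, rng.integers(2, 6), 40)
            u = cfs.symmetric_uncertainty(x, y)
            assert 0.0 <= u <= 1.0
            assert u == pytest.approx(cfs.symmetric_uncertainty(y, x), abs=1e-12)

    def test_su_identity_and_degenerate(self):
        x = np.array([0, 1, 0, 1, 2])
        assert cfs.symmetric_uncertainty(x, x) == 1.0
        assert cfs.symmetric_uncertainty(np.zeros(5), np.zeros(5)) == 0.0

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_entropy_bounds_property(self, levels):
        h = cfs.entropy(levels)
        assert 0.0 <= h <= np.log2(len(set(levels))) + 1e-12


def _random_table(rng, n_features=6, n=60, informative=2):
    y = rng.integers(0, 4, n)
    X = rng.normal(size=(n, n_features))
    for j in range(informative):
        X[:, j] += 0.8 * y
    return cfs.discretize(X, 4, labels=y)


class TestMerit:
    def test_singleton_merit_equals_class_su(self):
        table = _random_table(np.random.default_rng(3))
        su = cfs.class_correlations(table)
        for fid in table.feature_ids:
            sc = cfs.merit((fid,), table)
            assert sc.merit == pytest.approx(su[fid - 1], abs=1e-12)
            assert sc.rff_bar == 0.0

    def test_duplicate_feature_fully_redundant(self):
        """An exact copy adds nothing: with rff = 1 the merit of {f, copy}
        collapses to the singleton merit (and never exceeds it)."""
        rng = np.random.default_rng(4)
        y = rng.integers(0, 4, 80)
        x = y + rng.normal(scale=0.5, size=80)
        X = np.column_stack([x, x])
        table = cfs.discretize(X, 4, labels=y)
        pair = cfs.merit((1, 2), table)
        single = cfs.merit((1,), table)
        assert pair.rff_bar == pytest.approx(1.0)
        assert pair.merit == pytest.approx(single.merit, abs=1e-12)

    def test_two_independent_features_beat_one(self):
        # Merit = 2u / sqrt(2) > u when rff = 0
        assert cfs.merit_from_means(2, 0.3, 0.0) == pytest.approx(
            2 * 0.3 / np.sqrt(2))
        assert cfs.merit_from_means(2, 0.3, 0.0) > 0.3

    def test_merit_identity_on_every_emitted_score(self):
        table = _random_table(np.random.default_rng(5))
        ranking = cfs.greedy_rank(table)
        for sc in ranking.steps:
            assert sc.merit == pytest.approx(
                cfs.merit_from_means(sc.k, sc.rcf_bar, sc.rff_bar), abs=1e-12)

    def test_unknown_feature_rejected(self):
        table = _random_table(np.random.default_rng(6))
        with pytest.raises(cfs.CfsError):
            cfs.merit((99,), table)


class TestGreedySearch:
    def test_label_copy_ranks_first_with_unit_merit(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 4, 60)
        X = np.column_stack([rng.normal(size=60), y.astype(float),
                             rng.normal(size=60)])
        table = cfs.discretize(X, 4, labels=y)
        ranking = cfs.greedy_rank(table)
        assert ranking.order[0] == 2
        assert ranking.steps[0].merit == pytest.approx(1.0)

    def test_ranking_is_permutation_with_nested_prefixes(self):
        table = _random_table(np.random.default_rng(8))
        ranking = cfs.greedy_rank(table)
        assert sorted(ranking.order) == table.feature_ids
        subsets = ranking.nested_subsets()
        for a, b in zip(subsets, subsets[1:]):
            assert b[: len(a)] == a

    def test_greedy_against_exhaustive_oracle(self):
        """Greedy never beats brute force and usually attains it."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            table = _random_table(rng)
            ranking = cfs.greedy_rank(table)
            greedy_best = ranking.best.merit
            exhaustive = cfs.exhaustive_best_subset(table).merit
            assert greedy_best <= exhaustive + 1e-12
            if greedy_best == pytest.approx(exhaustive, abs=1e-9):
                hits += 1
        assert hits >= 40

    def test_permuted_labels_look_null(self):
        rng = np.random.default_rng(9)
        table = _random_table(rng, informative=0)
        observed = cfs.greedy_rank(table).best.merit
        null = []
        for _ in range(200):
            table.labels = rng.permutation(table.labels)
            null.append(cfs.greedy_rank(table).best.merit)
        assert observed < np.quantile(null, 0.975)


class TestStudySummaries:
    def test_reported_threshold_selection(self):
        sel = cfs.threshold_selection(REPORTED_MEAN_SU, 0.1)
        assert tuple(sorted(sel)) == REPORTED_SELECTED_SET

    def test_threshold_extremes(self):
        assert cfs.threshold_selection(REPORTED_MEAN_SU, 1.0) == []
        assert len(cfs.threshold_selection(REPORTED_MEAN_SU, 0.0)) == 27

    def test_reported_chosen_times_selection(self):
        sel = cfs.chosen_times_selection(REPORTED_CHOSEN_TIMES, 20)
        assert tuple(sorted(sel)) == REPORTED_SELECTED_SET

    def test_selection_frequency_counting(self):
        table = _random_table(np.random.default_rng(10))
        rankings = [cfs.greedy_rank(table) for _ in range(3)]
        freq = cfs.selection_frequency(rankings, top_k=6, min_times=2)
        assert (freq["chosen_times"] == 3).all()  # top_k = all features
        assert freq["chosen_times"].max() <= len(rankings)

    def test_average_class_correlation_over_datasets(self):
        rng = np.random.default_rng(11)
        tables = [_random_table(rng) for _ in range(4)]
        mean_su, selected = cfs.average_class_correlation(tables, threshold=0.1)
        assert len(mean_su) == 6
        assert set(selected) <= set(tables[0].feature_ids)
        # features 1-2 carry the signal by construction
        assert {1, 2} <= set(selected)


class TestSklearnEstimators:
    def test_selector_modes_and_support(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 4, 80)
        X = rng.normal(size=(80, 8))
        X[:, 2] += 1.2 * y
        X[:, 5] += 1.2 * y
        for mode in ("merit", "threshold", "top_k"):
            sel = cfs.CfsSelector(mode=mode, k=3).fit(X, y)
            mask = sel.get_support()
            assert mask.shape == (8,)
            assert sel.transform(X).shape[1] == mask.sum()
            assert mask[2] or mask[5]

    def test_ranker_and_clone_compat(self):
        from sklearn.base import clone

        rng = np.random.default_rng(13)
        y = rng.integers(0, 4, 60)
        X = rng.normal(size=(60, 5))
        X[:, 0] += y
        ranker = cfs.CfsRanker().fit(X, y)
        assert ranker.order_[0] == 0
        assert len(ranker.merits_) == 5
        cloned = clone(ranker)
        assert cloned.get_params() == ranker.get_params()
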