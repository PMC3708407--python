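"""mRMR: mutual information, relevance/redundancy, greedy vs exhaustive."""

import itertools
import math

import numpy as np
import pytest

from nodulecad.mrmr import (DiscreteFeatureSet, criterion_value, discretize,
                            discretize_table, mrmr_select, mutual_information,
                            redundancy, relevance, select_features)


def brute_force_mi(x, y):
    """Plug-in MI by explicit summation over the contingency cells."""
    n = len(x)
    total = 0.0
    for a in set(x.tolist()):
        for b in set(y.tolist()):
            pab = np.mean((x == a) & (y == b))
            if pab > 0:
                pa, pb = np.mean(x == a), np.mean(y == b)
                total += pab * math.log2(pab / (pa * pb))
    return total


class TestDiscretize:
    def test_normal_sample_mid_state_majority(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=2000)
        states = discretize(col)
        counts = np.bincount(states, minlength=3)
        assert np.all(counts > 0)
        # mass between mu-sigma and mu+sigma is ~Phi(1)-Phi(-1) ~ 0.68
        assert counts[1] == max(counts)
        assert counts[1] / len(col) == pytest.approx(0.683, abs=0.05)

    def test_constant_column_single_state(self):
        assert set(discretize(np.full(10, 2.5))) == {0}

    def test_affine_rescaling_leaves_coding_unchanged(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=200)
        np.testing.assert_array_equal(discretize(col), discretize(3.0 * col + 7.0))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0, np.nan]))

    def test_fitted_thresholds_apply_to_new_data(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(50, 2))
        test = rng.normal(size=(20, 2)) + 5.0  # shifted: coded on train scale
        y = rng.integers(0, 2, 50)
        _, thresholds = discretize_table(train, y)
        coded, _ = discretize_table(test, np.zeros(20, dtype=int), thresholds)
        assert np.all(coded.columns == 2)  # everything above train mu+sigma


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 0, 1, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_vectors_zero(self):
        assert mutual_information(
            np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cellwise_summation(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 3, 50)
        assert mutual_information(x, y) == pytest.approx(
            brute_force_mi(x, y), abs=1e-12
        )

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 4, 40)
            y = rng.integers(0, 3, 40)
            mi_xy = mutual_information(x, y)
            assert mi_xy == mutual_information(y, x)
            assert mi_xy >= 0.0

    def test_self_information_is_entropy(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 60)
        p = np.bincount(x) / len(x)
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mutual_information(x, x) == pytest.approx(entropy, abs=1e-12)


class TestRelevanceRedundancy:
    def test_relevance_of_label_copy_is_label_entropy(self):
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        table = DiscreteFeatureSet(y[:, None], y)
        p = np.mean(y)
        h = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
        assert relevance([0], table) == pytest.approx(h, abs=1e-12)

    def test_relevance_averages_known_mutual_informations(self):
        y = np.array([0, 0, 1, 1])
        cols = np.stack([y, np.array([0, 1, 0, 1])], axis=1)  # MI 1.0 and 0.0
        table = DiscreteFeatureSet(cols, y)
        assert relevance([0, 1], table) == pytest.approx(0.5)

    def test_redundancy_single_balanced_binary_is_entropy_one(self):
        x = np.array([0, 1, 0, 1, 0, 1])
        table = DiscreteFeatureSet(x[:, None], np.array([0, 1, 0, 1, 0, 1]))
        assert redundancy([0], table) == pytest.approx(1.0)

    def test_redundancy_two_independent_features(self):
        # four-term expansion: (H1 + 0 + 0 + H2) / 4
        x1 = np.array([0, 0, 1, 1])
        x2 = np.array([0, 1, 0, 1])
        table = DiscreteFeatureSet(np.stack([x1, x2], axis=1),
                                   np.array([0, 0, 1, 1]))
        assert redundancy([0, 1], table) == pytest.approx(0.5, abs=1e-12)

    def test_redundancy_duplicated_feature_all_terms_equal(self):
        x = np.array([0, 1, 0, 1])
        table = DiscreteFeatureSet(np.stack([x, x], axis=1),
                                   np.array([0, 0, 1, 1]))
        assert redundancy([0, 1], table) == pytest.approx(1.0, abs=1e-12)

    def test_loop_oracle_on_random_set(self):
        rng = np.random.default_rng(6)
        cols = rng.integers(0, 3, size=(40, 5))
        y = rng.integers(0, 2, 40)
        table = DiscreteFeatureSet(cols, y)
        s = [0, 2, 4]
        d_oracle = np.mean([brute_force_mi(cols[:, i], y) for i in s])
        r_oracle = np.mean(
            [brute_force_mi(cols[:, i], cols[:, j]) for i in s for j in s]
        )
        assert relevance(s, table) == pytest.approx(d_oracle, abs=1e-12)
        assert redundancy(s, table) == pytest.approx(r_oracle, abs=1e-12)

    def test_empty_set_rejected(self):
        table = DiscreteFeatureSet(np.zeros((4, 1), dtype=int),
                                   np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            relevance([], table)
        with pytest.raises(ValueError):
            redundancy([], table)


class TestGreedySelection:
    def test_single_pick_is_max_relevance(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 60)
        cols = np.stack([y, rng.integers(0, 3, 60), rng.integers(0, 3, 60)],
                        axis=1)
        result = mrmr_select(DiscreteFeatureSet(cols, y), 1)
        assert result.ranked_indices == [0]

    def test_duplicate_of_label_rejected_for_redundancy(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 200)
        # weakly relevant, partly independent of y, lower entropy than y
        weak = y * (rng.random(200) < 0.6).astype(int)
        cols = np.stack([y, y.copy(), weak], axis=1)
        result = mrmr_select(DiscreteFeatureSet(cols, y), 2, "difference")
        assert result.ranked_indices[0] == 0
        # the exact duplicate of the first pick adds maximal redundancy,
        # so the weak independent feature wins the second step
        assert result.ranked_indices == [0, 2]
        # exhaustive confirmation over both 2-subsets containing the first pick
        dup_val = criterion_value([0, 1], DiscreteFeatureSet(cols, y), "difference")
        weak_val = criterion_value([0, 2], DiscreteFeatureSet(cols, y), "difference")
        assert weak_val > dup_val

    @pytest.mark.parametrize("criterion", ["difference", "quotient"])
    def test_greedy_matches_exhaustive_stepwise_maximization(self, criterion):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n_feat = int(rng.integers(3, 9))
            cols = rng.integers(0, 3, size=(30, n_feat))
            y = rng.integers(0, 2, 30)
            table = DiscreteFeatureSet(cols, y)
            result = mrmr_select(table, 2, criterion)
            # oracle: best first by relevance, then exhaustive 2nd pick
            rels = [brute_force_mi(cols[:, i], y) for i in range(n_feat)]
            first = int(np.argmax(rels))
            best_second, best_val = None, -np.inf
            for j in range(n_feat):
                if j == first:
                    continue
                val = criterion_value([first, j], table, criterion)
                if val > best_val + 1e-12:
                    best_second, best_val = j, val
            assert result.ranked_indices == [first, best_second]

    def test_ranking_has_distinct_indices_and_recorded_scores(self):
        rng = np.random.default_rng(10)
        cols = rng.integers(0, 3, size=(40, 6))
        y = rng.integers(0, 2, 40)
        result = mrmr_select(DiscreteFeatureSet(cols, y), 6)
        assert sorted(result.ranked_indices) == list(range(6))
        assert len(result.scores) == len(result.relevance) == 6

    def test_k_out_of_range_rejected(self):
        table = DiscreteFeatureSet(np.zeros((4, 2), dtype=int),
                                   np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            mrmr_select(table, 3)

    def test_selection_invariant_to_affine_feature_maps(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(80, 5))
        y = (x[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(int)
        r1 = select_features(x, y, 3)
        r2 = select_features(x * np.array([2.0, 0.5, 10.0, 1.0, 3.0]) + 1.0, y, 3)
        assert r1.ranked_indices == r2.ranked_indices


class TestDiscriminativeRanking:
    def test_shape_features_more_relevant_than_injected_noise(self):
        """Compactness and aspect ratio carry far more class information than
        pure-noise columns, so they dominate the relevance component that
        drives the first mRMR pick.

        (Note the full greedy ordering under the diagonal-inclusive
        difference criterion intentionally dilutes redundancy, so a later
        greedy position is not a pure relevance ranking; the discriminative
        check is therefore on relevance and on the maximal-relevance first
        pick.)
        """
        from nodulecad import GeneratorConfig, generate_dataset
        from nodulecad.mrmr import discretize_table, mutual_information
        from nodulecad.pipeline import FeatureExtractor
        from nodulecad.shape import GEO_NAMES

        idx_comp = GEO_NAMES.index("geo_compactness")
        idx_ar = GEO_NAMES.index("geo_aspect_ratio")
        wins = 0
        n_runs = 30
        for seed in range(n_runs):
            ds = generate_dataset(GeneratorConfig(seed=seed, class_separation=1.0))
            table = FeatureExtractor().fit(ds).geometric_table(ds)
            rng = np.random.default_rng(1000 + seed)
            values = np.hstack([table.values, rng.normal(size=(len(ds), 3))])
            disc, _ = discretize_table(values, table.y)
            mi = [
                mutual_information(disc.columns[:, j], disc.class_labels)
                for j in range(values.shape[1])
            ]
            noise_max = max(mi[10:])
            first_pick = select_features(values, table.y, 1).ranked_indices[0]
            wins += (mi[idx_comp] > noise_max and mi[idx_ar] > noise_max
                     and first_pick < 10)
        assert wins / n_runs >= 0.95
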