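"""Cross-validation splits, ranking metrics and protocol runs."""

import numpy as np
import pytest

import pmfmda.evaluation as ev
from pmfmda import synth
from pmfmda.model import Hyperparams, PMFMDA
from conftest import auc_pair_count_oracle, average_precision_oracle


@pytest.fixture
def planted():
    spec = synth.SynthSpec(n_mirnas=20, n_diseases=12, latent_dim=3,
                           density=0.18, seed=42)
    return synth.generate_planted_associations(spec)


class TestSplits:
    def test_kfold_exact_division(self, planted):
        splits = ev.make_kfold_splits(planted.assoc, k=5, seed=0)
        sizes = sorted(len(s.test_pairs) for s in splits)
        n = planted.assoc.n_associations
        assert sum(sizes) == n
        assert sizes[-1] - sizes[0] <= 1

    def test_kfold_partitions_positives(self, planted):
        splits = ev.make_kfold_splits(planted.assoc, k=4, seed=1)
        all_test = [p for s in splits for p in s.test_pairs]
        assert len(all_test) == len(set(all_test)) == planted.assoc.n_associations
        assert set(all_test) == set(planted.assoc.pairs())

    def test_kfold_train_matrices_zero_their_tests(self, planted):
        for s in ev.make_kfold_splits(planted.assoc, k=3, seed=2):
            for i, j in s.test_pairs:
                assert s.train.values[i, j] == 0
            # everything else untouched
            diff = planted.assoc.values - s.train.values
            assert int(diff.sum()) == len(s.test_pairs)

    def test_kfold_too_many_folds_errors(self, tiny_assoc):
        with pytest.raises(ValueError):
            ev.make_kfold_splits(tiny_assoc, k=50)

    def test_loocv_one_split_per_association(self, planted):
        splits = ev.make_loocv_splits(planted.assoc)
        assert len(splits) == planted.assoc.n_associations
        for s in splits:
            (i, j), = s.test_pairs
            assert planted.assoc.values[i, j] == 1
            assert s.train.values[i, j] == 0
            assert (planted.assoc.values - s.train.values).sum() == 1

    def test_loocv_single_association(self):
        from pmfmda.io import AssociationMatrix
        a = AssociationMatrix(["m"], ["d"], np.array([[1.0]]))
        (s,) = ev.make_loocv_splits(a)
        assert s.train.values.sum() == 0

    def test_cvd_zeroes_whole_column(self, planted):
        j = int(planted.assoc.values.sum(axis=0).argmax())
        d = planted.assoc.disease_names[j]
        sp = ev.make_cvd_split(planted.assoc, d)
        assert not sp.train.values[:, j].any()
        assert len(sp.test_pairs) == int(planted.assoc.values[:, j].sum())
        # all other columns identical
        others = np.delete(np.arange(planted.assoc.n_diseases), j)
        np.testing.assert_array_equal(sp.train.values[:, others],
                                      planted.assoc.values[:, others])
        # re-adding the test pairs reconstructs Y
        rebuilt = sp.train.values.copy()
        for i, jj in sp.test_pairs:
            rebuilt[i, jj] = 1
        np.testing.assert_array_equal(rebuilt, planted.assoc.values)

    def test_cvd_empty_disease_errors(self, tiny_assoc):
        tiny_assoc.values[:, 2] = 0
        with pytest.raises(ValueError, match="nothing to hold out"):
            ev.make_cvd_split(tiny_assoc, "d2")


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = ev.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert (pts.iloc[0].fpr, pts.iloc[0].tpr) == (0.0, 0.0)
        assert (pts.iloc[-1].fpr, pts.iloc[-1].tpr) == (1.0, 1.0)

    def test_hand_pair_count(self):
        auc, _ = ev.roc_auc([0.9, 0.8, 0.1], [1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            ev.roc_auc([0.1, 0.2], [1, 1])

    def test_mean_half_over_all_labelings(self):
        """With fixed distinct scores, averaging over every 2-class labeling
        of 6 items gives exactly 1/2."""
        import itertools
        scores = [0.1, 0.25, 0.4, 0.55, 0.7, 0.85]
        aucs = []
        for labels in itertools.product([0, 1], repeat=6):
            if 0 < sum(labels) < 6:
                aucs.append(ev.roc_auc(scores, list(labels))[0])
        assert np.mean(aucs) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        auc, _ = ev.roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_count_oracle(scores, labels),
                                    abs=1e-12)


class TestPrAupr:
    def test_perfect_ranking(self):
        aupr, _ = ev.pr_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == 1.0

    def test_single_positive_ranked_last(self):
        n = 8
        scores = np.arange(n, dtype=float)
        labels = np.zeros(n, int)
        labels[0] = 1  # lowest score
        aupr, _ = ev.pr_aupr(scores, labels)
        assert aupr == pytest.approx(1 / n)

    def test_hand_step_rule(self):
        aupr, _ = ev.pr_aupr([3, 2, 1], [1, 0, 1])
        assert aupr == pytest.approx(5 / 6)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            ev.pr_aupr([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_average_precision_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 200))
        scores = np.round(rng.random(n), 2)
        labels = (rng.random(n) < 0.3).astype(int)
        labels[int(rng.integers(n))] = 1
        aupr, _ = ev.pr_aupr(scores, labels)
        assert aupr == pytest.approx(average_precision_oracle(scores, labels),
                                     abs=1e-12)


class TestTopKHits:
    def test_saturation_and_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        positives = np.argsort(-scores)[:5]  # the top-5 by construction
        counts = ev.top_k_hits(scores, positives, [5, 10, 20])
        assert counts[5] == 5
        assert counts[5] <= counts[10] <= counts[20] == 5

    def test_k_beyond_candidates_counts_all(self):
        counts = ev.top_k_hits([0.3, 0.2, 0.1], [0], [2, 10])
        assert counts[10] == 1

    def test_unsorted_ks_rejected(self):
        with pytest.raises(ValueError):
            ev.top_k_hits([0.1], [0], [10, 5])

    def test_random_scores_hypergeometric_expectation(self):
        rng = np.random.default_rng(7)
        total = 0
        reps = 400
        for _ in range(reps):
            scores = rng.random(100)
            positives = rng.choice(100, size=10, replace=False)
            total += ev.top_k_hits(scores, positives, [10])[10]
        assert total / reps == pytest.approx(1.0, abs=0.15)


class TestRunProtocol:
    hp = Hyperparams(latent_dim=3, max_iter=800, tol=1e-8, seed=0)

    def test_kfold_recovers_planted_structure(self, planted):
        rep = ev.run_protocol(
            planted.assoc, protocol="kfold", hyperparams=self.hp, k=5,
            similarity_fn=ev.static_similarity_fn(planted.S_m_true,
                                                  planted.S_d_true),
            split_seed=0)
        assert rep.auc > 0.85
        assert 0 <= rep.aupr <= 1
        assert len(rep.per_fold) == 5
        assert rep.n_test_positives == planted.assoc.n_associations

    def test_identity_scorer_degenerates_to_chance(self, planted):
        """Scoring with the training matrix itself gives every held-out
        positive a zero score, tying it with the zero-scored negatives."""
        splits = ev.make_loocv_splits(planted.assoc)[:10]
        aucs = []
        for sp in splits:
            scores = sp.train.values  # degenerate oracle
            (i, j), = sp.test_pairs
            neg = planted.assoc.values == 0
            s = np.concatenate([[scores[i, j]], scores[neg]])
            l = np.concatenate([[1], np.zeros(int(neg.sum()), int)])
            aucs.append(ev.roc_auc(s, l)[0])
        assert np.mean(aucs) == pytest.approx(0.5, abs=1e-12)

    def test_cvd_reports_hits_and_beats_chance(self, planted):
        d = max(planted.assoc.disease_names,
                key=lambda x: planted.assoc.values[
                    :, planted.assoc.disease_index(x)].sum())
        rep = ev.run_protocol(
            planted.assoc, protocol="cv_d", hyperparams=self.hp,
            diseases=[d],
            similarity_fn=ev.static_similarity_fn(planted.S_m_true,
                                                  planted.S_d_true))
        assert rep.auc > 0.5
        assert rep.top_k_counts
        ks = sorted(rep.top_k_counts)
        counts = [rep.top_k_counts[k] for k in ks]
        assert counts == sorted(counts)
        assert all(rep.top_k_counts[k] <= min(k, rep.n_test_positives)
                   for k in ks)

    def test_leakage_guard_and_reproducibility(self, planted):
        seen = []

        def spy_fn(train):
            for i, j in zip(*np.nonzero(planted.assoc.values != train.values)):
                assert train.values[i, j] == 0
            seen.append(train.values.sum())
            from pmfmda.similarity import build_similarities
            return build_similarities(train)

        rep1 = ev.run_protocol(planted.assoc, protocol="kfold", k=3,
                               hyperparams=self.hp, similarity_fn=spy_fn,
                               split_seed=5)
        rep2 = ev.run_protocol(planted.assoc, protocol="kfold", k=3,
                               hyperparams=self.hp, similarity_fn=spy_fn,
                               split_seed=5)
        assert seen  # similarities really were recomputed per fold
        assert rep1.auc == rep2.auc and rep1.aupr == rep2.aupr

    def test_unknown_protocol_errors(self, planted):
        with pytest.raises(ValueError, match="unknown protocol"):
            ev.run_protocol(planted.assoc, protocol="bootstrap")


class TestGridSearch:
    def test_singleton_grid(self, planted):
        hp = Hyperparams(latent_dim=3, max_iter=300, tol=1e-7, seed=0)
        table, best = ev.grid_search(
            planted.assoc, [(1.0, 1.0, 0.005, 0.005)], protocol="kfold",
            hyperparams=hp, k=3,
            similarity_fn=ev.static_similarity_fn(planted.S_m_true,
                                                  planted.S_d_true))
        assert len(table) == 1
        assert best["lambda_1"] == 0.005

    def test_table_covers_grid_and_dict_expansion(self, planted):
        hp = Hyperparams(latent_dim=3, max_iter=150, tol=1e-6, seed=0)
        grid = {"lambda_u": [1.0], "lambda_v": [1.0],
                "lambda_1": [0.0, 0.005], "lambda_2": [0.005]}
        table, best = ev.grid_search(
            planted.assoc, grid, protocol="kfold", hyperparams=hp, k=3,
            similarity_fn=ev.static_similarity_fn(planted.S_m_true,
                                                  planted.S_d_true))
        assert len(table) == 2
        assert best["auc"] == table["auc"].max()

    def test_empty_grid_errors(self, planted):
        with pytest.raises(ValueError, match="empty grid"):
            ev.grid_search(planted.assoc, [])
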