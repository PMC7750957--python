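import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from swikit.scales import STANDARD_AMINO_ACIDS, get_scale
from swikit.seqio import SequenceRecord
from swikit.synthetic import LabelLink, SyntheticSpec, generate_dataset, perturb_weights
from swikit.training import (
    LabeledDataset,
    TrainingConfig,
    auc,
    bootstrap_resample,
    build_folds,
    composition_matrix,
    fit_logistic,
    greedy_cluster,
    optimize_weights,
    train_swi,
)


def brute_force_auc(scores, labels):
    """O(n^2) pairwise oracle: wins + half ties over positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_dataset(rng, n=60, n_clusters=6, length=30):
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))
        records.append((SequenceRecord(f"s{i}", seq), int(rng.random() < 0.5), f"c{i % n_clusters}"))
    # guarantee both classes
    records[0] = (records[0][0], 0, records[0][2])
    records[1] = (records[1][0], 1, records[1][2])
    return LabeledDataset(tuple(records))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.1], [1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_four_point_example(self):
        # 4 positive-negative pairs, 3 wins
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    def test_agrees_with_brute_force_and_sklearn(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            value = auc(scores, labels)
            assert value == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert value == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        # AUC depends on ranks only: trained weights are identified only up
        # to a positive affine transform and must travel with a calibration
        counts, lengths = composition_matrix(
            ["".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=25)) for _ in range(40)]
        )
        labels = np.array([0, 1] * 20)
        for _ in range(5):
            w = rng.normal(size=20)
            base = auc(counts @ w / lengths, labels)
            assert auc(counts @ (w + 3.7) / lengths, labels) == pytest.approx(base)
            assert auc(counts @ (2.5 * w) / lengths, labels) == pytest.approx(base)


class TestBuildFolds:
    def test_greedy_balancing_on_known_instance(self):
        sizes = [5, 5, 4, 4, 3, 3, 2, 2, 1, 1]
        records = []
        for ci, size in enumerate(sizes):
            for m in range(size):
                records.append((SequenceRecord(f"s{ci}_{m}", "ACDEFGHIK"), m % 2, f"c{ci}"))
        dataset = LabeledDataset(tuple(records))
        folds = build_folds(dataset, 2, seed=0)
        fold_sizes = [len(ix) for ix in folds.fold_indices(dataset)]
        assert sorted(fold_sizes) == [15, 15]  # greedy bin-packing oracle
        assert set(folds.fold_of_cluster.values()) == {0, 1}

    def test_one_cluster_per_fold_when_counts_match(self, rng):
        dataset = make_dataset(rng, n=12, n_clusters=4)
        folds = build_folds(dataset, 4)
        assert sorted(folds.fold_of_cluster.values()) == [0, 1, 2, 3]

    def test_fewer_clusters_than_folds_rejected(self, rng):
        dataset = make_dataset(rng, n=10, n_clusters=1)
        with pytest.raises(ValueError, match="folds"):
            build_folds(dataset, 2)

    def test_deterministic_given_seed(self, rng):
        dataset = make_dataset(rng, n=40, n_clusters=8)
        assert build_folds(dataset, 3, seed=5) == build_folds(dataset, 3, seed=5)


class TestBootstrap:
    def test_counts_per_class(self, rng):
        labels = np.array([0] * 30 + [1] * 10)
        ix = bootstrap_resample(labels, 1000, rng)
        assert len(ix) == 2000
        assert (labels[ix] == 1).sum() == 1000

    def test_same_seed_identical(self):
        labels = np.array([0, 1] * 10)
        a = bootstrap_resample(labels, 50, np.random.default_rng(3))
        b = bootstrap_resample(labels, 50, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            bootstrap_resample(np.ones(10), 5, rng)


class TestOptimizeWeights:
    def _separable_sample(self, rng, n=80):
        planted = np.array(get_scale("swi_final").as_vector())
        seqs = ["".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=60)) for _ in range(n)]
        counts, lengths = composition_matrix(seqs)
        scores = counts @ planted / lengths
        labels = (scores > np.median(scores)).astype(int)
        return counts, lengths, labels, planted

    def test_separable_sample_reaches_auc_one(self, rng):
        counts, lengths, labels, planted = self._separable_sample(rng)
        initial = planted * (1 + rng.uniform(-0.2, 0.2, 20))
        result = optimize_weights(counts, lengths, labels, initial)
        assert result.auc_final >= 0.999

    def test_perfect_initial_weights_stay_perfect(self, rng):
        counts, lengths, labels, planted = self._separable_sample(rng)
        result = optimize_weights(counts, lengths, labels, planted)
        assert result.auc_initial == 1.0
        assert result.auc_final == 1.0

    def test_monotone_improvement_over_initial(self, rng):
        for _ in range(5):
            counts, lengths = composition_matrix(
                ["".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=40)) for _ in range(60)]
            )
            labels = rng.integers(0, 2, 60)
            labels[:2] = [0, 1]
            initial = rng.uniform(0.3, 1.0, 20)
            result = optimize_weights(counts, lengths, labels, initial)
            assert result.auc_final >= result.auc_initial - 1e-12

    def test_single_class_rejected(self, rng):
        counts, lengths = composition_matrix(["ACDEFGHIK"] * 4)
        with pytest.raises(ValueError, match="both classes"):
            optimize_weights(counts, lengths, np.ones(4), np.ones(20))


class TestTrainSWI:
    def test_structural_contract_small_config(self, rng):
        dataset = make_dataset(rng, n=60, n_clusters=6)
        config = TrainingConfig(n_folds=2, n_bootstrap=3, n_per_class=20, seed=0)
        result = train_swi(dataset, get_scale("smith2003"), config)
        assert result.fold_weights.shape == (2, 20)
        assert result.test_aucs.shape == (2,)
        final = np.array(result.final.as_vector())
        assert np.allclose(final, result.fold_weights.mean(axis=0))

    def test_same_seed_bitwise_identical(self, rng):
        dataset = make_dataset(rng, n=40, n_clusters=5)
        config = TrainingConfig(n_folds=2, n_bootstrap=2, n_per_class=10, seed=7)
        a = train_swi(dataset, get_scale("smith2003"), config)
        b = train_swi(dataset, get_scale("smith2003"), config)
        assert np.array_equal(a.fold_weights, b.fold_weights)
        assert np.array_equal(a.test_aucs, b.test_aucs)

    def test_recovers_planted_weights_on_synthetic_data(self):
        # scaled-down end-to-end parameter-recovery experiment
        planted = get_scale("swi_final")
        dataset = generate_dataset(SyntheticSpec(seed=0))
        initial = perturb_weights(planted, 0.3, rng=123)
        config = TrainingConfig(n_folds=3, n_bootstrap=20, n_per_class=100, seed=1)
        result = train_swi(dataset, initial, config)
        rho = spearmanr(result.final.as_vector(), planted.as_vector()).statistic
        assert rho >= 0.8
        assert result.test_aucs.mean() >= 0.85
        assert np.all(result.test_aucs >= result.initial_test_aucs - 1e-9)


class TestFitLogistic:
    def test_recovers_simulated_calibration(self):
        rng = np.random.default_rng(7)
        a_true, b_true = 81.05812, -62.7775
        x = rng.uniform(0.55, 1.0, 10000)
        p = 1 / (1 + np.exp(-(a_true * x + b_true)))
        y = (rng.random(10000) < p).astype(int)
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.calibration.a == pytest.approx(a_true, rel=0.10)
        assert fit.calibration.b == pytest.approx(b_true, rel=0.10)

    def test_null_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=5000)
        y = (rng.random(5000) < 0.5).astype(int)
        fit = fit_logistic(x, y)
        assert abs(fit.calibration.a) < 3 * fit.a_stderr

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.linspace(0, 0.4, 50), np.linspace(0.6, 1.0, 50)])
        y = np.array([0] * 50 + [1] * 50)
        assert not fit_logistic(x, y).converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic([0.1, 0.2], [1, 1])


class TestGreedyCluster:
    def test_identical_sequences_co_cluster(self):
        records = [SequenceRecord("a", "MKVLWAALLV"), SequenceRecord("b", "MKVLWAALLV")]
        assignment = greedy_cluster(records)
        assert assignment["a"] == assignment["b"]

    def test_disjoint_kmer_sets_separate(self):
        records = [SequenceRecord("a", "AAAAAAAAAA"), SequenceRecord("b", "WWWWWWWWWW")]
        assignment = greedy_cluster(records)
        assert assignment["a"] != assignment["b"]

    def test_mutated_family_co_clusters_randoms_stay_out(self, rng):
        ancestor = "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=120))
        records = []
        for i in range(10):  # 5% substitution copies of one ancestor
            seq = list(ancestor)
            for j in range(len(seq)):
                if rng.random() < 0.05:
                    seq[j] = rng.choice(list(STANDARD_AMINO_ACIDS))
            records.append(SequenceRecord(f"fam{i}", "".join(seq)))
        for i in range(10):
            records.append(
                SequenceRecord(f"rand{i}", "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=120)))
            )
        assignment = greedy_cluster(records)
        family_clusters = {assignment[f"fam{i}"] for i in range(10)}
        assert len(family_clusters) == 1
        assert all(assignment[f"rand{i}"] not in family_clusters for i in range(10))

    def test_deterministic(self, rng):
        records = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=50)))
            for i in range(20)
        ]
        assert greedy_cluster(records) == greedy_cluster(records)
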