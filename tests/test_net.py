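"""Classifier training, cross-validation, ROC/AUC and bootstrap CIs."""

import numpy as np
import pytest

from shankgait import net
from shankgait import reference as ref
from shankgait import synthetic as syn
from shankgait.net import NetConfig


def _auc_rank_oracle(scores, positives):
    """O(n^2) Mann-Whitney AUC: P(random positive outranks negative)."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def _blobs(rng, n_per=100, spread=1.0):
    centers = np.array(
        [[0, 0, 0, 0, 0, 0], [3, 3, 0, 0, 0, 0], [0, 0, 3, 3, 0, 0]], float
    )
    X = np.vstack(
        [c + spread * rng.standard_normal((n_per, 6)) for c in centers]
    )
    y = np.repeat(["a", "b", "c"], n_per)
    return X, y


class TestTrainMlp:
    def test_linearly_separable_reaches_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-4, 0.5, (40, 6)), rng.normal(4, 0.5, (40, 6))])
        y = np.repeat([0, 1], 40)
        model = net.train_mlp(X, y, NetConfig(seed=1))
        assert (model.predict(X) == y).mean() == 1.0

    def test_same_seed_identical_weights(self, rng):
        X, y = _blobs(rng, n_per=40)
        m1 = net.train_mlp(X, y, NetConfig(seed=7))
        m2 = net.train_mlp(X, y, NetConfig(seed=7))
        for w1, w2 in zip(m1["mlp"].coefs_, m2["mlp"].coefs_):
            assert np.array_equal(w1, w2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            net.train_mlp(rng.normal(size=(10, 6)), np.zeros(10))

    def test_near_bayes_error_on_gaussian_blobs(self, rng):
        """Known overlap: test error at most double the ~5% Bayes rate."""
        Xtr, ytr = _blobs(rng, n_per=100, spread=0.95)
        Xte, yte = _blobs(rng, n_per=200, spread=0.95)
        model = net.train_mlp(Xtr, ytr, NetConfig(seed=3))
        err = (model.predict(Xte) != yte).mean()
        assert err <= 0.10


class TestKfoldCv:
    def test_fold_sizes_for_reference_cohort(self, small_cohort):
        X, y = net.cohort_features(small_cohort)
        probs, classes, info = net.kfold_cv_predict(X, y, k=8, seed=0)
        assert probs.shape == (161, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert info["resampled_partitions"] == 0
        # 161 subjects over 8 folds -> folds of 20/21, training sets ~141
        from sklearn.model_selection import KFold

        sizes = [len(te) for _, te in KFold(8, shuffle=True,
                                            random_state=0).split(X)]
        assert set(sizes) <= {20, 21}

    def test_leave_one_out_limit_runs(self, rng):
        X = np.vstack([rng.normal(-2, 1, (6, 6)), rng.normal(2, 1, (6, 6))])
        y = np.repeat([0, 1], 6)
        probs, classes, _ = net.kfold_cv_predict(X, y, k=len(y), seed=1)
        assert probs.shape == (12, 2)

    def test_label_shuffled_cohort_has_chance_auc(self, small_cohort):
        """Pooled CV AUC on permuted labels is 0.5 +/- 0.05 per class
        (averaged over permutation replicates)."""
        X, y = net.cohort_features(small_cohort)
        rng = np.random.default_rng(0)
        aucs = {c: [] for c in np.unique(y)}
        # 30 replicates: per-replicate AUC has sd ~0.06 under the null,
        # so the mean carries ~0.012 Monte-Carlo error against the 0.05 band
        for rep in range(30):
            yp = rng.permutation(y)
            probs, classes, _ = net.kfold_cv_predict(X, yp, k=8, seed=1000 + rep)
            for r in net.roc_auc_ovr(probs, yp, classes):
                aucs[r.label].append(r.auc)
        for c, vals in aucs.items():
            assert abs(np.mean(vals) - 0.5) <= 0.05, (c, np.mean(vals))


class TestRocAuc:
    def test_perfect_and_constant_scores(self):
        y = np.repeat(["neg", "pos"], 10)
        perfect = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        probs = np.column_stack([1 - perfect, perfect])
        rocs = net.roc_auc_ovr(probs, y, classes=np.array(["neg", "pos"]))
        assert rocs[1].auc == 1.0
        const = np.full((20, 2), 0.5)
        rocs = net.roc_auc_ovr(const, y, classes=np.array(["neg", "pos"]))
        assert rocs[0].auc == 0.5 and rocs[1].auc == 0.5

    def test_trapezoid_equals_rank_oracle(self, rng):
        """Trapezoid AUC equals the pairwise-comparison statistic to 1e-12."""
        scores = np.round(rng.uniform(size=50), 2)  # force ties
        y = rng.choice(["x", "o"], size=50)
        probs = np.column_stack([1 - scores, scores])
        rocs = net.roc_auc_ovr(probs, y, classes=np.array(["o", "x"]))
        oracle = _auc_rank_oracle(scores, y == "x")
        assert abs(rocs[1].auc - oracle) < 1e-12

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=60)
        y = rng.choice([0, 1], size=60)
        a1 = net.roc_auc_ovr(np.column_stack([1 - scores, scores]),
                             y, classes=np.array([0, 1]))[1].auc
        warped = scores**3  # strictly monotone
        a2 = net.roc_auc_ovr(np.column_stack([1 - warped, warped]),
                             y, classes=np.array([0, 1]))[1].auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            net.roc_auc_ovr(np.full((4, 1), 0.5), np.zeros(4),
                            classes=np.array([0.0]))


class TestBootstrap:
    def _tight_cohort(self, n_per=18):
        groups = []
        for stage in ref.STAGES:
            means = {p: ref.RIGHT_SENSOR[p][stage][0] for p in ref.PARAMETERS}
            sds = {p: 0.25 * ref.RIGHT_SENSOR[p][stage][1]
                   for p in ref.PARAMETERS}
            groups.append(syn.GroupSpec(stage, n_per, means, sds))
        return syn.make_cohort(groups, seed=77)

    def test_tiny_bootstrap_returns_ordered_bounds(self, rng):
        X = np.vstack([rng.normal(-2, 1, (8, 6)), rng.normal(2, 1, (8, 6))])
        y = np.repeat([0, 1], 8)
        cis = net.bootstrap_auc_ci(X, y, B=2, k=4, seed=5)
        for ci in cis:
            assert ci.lower <= ci.upper

    def test_separated_classes_high_frail_lower_bound(self):
        table = self._tight_cohort()
        X, y = net.cohort_features(table)
        cis = net.bootstrap_auc_ci(X, y, B=20, k=6, seed=9)
        frail = next(c for c in cis if c.label == "frail")
        assert frail.lower > 0.8

    def test_same_seed_identical_ci(self, rng):
        X = np.vstack([rng.normal(-2, 1, (10, 6)), rng.normal(2, 1, (10, 6))])
        y = np.repeat([0, 1], 10)
        a = net.bootstrap_auc_ci(X, y, B=5, k=4, seed=3)
        b = net.bootstrap_auc_ci(X, y, B=5, k=4, seed=3)
        assert [(c.lower, c.upper) for c in a] == [(c.lower, c.upper) for c in b]


def test_frail_auc_exceeds_prefrail_auc_across_replicates():
    """On synthetic reference cohorts the frail-vs-rest AUC beats the
    pre-frail-vs-rest AUC in at least 90% of seeded replicates — the
    pre-frail stage is the hardest to separate."""
    wins = 0
    n_rep = 20
    for s in range(n_rep):
        table = syn.make_cohort(seed=9000 + s)
        X, y = net.cohort_features(table)
        probs, classes, _ = net.kfold_cv_predict(X, y, k=8, seed=s)
        aucs = {r.label: r.auc for r in net.roc_auc_ovr(probs, y, classes)}
        wins += aucs["frail"] > aucs["pre-frail"]
    assert wins / n_rep >= 0.9
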