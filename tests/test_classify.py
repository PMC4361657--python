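import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tolerograph import (CvConfig, DataError, ExpressionMatrix, SimConfig,
                         cross_validate, feature_stability, generate_dataset,
                         make_folds, permute_group_labels, roc_auc,
                         select_features)
from tolerograph.core import NONTOL, TOL, Sample


def pair_counting_auc(scores, truth, positive=TOL):
    """Concordant-pair fraction with half-credit for ties."""
    pos = [s for s, t in zip(scores, truth) if t == positive]
    neg = [s for s, t in zip(scores, truth) if t != positive]
    total = len(pos) * len(neg)
    c = sum(1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg)
    return c / total


class TestMakeFolds:
    def test_study_sized_partition(self):
        _, samples, _ = generate_dataset(SimConfig(
            n_probes=10, n_tol_up=0, n_tol_down=0, n_ntol_up=0, n_ntol_down=0,
            n_confounded=0, seed=1))
        folds = make_folds(samples, CvConfig(n_folds=10, seed=1))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [3, 3, 3, 3, 3, 3, 3, 3, 4, 4]   # 32 patients, 10 folds
        flat = [sid for f in folds for sid in f]
        assert len(flat) == len(set(flat)) == 32
        # per-class fold counts differ by <= 1
        group_of = {s.sample_id: s.group for s in samples}
        for g, n in ((TOL, 15), (NONTOL, 17)):
            counts = [sum(1 for sid in f if group_of[sid] == g) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_controls_excluded(self):
        _, samples, _ = generate_dataset(SimConfig(
            n_probes=10, n_tol_up=0, n_tol_down=0, n_ntol_up=0, n_ntol_down=0,
            n_confounded=0, seed=2))
        folds = make_folds(samples, CvConfig(seed=2))
        group_of = {s.sample_id: s.group for s in samples}
        assert all(group_of[sid] != "CTRL" for f in folds for sid in f)

    def test_seed_determinism(self):
        _, samples, _ = generate_dataset(SimConfig(
            n_probes=10, n_tol_up=0, n_tol_down=0, n_ntol_up=0, n_ntol_down=0,
            n_confounded=0, seed=3))
        assert make_folds(samples, CvConfig(seed=5)) == \
            make_folds(samples, CvConfig(seed=5))


class TestSelectFeatures:
    def test_k_equals_n_returns_all(self):
        x = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3", "s4"],
                             np.random.default_rng(0).normal(size=(2, 4)))
        with pytest.warns(UserWarning):
            feats = select_features(x, [1, 1, 0, 0], k=5)
        assert sorted(feats) == ["a", "b"]

    def test_planted_features_dominate_topk(self):
        successes = 0
        for seed in range(5):
            cfg = SimConfig(n_probes=2000, n_tol_up=10, n_tol_down=10,
                            n_ntol_up=0, n_ntol_down=0, n_confounded=0,
                            effect_log2=1.5, sd_range=(0.4, 0.4), seed=seed)
            x, samples, truth = generate_dataset(cfg)
            patients = [s for s in samples if s.group in (TOL, NONTOL)]
            sub = x.subset_samples([s.sample_id for s in patients])
            labels = np.array([1 if s.group == TOL else 0 for s in patients])
            feats = select_features(sub, labels, k=20, selector="sam_d")
            planted = set(truth.probes_in("TOL_UP", "TOL_DOWN"))
            if planted <= set(feats):
                successes += 1
        assert successes >= 4

    def test_equal_strength_lexicographic_tiebreak(self):
        vals = np.array([[0.0, 0, 1, 1], [0, 0, 1, 1]])
        x = ExpressionMatrix(["zz", "aa"], ["s1", "s2", "s3", "s4"], vals)
        feats = select_features(x, [1, 1, 0, 0], k=1, selector="snr")
        assert feats == ["aa"]


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [TOL, TOL, NONTOL, NONTOL],
                            bootstrap_reps=50)
        assert auc == 1.0

    def test_all_equal_scores_half(self):
        _, auc, _ = roc_auc([0.5] * 6, [TOL] * 3 + [NONTOL] * 3,
                            bootstrap_reps=50)
        assert auc == 0.5

    def test_one_swap_gives_three_quarters(self):
        _, auc, _ = roc_auc([0.9, 0.4, 0.8, 0.3],
                            [TOL, TOL, NONTOL, NONTOL], bootstrap_reps=50)
        assert auc == pytest.approx(0.75)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False),
                              st.booleans()),
                    min_size=4, max_size=12))
    def test_matches_pair_counting_oracle(self, items):
        truth = [TOL if b else NONTOL for _, b in items]
        if len(set(truth)) < 2:
            return
        scores = [s for s, _ in items]
        _, auc, _ = roc_auc(scores, truth, bootstrap_reps=10)
        assert auc == pytest.approx(pair_counting_auc(scores, truth),
                                    abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [TOL, TOL], bootstrap_reps=10)


class TestCrossValidate:
    def test_positive_control_high_accuracy(self):
        cfg = SimConfig(n_probes=1000, n_tol_up=10, n_tol_down=10,
                        n_ntol_up=0, n_ntol_down=0, n_confounded=0,
                        effect_log2=2.0, sd_range=(0.4, 0.4), seed=51)
        x, samples, _ = generate_dataset(cfg)
        report = cross_validate(x, samples,
                                CvConfig(seed=51, bootstrap_ci_reps=100))
        assert report.weighted_accuracy >= 0.9
        assert report.auc >= 0.95
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1] + 1e-9

    def test_partition_and_conservation_invariants(self):
        cfg = SimConfig(n_probes=300, n_tol_up=5, n_tol_down=5, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0, seed=52)
        x, samples, _ = generate_dataset(cfg)
        report = cross_validate(x, samples,
                                CvConfig(seed=52, bootstrap_ci_reps=50))
        held = [sid for f in report.folds for sid in f.held_out]
        assert len(held) == len(set(held)) == 32
        total = sum(sum(r.values()) for r in report.confusion.values())
        assert total == 32
        assert all(c <= 10 for c in report.stability.values())

    def test_no_leakage_from_holdout_labels(self):
        # corrupting the held-out samples' labels must not change the
        # features selected in any fold
        cfg = SimConfig(n_probes=300, n_tol_up=5, n_tol_down=5, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0, seed=53)
        x, samples, _ = generate_dataset(cfg)
        r1 = cross_validate(x, samples, CvConfig(seed=53, bootstrap_ci_reps=10))
        flipped = [s.with_group({TOL: NONTOL, NONTOL: TOL}.get(s.group, s.group))
                   if s.sample_id in set(r1.folds[0].held_out) else s
                   for s in samples]
        # folds change when labels change (stratification), so compare the
        # fold whose training set is identical: rebuild fold 0 by hand
        from tolerograph.classify import select_features as sf
        train_ids = [s.sample_id for s in samples
                     if s.group in (TOL, NONTOL)
                     and s.sample_id not in set(r1.folds[0].held_out)]
        sub = x.subset_samples(train_ids)
        group_of = {s.sample_id: s.group for s in samples}
        labels = np.array([1 if group_of[sid] == TOL else 0
                           for sid in train_ids])
        assert sf(sub, labels, 20, "sam_d") == r1.folds[0].features

    def test_permuted_labels_near_chance(self):
        accs = []
        for seed in range(3):
            cfg = SimConfig(n_probes=500, n_tol_up=0, n_tol_down=0,
                            n_ntol_up=0, n_ntol_down=0, n_confounded=0,
                            seed=60 + seed)
            x, samples, _ = generate_dataset(cfg)
            perm = permute_group_labels(samples, seed=60 + seed)
            report = cross_validate(x, perm,
                                    CvConfig(seed=60 + seed,
                                             bootstrap_ci_reps=10))
            accs.append(report.weighted_accuracy)
        assert np.mean(accs) < 0.72   # binomial upper bound around 17/32


class TestFeatureStability:
    def test_counts_and_ordering(self):
        cfg = SimConfig(n_probes=500, n_tol_up=5, n_tol_down=5, n_ntol_up=0,
                        n_ntol_down=0, n_confounded=0, effect_log2=2.0,
                        sd_range=(0.3, 0.3), seed=61)
        x, samples, truth = generate_dataset(cfg)
        report = cross_validate(x, samples,
                                CvConfig(seed=61, bootstrap_ci_reps=10))
        stable = feature_stability(report, min_count=9)
        counts = [c for _, c in stable]
        assert counts == sorted(counts, reverse=True)
        planted = set(truth.probes_in("TOL_UP", "TOL_DOWN"))
        assert len({p for p, _ in stable} & planted) >= 8
        # min_count=0 returns every ever-selected feature
        assert len(feature_stability(report, min_count=0)) == \
            len(report.stability)
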