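"""Feature extraction, shrinkage LDA, AUC, donor-selection evaluation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rsvpcar as rc
from rsvpcar.synthetic_cohort import ClusterDispersion

from conftest import two_cluster_spec


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(target > nontarget) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFeatures:
    def test_default_dimensionality_is_96(self, small_epochs):
        cfg = rc.FeatureConfig()
        feats, labels = rc.extract_features(small_epochs, cfg)
        assert feats.shape == (small_epochs.n_epochs, 96)
        assert cfg.n_features() == 96
        np.testing.assert_array_equal(labels, small_epochs.labels)

    def test_single_sample_bins_are_identity(self, small_epochs):
        cfg = rc.FeatureConfig(bin_width=5.0)  # one sample at 200 Hz
        feats, _ = rc.extract_features(small_epochs, cfg)
        lo = small_epochs.sample_index(0.0)
        raw = small_epochs.data[:, :, lo : lo + 160].reshape(
            small_epochs.n_epochs, -1
        )
        np.testing.assert_allclose(feats, raw, rtol=1e-6)

    def test_constant_epoch_gives_constant_features(self):
        ep = rc.EpochSet(
            "S", np.full((3, 2, 100), 2.5), [1, 0, 0], ["A", "B", "C"],
            rate=200.0, window=(0.0, 500.0), channel_names=["CZ", "PZ"],
        )
        cfg = rc.FeatureConfig(segment=(0.0, 500.0), bin_width=50.0,
                               channels=("CZ", "PZ"))
        feats, _ = rc.extract_features(ep, cfg)
        np.testing.assert_allclose(feats, 2.5)

    def test_bin_width_must_divide_segment(self):
        with pytest.raises(ValueError, match="divide"):
            rc.FeatureConfig(segment=(0.0, 800.0), bin_width=70.0)


class TestLDA:
    def test_separable_gaussians_high_auc(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal([0, 0], 1.0, size=(500, 2))
        x1 = rng.normal([5, 5], 1.0, size=(500, 2))
        x = np.vstack([x0, x1])
        y = np.array([0] * 500 + [1] * 500)
        clf = rc.fit_lda(x[::2], y[::2])
        assert rc.auc(clf.decision_scores(x[1::2]), y[1::2]) > 0.99

    def test_identical_distributions_chance_auc(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(10):
            x = rng.standard_normal((400, 5))
            y = np.array([0, 1] * 200)
            clf = rc.fit_lda(x[:300], y[:300])
            aucs.append(rc.auc(clf.decision_scores(x[300:]), y[300:]))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_duplicated_column_fits_with_shrinkage(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((60, 4))
        x = np.hstack([x, x[:, :1]])  # singular pooled covariance
        y = np.array([0, 1] * 30)
        clf = rc.fit_lda(x, y, shrinkage=0.1)
        assert clf.weights.shape == (5,)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="target"):
            rc.fit_lda(np.zeros((4, 2)), [1, 1, 1, 1])


class TestAUC:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 1, 1, 1], [0, 1, 0, 1], 0.5),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
        ],
    )
    def test_hand_computed_values(self, scores, labels, expected):
        assert rc.auc(scores, labels) == pytest.approx(expected)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            rc.auc([1.0, 2.0], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            assert rc.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    @given(st.sampled_from([np.exp, np.tanh, lambda s: 3 * s + 1]))
    def test_invariant_under_increasing_transform(self, fn):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(40)
        labels = np.array([0, 1] * 20)
        assert rc.auc(fn(scores), labels) == pytest.approx(rc.auc(scores, labels))


class TestEvaluateModel:
    def make_uniform_cohort(self, n_subjects=4, noise_sd=0.0):
        spec = two_cluster_spec(n_subjects=n_subjects, noise_sd=noise_sd,
                                latencies=(350.0, 350.0))
        return rc.generate_cohort(spec)[0]

    def test_identical_noiseless_cohort_auc_is_one(self):
        cohort = self.make_uniform_cohort()
        for model in ("random", "car"):
            res = rc.evaluate_model(cohort, model, 2, calibration_blocks=1,
                                    reps=2, seed=0)
            np.testing.assert_allclose(res.aucs, 1.0)

    def test_zero_amplitude_cohort_is_chance(self):
        import dataclasses

        spec = two_cluster_spec(n_subjects=6, noise_sd=10.0)
        spec = dataclasses.replace(
            spec, base_amplitude=0.0, between=ClusterDispersion(),
            within=ClusterDispersion(), cluster_latencies=None,
        )
        cohort, _ = rc.generate_cohort(spec)
        res = rc.evaluate_model(cohort, "random", 3, calibration_blocks=1,
                                reps=3, seed=1)
        assert 0.45 <= res.mean_auc <= 0.55

    def test_n_donors_bounds_enforced(self):
        cohort = self.make_uniform_cohort()
        with pytest.raises(ValueError, match="cohort size"):
            rc.evaluate_model(cohort, "random", len(cohort), seed=0)

    def test_car_never_trains_or_scores_leaked_epochs(self):
        cohort = self.make_uniform_cohort(noise_sd=5.0)
        res = rc.evaluate_model(cohort, "car", 2, calibration_blocks=2,
                                seed=0)
        assert res.provenance["leakage_checked"]
        for sid, donor_lists in res.provenance["selected_donors"].items():
            for donors in donor_lists:
                assert sid not in donors
                assert len(donors) == 2
        assert res.provenance["scored_epochs"] == "non-calibration only"

    def test_random_model_repetitions_vary_and_are_seeded(self):
        cohort = self.make_uniform_cohort(n_subjects=6, noise_sd=5.0)
        a = rc.evaluate_model(cohort, "random", 2, calibration_blocks=1,
                              reps=4, seed=7)
        b = rc.evaluate_model(cohort, "random", 2, calibration_blocks=1,
                              reps=4, seed=7)
        np.testing.assert_array_equal(a.aucs, b.aucs)
        assert a.aucs.shape == (6, 4)

    def test_optional_pooling_flags(self):
        """Per-donor z-scoring and nontarget subsampling stay above chance
        and remain deterministic under a fixed seed."""
        cohort = self.make_uniform_cohort(n_subjects=5, noise_sd=5.0)
        a = rc.evaluate_model(cohort, "random", 2, calibration_blocks=1,
                              reps=2, seed=4, zscore_donors=True,
                              nontarget_keep=0.3)
        b = rc.evaluate_model(cohort, "random", 2, calibration_blocks=1,
                              reps=2, seed=4, zscore_donors=True,
                              nontarget_keep=0.3)
        np.testing.assert_array_equal(a.aucs, b.aucs)
        assert a.mean_auc > 0.8  # identical-subject cohort stays separable

    def test_car_beats_random_on_clustered_cohort(self):
        """Donor ranking recovers cluster structure -> higher transfer AUC."""
        spec = two_cluster_spec(
            n_subjects=10, noise_sd=8.0, seed=3,
            paradigm=rc.ParadigmConfig(n_symbols=6, rounds_per_trial=3,
                                       trials_per_block=4, n_blocks=4),
            within=ClusterDispersion(8.0, 0.3, 5.0, 0.03),
            latencies=(280.0, 480.0),
        )
        cohort, table = rc.generate_cohort(spec)
        car = rc.evaluate_model(cohort, "car", 4, calibration_blocks=1, seed=0)
        rnd = rc.evaluate_model(cohort, "random", 4, calibration_blocks=1,
                                reps=5, seed=0)
        assert car.mean_auc > rnd.mean_auc
        # parameter recovery: CAR's donors share the test subject's cluster
        clusters = table.set_index("subject_id")["cluster_id"]
        same = [
            np.mean([clusters[d] == clusters[sid] for d in donors[0]])
            for sid, donors in car.provenance["selected_donors"].items()
        ]
        assert np.mean(same) > 0.9


class TestCompareModels:
    def _result(self, aucs, model="a"):
        aucs = np.asarray(aucs, dtype=float)
        return rc.EvaluationResult(
            model=model, n_donors=1,
            subject_ids=[f"S{i}" for i in range(len(aucs))],
            aucs=aucs[:, None], seeds=[0], calibration_blocks=1,
        )

    def test_identical_samples_t_zero_p_one(self):
        a = self._result([0.6, 0.7, 0.8])
        cmp = rc.compare_models(a, self._result([0.6, 0.7, 0.8], "b"))
        assert cmp.t_stat == 0.0
        assert cmp.p_value == 1.0
        assert not cmp.degenerate

    def test_constant_shift_reported_as_degenerate(self):
        a = self._result([0.6, 0.7, 0.8])
        b = self._result([0.7, 0.8, 0.9], "b")
        cmp = rc.compare_models(a, b)
        assert cmp.degenerate
        assert np.isnan(cmp.p_value)
        assert cmp.mean_difference == pytest.approx(-0.1)

    def test_shifted_gaussians_detected(self):
        rng = np.random.default_rng(9)
        a = self._result(np.clip(rng.normal(0.6, 0.05, 30), 0, 1))
        b = self._result(np.clip(rng.normal(0.7, 0.05, 30), 0, 1), "b")
        cmp = rc.compare_models(a, b)
        assert cmp.p_value < 0.01
        assert cmp.ks_p_a > 0.05  # sample consistent with normality

    def test_mismatched_subjects_raise(self):
        a = self._result([0.6, 0.7])
        b = rc.EvaluationResult(
            model="b", n_donors=1, subject_ids=["X", "Y"],
            aucs=np.array([[0.6], [0.7]]), seeds=[0], calibration_blocks=1,
        )
        with pytest.raises(ValueError, match="subjects"):
            rc.compare_models(a, b)
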