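"""Early-prediction arm: leakage-free snapshots, forest accuracy, Shapley."""

import numpy as np
import pandas as pd
import pytest

from sofatraj.prediction import (
    build_feature_snapshot,
    evaluate,
    shapley_attribution,
    train_classifier,
)

from ._oracles import exact_shapley


def _labels_balanced(ids, rng):
    return pd.Series(rng.permutation(np.repeat(list("ABCD"), len(ids) // 4 + 1))[: len(ids)],
                     index=ids)


class TestSnapshot:
    def test_six_hour_features_are_window_one_subscores(self, noiseless_cohort):
        _, cohort = noiseless_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        from sofatraj.sofa import ORGANS

        for o, organ in enumerate(ORGANS):
            expected = cohort.truth_subscores[:, o, 0]
            got = snap.X[f"sofa_{organ}_latest"].to_numpy()
            assert np.array_equal(got, expected.astype(float))
            assert np.array_equal(
                snap.X[f"sofa_{organ}_worst"].to_numpy(), expected.astype(float)
            )

    def test_leakage_free(self, default_cohort):
        """Corrupting every measurement at hours >= t never changes the snapshot."""
        _, cohort = default_cohort
        for t in (6, 24, 60):
            snap = build_feature_snapshot(cohort.measurements, cohort.covariates, t)
            corrupted = cohort.measurements.copy()
            late = corrupted["hour"] >= t
            corrupted.loc[late, "value"] = np.where(
                corrupted.loc[late, "variable"] == "gcs", 3.0, 1.0
            )
            snap2 = build_feature_snapshot(corrupted, cohort.covariates, t)
            pd.testing.assert_frame_equal(snap.X, snap2.X)

    def test_measurement_at_exact_cutoff_excluded(self):
        meas = pd.DataFrame(
            {"patient_id": ["p0", "p0"], "hour": [2.0, 6.0],
             "variable": "platelets", "value": [200.0, 10.0]}
        )
        cov = pd.DataFrame(
            {"age": [50.0], "sex": ["male"], "comorbidity_index": [2],
             "ventilated": [False]}, index=pd.Index(["p0"], name="patient_id")
        )
        snap = build_feature_snapshot(meas, cov, 6)
        assert snap.X["platelets_worst"].iloc[0] == 200.0

    def test_worst_so_far_monotone(self, default_cohort):
        _, cohort = default_cohort
        s6 = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        s60 = build_feature_snapshot(cohort.measurements, cohort.covariates, 60)
        for organ in ("respiration", "coagulation", "renal"):
            col = f"sofa_{organ}_worst"
            assert (s60.X[col] >= s6.X[col] - 1e-12).all()

    def test_invalid_cutoff_rejected(self, default_cohort):
        _, cohort = default_cohort
        with pytest.raises(ValueError, match="cutoff"):
            build_feature_snapshot(cohort.measurements, cohort.covariates, 12)


class TestClassifier:
    def test_separable_labels_high_accuracy(self, default_cohort, rng):
        _, cohort = default_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        # labels perfectly determined by two binary features
        labels = pd.Series(
            np.array(["A", "B", "C", "D"])[
                (2 * snap.X["male"] + snap.X["ventilated"]).astype(int)
            ],
            index=snap.X.index,
        )
        trained = train_classifier(snap, labels, seed=0, n_estimators=200)
        report = evaluate(trained, snap, labels, n_boot=200, seed=0)
        assert report.accuracy >= 0.95

    def test_random_balanced_labels_chance_level(self, default_cohort, rng):
        _, cohort = default_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        labels = _labels_balanced(snap.X.index, rng)
        trained = train_classifier(snap, labels, seed=1, n_estimators=200)
        report = evaluate(trained, snap, labels, n_boot=200, seed=1)
        se = np.sqrt(0.25 * 0.75 / report.n_test)
        assert abs(report.accuracy - 0.25) < 3 * se

    def test_seeded_determinism(self, default_cohort):
        _, cohort = default_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 24)
        labels = cohort.truth_labels
        r1 = evaluate(train_classifier(snap, labels, seed=5, n_estimators=100),
                      snap, labels, n_boot=200, seed=5)
        r2 = evaluate(train_classifier(snap, labels, seed=5, n_estimators=100),
                      snap, labels, n_boot=200, seed=5)
        assert r1.accuracy == r2.accuracy
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_report_structure(self, default_cohort):
        _, cohort = default_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        labels = cohort.truth_labels
        trained = train_classifier(snap, labels, seed=2, n_estimators=100)
        report = evaluate(trained, snap, labels, n_boot=200, seed=2)
        assert report.ci_low <= report.accuracy <= report.ci_high
        test_counts = labels.loc[trained.test_ids].value_counts()
        for cls in report.confusion.index:
            assert report.confusion.loc[cls].sum() == test_counts[cls]

    def test_bootstrap_requires_enough_resamples(self, default_cohort):
        _, cohort = default_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        trained = train_classifier(snap, cohort.truth_labels, seed=0, n_estimators=50)
        with pytest.raises(ValueError, match="n_boot"):
            evaluate(trained, snap, cohort.truth_labels, n_boot=10)


class TestShapley:
    def test_additive_model_exact(self):
        f = lambda Z: Z[:, 0] + Z[:, 1]
        rep = shapley_attribution(
            f, np.array([[2.0, 4.0]]), np.zeros((1, 2)), n_permutations=200, seed=0
        )
        assert rep.values[0] == pytest.approx([2.0, 4.0], abs=0.05)
        assert rep.baselines[0] == pytest.approx(0.0)

    def test_duplicated_features_symmetric(self, rng):
        f = lambda Z: Z[:, 0] * Z[:, 1] + 0.5 * Z[:, 2]
        b = rng.normal(0, 1, (40, 1))
        background = np.hstack([b, b, rng.normal(0, 1, (40, 1))])
        rep = shapley_attribution(
            f, np.array([[1.5, 1.5, 2.0]]), background, n_permutations=4000, seed=3
        )
        assert rep.values[0, 0] == pytest.approx(rep.values[0, 1], abs=0.05)

    def test_matches_exhaustive_enumeration(self, rng):
        f = lambda Z: Z[:, 0] * Z[:, 1] + np.sin(Z[:, 2])
        background = rng.normal(0, 1, (30, 3))
        x = np.array([1.2, -0.7, 2.0])
        exact = exact_shapley(f, x, background)
        rep = shapley_attribution(
            f, x[None, :], background, n_permutations=5000, seed=2
        )
        assert rep.values[0] == pytest.approx(exact, abs=0.05)

    def test_local_accuracy(self, rng):
        f = lambda Z: Z[:, 0] ** 2 - Z[:, 1] * Z[:, 2] + Z[:, 3]
        background = rng.normal(0, 1, (25, 4))
        X = rng.normal(0, 1, (3, 4))
        rep = shapley_attribution(f, X, background, n_permutations=300, seed=1)
        for i in range(3):
            assert rep.values[i].sum() == pytest.approx(
                rep.outputs[i] - rep.baselines[i], abs=1e-9
            )

    def test_classifier_interface(self, default_cohort):
        _, cohort = default_cohort
        snap = build_feature_snapshot(cohort.measurements, cohort.covariates, 6)
        trained = train_classifier(snap, cohort.truth_labels, seed=0, n_estimators=50)
        rep = shapley_attribution(
            trained,
            snap.X.loc[trained.test_ids[:3]],
            snap.X.loc[trained.train_ids[:100]],
            n_permutations=50,
            seed=0,
        )
        assert rep.values.shape == (3, snap.X.shape[1])
        assert len(rep.explained_class) == 3
        assert set(rep.explained_class) <= set(trained.classes)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_permutations"):
            shapley_attribution(
                lambda Z: Z[:, 0], np.ones((1, 1)), np.zeros((1, 1)), n_permutations=10
            )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            shapley_attribution(
                lambda Z: Z[:, 0], np.ones((1, 2)), np.zeros((0, 2)), n_permutations=50
            )
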