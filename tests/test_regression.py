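import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from bpfusion.evaluation import compute_errors
from bpfusion.regression import (
    BPRandomForest,
    ModelConfig,
    calibrate,
    load_model,
    predict_records,
    save_model,
    split_calibration,
    train,
)
from bpfusion.synthetic import (
    CohortConfig,
    feature_frame_to_vectors,
    generate_feature_cohort,
)


def cohort_vectors(n_subjects, seed=0, **cfg_kw):
    cfg = replace(CohortConfig(), n_subjects=n_subjects, seed=seed, **cfg_kw)
    table, _ = generate_feature_cohort(cfg)
    return feature_frame_to_vectors(table)


class TestModelConfig:
    def test_printed_defaults(self):
        cfg = ModelConfig()
        assert (cfg.n_trees, cfg.max_depth, cfg.min_samples_split,
                cfg.min_samples_leaf, cfg.bootstrap) == (100, 50, 2, 1, True)

    def test_positive_integers_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(n_trees=0)


class TestTrainPredict:
    def test_held_out_error_near_noise_floor(self):
        """With BP = f(PAT, HR, Age) + eps, held-out MAE <= 1.5 * sigma_eps."""
        cfg = replace(CohortConfig(), subject_offset_sd=0.0, eps_sd=3.0)
        train_vecs = cohort_vectors(50, seed=0, subject_offset_sd=0.0)   # 300 records
        test_vecs = cohort_vectors(17, seed=999, subject_offset_sd=0.0)  # ~100 records
        model = train(train_vecs, "SBP", config=ModelConfig(random_seed=0))
        y = np.array([v.sbp_ref for v in test_vecs])
        mae = compute_errors(y, predict_records(model, test_vecs), "SBP").mae
        assert mae <= 1.5 * cfg.eps_sd

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least"):
            train(cohort_vectors(1), "SBP")

    def test_constant_target_rejected(self):
        vecs = cohort_vectors(5)
        for v in vecs:
            v.sbp_ref = 120.0
        with pytest.raises(ValueError, match="constant target"):
            train(vecs, "SBP")

    def test_determinism_under_seed(self):
        vecs = cohort_vectors(10)
        m1 = train(vecs, "SBP", config=ModelConfig(random_seed=7))
        m2 = train(vecs, "SBP", config=ModelConfig(random_seed=7))
        np.testing.assert_array_equal(predict_records(m1, vecs),
                                      predict_records(m2, vecs))

    def test_train_error_below_held_out(self):
        tr = cohort_vectors(20, seed=1)
        te = cohort_vectors(10, seed=2)
        model = train(tr, "SBP")
        mae_tr = compute_errors([v.sbp_ref for v in tr],
                                predict_records(model, tr), "SBP").mae
        mae_te = compute_errors([v.sbp_ref for v in te],
                                predict_records(model, te), "SBP").mae
        assert mae_tr < mae_te

    def test_predictions_within_training_envelope(self):
        tr = cohort_vectors(20, seed=3)
        te = cohort_vectors(10, seed=4)
        model = train(tr, "SBP")
        y_tr = np.array([v.sbp_ref for v in tr])
        pred = predict_records(model, te)
        assert np.all(pred >= y_tr.min() - 10) and np.all(pred <= y_tr.max() + 10)

    def test_column_order_irrelevant(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() * 2 + rng.normal(0, 0.1, 40)
        model = BPRandomForest(random_state=0).fit(X, y)
        np.testing.assert_array_equal(model.predict(X),
                                      model.predict(X[["c", "a", "b"]]))

    def test_feature_name_mismatch_is_schema_error(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        model = BPRandomForest(random_state=0).fit(X, rng.normal(size=40))
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(X.rename(columns={"b": "z"}))

    def test_degenerate_identical_targets_predict_that_value(self):
        # unit harness bypassing the constant-target guard
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        est = BPRandomForest(random_state=0)
        forest = est._new_forest()
        forest.fit(X, np.full(30, 117.0))
        np.testing.assert_allclose(forest.predict(X), 117.0)


class TestCalibration:
    def test_offset_strategy_shifts_by_mean_residual(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 50)
        model = BPRandomForest(random_state=0, calibration_strategy="offset").fit(X, y)
        base = model.predict(X)
        model.calibrate(X, base + 3.0)  # residuals exactly +3
        np.testing.assert_allclose(model.predict(X), base + 3.0, atol=1e-9)

    def test_empty_calibration_returns_model_unchanged(self, caplog):
        vecs = cohort_vectors(10)
        model = train(vecs, "SBP")
        before = predict_records(model, vecs)
        with caplog.at_level(logging.WARNING, logger="bpfusion.regression"):
            model = calibrate(model, [])
        assert "empty calibration" in caplog.text
        np.testing.assert_array_equal(predict_records(model, vecs), before)

    def test_calibrating_on_training_data_is_benign(self):
        vecs = cohort_vectors(10, seed=5)
        model = train(vecs, "SBP", config=ModelConfig(random_seed=1))
        before = predict_records(model, vecs)
        model = calibrate(model, vecs)
        after = predict_records(model, vecs)
        # same data re-weighted: predictions move only within tree randomness
        assert np.mean(np.abs(after - before)) < 2.0

    def test_strategy_recorded_in_summary(self):
        vecs = cohort_vectors(10, seed=6)
        model = train(vecs, "SBP")
        model = calibrate(model, vecs[:5])
        assert model.training_summary_["calibration"]["strategy"] == "augment"
        assert model.training_summary_["calibration"]["n_calibration"] == 5


class TestSplitCalibration:
    def test_quarter_of_six_is_two_per_subject(self):
        vecs = cohort_vectors(15)  # 15 subjects x 6 records
        cal, ev = split_calibration(vecs, fraction=0.25, seed=0)
        assert len(cal) == 30 and len(ev) == 60  # ceil(0.25*6)=2 per subject
        per_subject = {}
        for v in cal:
            per_subject[v.subject_id] = per_subject.get(v.subject_id, 0) + 1
        assert all(k == 2 for k in per_subject.values())

    def test_disjoint_and_exhaustive(self):
        vecs = cohort_vectors(5, seed=1)
        cal, ev = split_calibration(vecs, seed=3)
        ids = lambda vs: {id(v) for v in vs}
        assert not (ids(cal) & ids(ev))
        assert len(cal) + len(ev) == len(vecs)

    def test_zero_fraction_empty_calibration(self):
        vecs = cohort_vectors(5)
        cal, ev = split_calibration(vecs, fraction=0.0, seed=0)
        assert cal == [] and len(ev) == len(vecs)

    def test_deterministic_under_seed(self):
        vecs = cohort_vectors(5, seed=2)
        a = split_calibration(vecs, seed=11)
        b = split_calibration(vecs, seed=11)
        assert [v.subject_id for v in a[0]] == [v.subject_id for v in b[0]]

    def test_single_record_subject_goes_to_evaluation(self, caplog):
        vecs = cohort_vectors(3, seed=3, records_per_subject=6)
        lone = cohort_vectors(1, seed=4, records_per_subject=1)
        lone[0].subject_id = "LONE"
        with caplog.at_level(logging.WARNING, logger="bpfusion.regression"):
            cal, ev = split_calibration(vecs + lone, seed=0)
        assert "single record" in caplog.text
        assert lone[0] in ev and lone[0] not in cal

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 8"):
            split_calibration(cohort_vectors(1, records_per_subject=4))


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        vecs = cohort_vectors(10, seed=7)
        model = train(vecs, "DBP")
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(predict_records(model, vecs),
                                      predict_records(back, vecs))
        assert back.target_name == "DBP"


class TestMissingPpt:
    def test_ppt_imputed_with_training_mean(self):
        vecs = cohort_vectors(10, seed=8)
        for v in vecs[:3]:
            v.values["PPT"] = math.nan
        model = train(vecs, "SBP", selected=["PATf", "HR", "Age", "PPT"])
        # all records usable despite missing PPT
        assert model.training_summary_["n_records"] == len(vecs)
        pred = predict_records(model, vecs)
        assert np.isfinite(pred).all()
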