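"""SOFA engine: rubric bands, worst-value aggregation, LOCF/NOCB imputation."""

import numpy as np
import pandas as pd
import pytest

from sofatraj.sofa import (
    ORGANS,
    WindowGrid,
    aggregate_windows,
    build_trajectories,
    impute_trajectory,
    score_window,
)

NORMAL = {
    "pao2_fio2_ratio": 450, "platelets": 250, "bilirubin": 0.5, "map": 80,
    "gcs": 15, "creatinine": 0.8, "urine_6h": 400,
}


def _score(overrides, ventilated=False):
    values = dict(NORMAL)
    values.update(overrides)
    return score_window(values, ventilated=ventilated)


# exhaustive band-edge table: (organ, overrides, ventilated, expected subscore)
RUBRIC_EDGES = [
    ("respiration", {"pao2_fio2_ratio": 400}, False, 0),
    ("respiration", {"pao2_fio2_ratio": 399.9}, False, 1),
    ("respiration", {"pao2_fio2_ratio": 300}, False, 1),
    ("respiration", {"pao2_fio2_ratio": 299.9}, False, 2),
    ("respiration", {"pao2_fio2_ratio": 200}, False, 2),
    ("respiration", {"pao2_fio2_ratio": 199.9}, True, 3),
    ("respiration", {"pao2_fio2_ratio": 199.9}, False, 2),  # no support: capped
    ("respiration", {"pao2_fio2_ratio": 100}, True, 3),
    ("respiration", {"pao2_fio2_ratio": 99.9}, True, 4),
    ("respiration", {"pao2_fio2_ratio": 99.9}, False, 2),
    ("coagulation", {"platelets": 150}, False, 0),
    ("coagulation", {"platelets": 149.9}, False, 1),
    ("coagulation", {"platelets": 100}, False, 1),
    ("coagulation", {"platelets": 99.9}, False, 2),
    ("coagulation", {"platelets": 50}, False, 2),
    ("coagulation", {"platelets": 49.9}, False, 3),
    ("coagulation", {"platelets": 20}, False, 3),
    ("coagulation", {"platelets": 19.9}, False, 4),
    ("liver", {"bilirubin": 1.1}, False, 0),
    ("liver", {"bilirubin": 1.2}, False, 1),
    ("liver", {"bilirubin": 1.9}, False, 1),
    ("liver", {"bilirubin": 2.0}, False, 2),
    ("liver", {"bilirubin": 5.9}, False, 2),
    ("liver", {"bilirubin": 6.0}, False, 3),
    ("liver", {"bilirubin": 11.9}, False, 3),
    ("liver", {"bilirubin": 12.0}, False, 4),
    ("cardiovascular", {"map": 70}, False, 0),
    ("cardiovascular", {"map": 69.9}, False, 1),
    ("cardiovascular", {"dobutamine": 2.0}, False, 2),
    ("cardiovascular", {"dopamine": 5.0}, False, 2),
    ("cardiovascular", {"dopamine": 5.1}, False, 3),
    ("cardiovascular", {"epinephrine": 0.1}, False, 3),
    ("cardiovascular", {"norepinephrine": 0.1}, False, 3),
    ("cardiovascular", {"dopamine": 15.1}, False, 4),
    ("cardiovascular", {"epinephrine": 0.11}, False, 4),
    ("cardiovascular", {"norepinephrine": 0.11}, False, 4),
    ("cns", {"gcs": 15}, False, 0),
    ("cns", {"gcs": 14}, False, 1),
    ("cns", {"gcs": 13}, False, 1),
    ("cns", {"gcs": 12}, False, 2),
    ("cns", {"gcs": 10}, False, 2),
    ("cns", {"gcs": 9}, False, 3),
    ("cns", {"gcs": 6}, False, 3),
    ("cns", {"gcs": 5}, False, 4),
    ("cns", {"gcs": 3}, False, 4),
    ("renal", {"creatinine": 1.1}, False, 0),
    ("renal", {"creatinine": 1.2}, False, 1),
    ("renal", {"creatinine": 1.9}, False, 1),
    ("renal", {"creatinine": 2.0}, False, 2),
    ("renal", {"creatinine": 3.4}, False, 2),
    ("renal", {"creatinine": 3.5}, False, 3),
    ("renal", {"creatinine": 4.9}, False, 3),
    ("renal", {"creatinine": 5.0}, False, 4),
    ("renal", {"urine_6h": 125}, False, 0),
    ("renal", {"urine_6h": 124.9}, False, 3),
    ("renal", {"urine_6h": 50}, False, 3),
    ("renal", {"urine_6h": 49.9}, False, 4),
]


@pytest.mark.parametrize("organ,overrides,ventilated,expected", RUBRIC_EDGES)
def test_rubric_band_edges(organ, overrides, ventilated, expected):
    scores, _ = _score(overrides, ventilated=ventilated)
    assert scores[organ] == expected


def test_all_normal_scores_zero():
    scores, total = _score({})
    assert all(scores[o] == 0 for o in ORGANS)
    assert total == 0


def test_worked_moderate_case():
    scores, total = _score(
        {"pao2_fio2_ratio": 250, "platelets": 90, "bilirubin": 0.8, "map": 75,
         "gcs": 15, "creatinine": 1.0}
    )
    assert (scores["respiration"], scores["coagulation"]) == (2, 2)
    assert total == 4


def test_maximal_case_scores_24():
    scores, total = _score(
        {"pao2_fio2_ratio": 80, "platelets": 10, "bilirubin": 15,
         "norepinephrine": 0.3, "gcs": 3, "creatinine": 6.0, "urine_6h": 10},
        ventilated=True,
    )
    assert all(scores[o] == 4 for o in ORGANS)
    assert total == 24


def test_missing_organ_gives_nan_subscore_and_total():
    values = {k: v for k, v in NORMAL.items() if k != "gcs"}
    scores, total = score_window(values)
    assert np.isnan(scores["cns"]) and np.isnan(total)


def test_partial_renal_uses_present_component():
    values = dict(NORMAL)
    del values["urine_6h"]
    values["creatinine"] = 2.5
    scores, _ = score_window(values)
    assert scores["renal"] == 2


def test_negative_platelets_rejected():
    with pytest.raises(ValueError, match="platelets"):
        _score({"platelets": -5})


def _records(rows):
    return pd.DataFrame(rows, columns=["patient_id", "hour", "variable", "value"])


class TestAggregation:
    def test_worst_directions(self):
        rec = _records(
            [("p", 2, "platelets", 120), ("p", 5, "platelets", 90),
             ("p", 1, "gcs", 15), ("p", 4, "gcs", 9),
             ("p", 3, "bilirubin", 0.5), ("p", 4, "bilirubin", 2.2)]
        )
        worst = aggregate_windows(rec).set_index("variable")["value"]
        assert worst["platelets"] == 90  # minimum worsens coagulation
        assert worst["gcs"] == 9  # lowest GCS irrespective of sedation
        assert worst["bilirubin"] == 2.2  # maximum worsens liver

    def test_daily_urine_divided_by_four(self):
        rec = _records([("p", 1, "urine_24h", 400)])
        worst = aggregate_windows(rec)
        assert worst["variable"].tolist() == ["urine_6h"]
        assert worst["value"].tolist() == [100.0]

    def test_windows_half_open(self):
        rec = _records([("p", 6.0, "gcs", 10), ("p", 5.999, "gcs", 12)])
        worst = aggregate_windows(rec).set_index("window")["value"]
        assert worst[1] == 12 and worst[2] == 10

    def test_hours_beyond_horizon_dropped(self):
        rec = _records([("p", 71.9, "gcs", 10), ("p", 72.0, "gcs", 3)])
        worst = aggregate_windows(rec)
        assert worst["value"].tolist() == [10]

    def test_unknown_variable_named_in_error(self):
        rec = _records([("p", 1, "serum_rhubarb", 5)])
        with pytest.raises(ValueError, match="serum_rhubarb"):
            aggregate_windows(rec)

    def test_order_and_duplication_invariance(self):
        rec = _records(
            [("p", h, "platelets", v) for h, v in [(1, 100), (2, 80), (3, 90)]]
        )
        shuffled = rec.sample(frac=1.0, random_state=2)
        duplicated = pd.concat([rec, rec])
        base = aggregate_windows(rec)
        for other in (shuffled, duplicated):
            assert aggregate_windows(other).equals(base)


# constructed missingness patterns: (input row, expected imputed row)
IMPUTE_CASES = [
    ([np.nan, 3, np.nan, np.nan, 2, np.nan], [3, 3, 3, 3, 2, 2]),
    ([1, 2, 3, 4, 3, 2], [1, 2, 3, 4, 3, 2]),  # fully observed: unchanged
    ([np.nan] * 6, [0] * 6),  # never observed: zero fill
    ([2, np.nan, np.nan, np.nan, np.nan, np.nan], [2] * 6),
    ([np.nan, np.nan, np.nan, np.nan, np.nan, 4], [4] * 6),
    ([np.nan, 1, np.nan, 3, np.nan, np.nan], [1, 1, 1, 3, 3, 3]),
    ([0, np.nan, 4, np.nan, 0, np.nan], [0, 0, 4, 4, 0, 0]),
    ([np.nan, np.nan, 2, 2, np.nan, np.nan], [2, 2, 2, 2, 2, 2]),
    ([4, np.nan, np.nan, 1, np.nan, 0], [4, 4, 4, 1, 1, 0]),
    ([np.nan, 0, np.nan, 0, np.nan, 0], [0, 0, 0, 0, 0, 0]),
    ([3, 3, np.nan, np.nan, np.nan, 1], [3, 3, 3, 3, 3, 1]),
    ([np.nan, np.nan, np.nan, 2, 1, np.nan], [2, 2, 2, 2, 1, 1]),
    ([1, np.nan, 1, np.nan, 1, np.nan], [1, 1, 1, 1, 1, 1]),
    ([np.nan, 4, 4, np.nan, np.nan, 4], [4, 4, 4, 4, 4, 4]),
    ([2, 1, np.nan, np.nan, 3, 4], [2, 1, 1, 1, 3, 4]),
    ([np.nan, np.nan, 0, np.nan, 4, np.nan], [0, 0, 0, 0, 4, 4]),
    ([0, np.nan, np.nan, np.nan, np.nan, 2], [0, 0, 0, 0, 0, 2]),
    ([np.nan, 2, 3, 4, np.nan, np.nan], [2, 2, 3, 4, 4, 4]),
    ([4, 0, np.nan, 0, 4, np.nan], [4, 0, 0, 0, 4, 4]),
    ([np.nan, np.nan, np.nan, np.nan, 1, 2], [1, 1, 1, 1, 1, 2]),
]


@pytest.mark.parametrize("row,expected", IMPUTE_CASES)
def test_imputation_patterns(row, expected):
    out = impute_trajectory(np.asarray([row], dtype=float))
    assert out.tolist() == [expected]


def test_imputation_idempotent(rng):
    raw = rng.integers(0, 5, (6, 12)).astype(float)
    raw[rng.random((6, 12)) < 0.4] = np.nan
    once = impute_trajectory(raw)
    assert np.array_equal(impute_trajectory(once.astype(float)), once)


class TestBuildTrajectories:
    def test_single_measurement_locf_and_zero_rows(self):
        rec = _records([("p1", 1.0, "platelets", 90)])
        totals, trajectories = build_trajectories(rec)
        t = trajectories[0]
        assert np.array_equal(t.subscores[1], np.full(12, 2))  # coagulation LOCF
        for organ_row in (0, 2, 3, 4, 5):
            assert np.array_equal(t.subscores[organ_row], np.zeros(12))
        assert totals.iloc[0].tolist() == [2] * 12

    def test_column_sum_identity_and_bounds(self, default_cohort):
        _, cohort = default_cohort
        totals, trajectories = build_trajectories(
            cohort.measurements, cohort.covariates, patient_ids=cohort.patient_ids
        )
        arr = totals.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 24
        for t in trajectories[:20]:
            assert np.array_equal(t.subscores.sum(axis=0), t.totals)

    def test_record_order_invariance(self, noiseless_cohort):
        _, cohort = noiseless_cohort
        shuffled = cohort.measurements.sample(frac=1.0, random_state=0)
        a, _ = build_trajectories(cohort.measurements, cohort.covariates)
        b, _ = build_trajectories(shuffled, cohort.covariates)
        assert a.equals(b)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_trajectories(_records([]), patient_ids=[])

    def test_ventilated_flag_gates_high_respiration(self):
        rec = _records([("p1", 1.0, "pao2_fio2_ratio", 80)])
        cov = pd.DataFrame({"ventilated": [True]}, index=pd.Index(["p1"], name="patient_id"))
        with_vent, _ = build_trajectories(rec, cov)
        without, _ = build_trajectories(rec)
        assert with_vent.iloc[0, 0] == 4 and without.iloc[0, 0] == 2


def test_window_grid_partition():
    grid = WindowGrid()
    hours = np.array([0.0, 5.999, 6.0, 35.9, 66.0, 71.999])
    assert grid.window_of(hours).tolist() == [1, 1, 2, 6, 12, 12]
    assert grid.n_windows == 12
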