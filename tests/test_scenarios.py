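"""Factorial grid reproduction, serialization round-trips, power curves."""

import numpy as np
import pandas as pd
import pytest

from rocpower import DesignSpec, ScenarioGrid, ScenarioResult, power_curve, run_grid


@pytest.fixture(scope="module")
def study_grid_result():
    return run_grid(ScenarioGrid(powers=(0.80,)))


class TestRunGrid:
    def test_extreme_cells_and_fold_ratio(self, study_grid_result):
        s = study_grid_result.summary()[0.80]
        assert s["n_pos_max"] == 3709  # discrete, delta 0.02, rho 0.3
        assert s["n_pos_min"] == 36  # continuous, delta 0.10, rho 0.8
        assert s["fold_ratio"] == 103

    def test_row_count_is_cells_times_powers(self):
        grid = ScenarioGrid(powers=(0.80, 0.90))
        table = run_grid(grid).table
        assert len(table) == 5 * 3 * 2 * 2

    def test_single_cell_grid(self):
        grid = ScenarioGrid(
            deltas=(0.04,), rhos=(0.5,), data_types=("discrete",), powers=(0.80, 0.95)
        )
        table = run_grid(grid).table
        assert len(table) == 2
        assert table["error"].isna().all()

    def test_every_published_column_present(self, study_grid_result):
        needed = {
            "n_pos", "n_neg", "n_total",
            "ed_pos", "ed_neg", "ed_total",
            "diss_pos", "diss_neg", "diss_total",
            "target_power", "achieved_power",
        }
        assert needed <= set(study_grid_result.table.columns)

    def test_continuous_never_needs_more_than_discrete(self, study_grid_result):
        t = study_grid_result.table
        wide = t.pivot_table(
            index=["delta_auc", "rho"], columns="data_type", values="n_pos"
        )
        assert (wide["continuous"] <= wide["discrete"]).all()

    def test_n_nonincreasing_in_delta_and_rho(self, study_grid_result):
        t = study_grid_result.table
        for (dtype, rho), sub in t.groupby(["data_type", "rho"]):
            n = sub.sort_values("delta_auc")["n_pos"].to_numpy()
            assert (np.diff(n) < 0).all()
        for (dtype, delta), sub in t.groupby(["data_type", "delta_auc"]):
            n = sub.sort_values("rho")["n_pos"].to_numpy()
            assert (np.diff(n) < 0).all()

    def test_infeasible_cell_becomes_error_row(self):
        grid = ScenarioGrid(deltas=(0.0, 0.04), rhos=(0.3,), powers=(0.80,))
        table = run_grid(grid).table
        errs = table[table["error"].notna()]
        assert len(errs) == 2  # one per data type
        assert table["n_pos"].notna().sum() == 2

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ScenarioGrid(deltas=())


class TestSerialization:
    def test_csv_round_trip_lossless(self, study_grid_result, tmp_path):
        path = tmp_path / "grid.csv"
        study_grid_result.to_csv(path)
        back = ScenarioResult.read_csv(path)
        pd.testing.assert_frame_equal(
            back.table, study_grid_result.table, check_dtype=False
        )

    def test_json_nested_by_scenario(self, study_grid_result, tmp_path):
        import json

        path = tmp_path / "grid.json"
        study_grid_result.to_json(path)
        data = json.loads(path.read_text())
        assert len(data["scenarios"]) == 30
        assert data["metadata"]["conventions"]["null_variance_anchor"] == "auc1"


class TestPowerCurve:
    def test_monotone_nondecreasing(self):
        spec = DesignSpec(data_type="discrete", auc1=0.80, auc2=0.84, rho_pos=0.5)
        curve = power_curve(spec, range(50, 2000, 50))
        assert (np.diff(curve["power"]) >= 0).all()

    def test_published_enrollment_at_target_power(self):
        # weakest discrete scenario: total enrollment 9274 at the 0.80-power n
        spec = DesignSpec(
            data_type="discrete", auc1=0.80, auc2=0.82, rho_pos=0.3, dropout_rate=0.2
        )
        curve = power_curve(spec, [3708, 3709])
        at_n = curve[curve["n_pos"] == 3709].iloc[0]
        assert at_n["diss_total"] == 9274
        assert at_n["power"] >= 0.80
        assert curve[curve["n_pos"] == 3708].iloc[0]["power"] < 0.80

    def test_published_continuous_enrollment(self):
        # continuous delta 0.02, rho 0.3: per-group enrollment 3509 at n = 2807
        spec = DesignSpec(
            data_type="continuous", auc1=0.80, auc2=0.82, rho_pos=0.3, dropout_rate=0.2
        )
        curve = power_curve(spec, [2807])
        assert curve.iloc[0]["diss_total"] == 2 * 3509

    def test_small_n_power_bounded(self):
        spec = DesignSpec(data_type="discrete", auc1=0.80, auc2=0.82, rho_pos=0.3)
        for n in (2, 3, 4):
            p = power_curve(spec, [n])["power"].iloc[0]
            assert 0.0 < p < 1.0

    def test_empty_range_rejected(self):
        spec = DesignSpec(data_type="discrete", auc1=0.80, auc2=0.82, rho_pos=0.3)
        with pytest.raises(ValueError):
            power_curve(spec, [])
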