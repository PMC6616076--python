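"""AME objective and genetic-algorithm fitting machinery."""

import numpy as np
import pandas as pd
import pytest

from streamseg.fitting import BehavioralTable, FitConfig, FitResult, _round_sig, ame, fit
from streamseg.ideal_observer import DprimePrediction


def table_from_rows(rows):
    return BehavioralTable(
        frame=pd.DataFrame(rows, columns=["delta_pitch", "duration_s", "dprime_mean"])
    )


def pred(dp, dur, d):
    return DprimePrediction(
        delta_pitch=dp, duration=dur, delta_t=0.0485, p_segregated=0.5, dprime=d, n_trials=10
    )


class TestAme:
    def test_exact_match_is_zero(self):
        data = table_from_rows([(25, 1.24, 0.8), (50, 3.96, 1.6)])
        preds = [pred(25, 1.24, 0.8), pred(50, 3.96, 1.6)]
        assert ame(preds, data) == 0.0

    def test_hand_computed_mean_absolute_error(self):
        # |0.9-0.7| = 0.2 and |1.0-1.4| = 0.4 average to 0.3
        data = table_from_rows([(25, 1.24, 0.7), (50, 3.96, 1.4)])
        preds = [pred(25, 1.24, 0.9), pred(50, 3.96, 1.0)]
        assert ame(preds, data) == pytest.approx(0.3)

    def test_row_order_invariance(self):
        rows = [(0, 1.24, 0.1), (25, 1.24, 0.5), (50, 3.96, 1.2)]
        preds = [pred(0, 1.24, 0.2), pred(25, 1.24, 0.9), pred(50, 3.96, 1.0)]
        assert ame(preds, table_from_rows(rows)) == pytest.approx(
            ame(preds, table_from_rows(rows[::-1]))
        )

    def test_missing_condition_rejected(self):
        data = table_from_rows([(25, 1.24, 0.8), (50, 3.96, 1.6)])
        with pytest.raises(ValueError, match="no prediction"):
            ame([pred(25, 1.24, 0.8)], data)

    def test_rmse_alternative(self):
        data = table_from_rows([(25, 1.24, 0.0), (50, 3.96, 0.0)])
        preds = [pred(25, 1.24, 0.3), pred(50, 3.96, 0.4)]
        assert ame(preds, data, objective="rmse") == pytest.approx(np.sqrt(0.125))


class TestBehavioralTable:
    def test_duplicate_conditions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            table_from_rows([(25, 1.24, 0.8), (25, 1.24, 0.9)])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            BehavioralTable(frame=pd.DataFrame({"delta_pitch": [1.0]}))

    def test_csv_round_trip_with_column_map(self, tmp_path):
        path = tmp_path / "ext.csv"
        pd.DataFrame(
            {"dPitch": [25.0], "dur": [1.24], "dprime": [0.9]}
        ).to_csv(path, index=False)
        table = BehavioralTable.from_csv(
            path, column_map={"dPitch": "delta_pitch", "dur": "duration_s", "dprime": "dprime_mean"}
        )
        assert table.conditions() == [(25.0, 1.24)]

    def test_missing_file_named_in_error(self):
        with pytest.raises(FileNotFoundError, match="nowhere.csv"):
            BehavioralTable.from_csv("nowhere.csv")


def tiny_fit_config(**kwargs):
    defaults = dict(
        free_parameters=("sigma",),
        ga_population=4,
        ga_generations=2,
        ga_seed=0,
        n_trials_per_eval=8,
        final_n_trials=8,
    )
    defaults.update(kwargs)
    return FitConfig(**defaults)


@pytest.fixture(scope="module")
def small_data(fast_model):
    """A two-condition behavioral table in the model's own d' range."""
    return table_from_rows([(25.0, 1.24, 0.3), (100.0, 1.24, 1.2)])


class TestFit:
    def test_reproducible_with_fixed_seed(self, small_data, fast_model):
        r1 = fit(small_data, tiny_fit_config(), fast_model)
        r2 = fit(small_data, tiny_fit_config(), fast_model)
        assert r1.sigma_hat == r2.sigma_hat
        assert r1.generations_log == r2.generations_log

    def test_best_log_non_increasing(self, small_data, fast_model):
        res = fit(small_data, tiny_fit_config(ga_generations=4), fast_model)
        log = np.array(res.generations_log)
        assert np.all(np.diff(log) <= 1e-12)

    def test_point_bounds_return_that_point(self, small_data, fast_model):
        cfg = tiny_fit_config(bounds={"sigma": (40.0, 40.0), "L": (0.05, 1.2)})
        res = fit(small_data, cfg, fast_model)
        assert res.sigma_hat == 40.0
        assert res.ame >= 0.0

    def test_sigma_only_protocol_keeps_L_fixed(self, small_data, fast_model):
        # mirror of the first fit protocol: L frozen at the model default 0.6
        res = fit(small_data, tiny_fit_config(), fast_model)
        assert res.L_hat is None
        assert fast_model.input_stage.L == 0.6

    def test_result_json_export(self, small_data, fast_model, tmp_path):
        res = fit(small_data, tiny_fit_config(), fast_model)
        path = tmp_path / "fit.json"
        res.to_json(path)
        assert '"sigma_hat"' in path.read_text()


class TestRounding:
    def test_study_reporting_convention(self):
        # sigma and AME to the first significant figure, L to the second
        res = FitResult(
            sigma_hat=41.3,
            L_hat=0.347,
            ame=0.52,
            ame_final=0.5,
            generations_log=(1.0,),
            seed=0,
            config=FitConfig(),
        )
        rounded = res.rounded()
        assert rounded["sigma"] == 40.0
        assert rounded["L"] == 0.35
        assert rounded["ame"] == 0.5

    def test_round_sig_basics(self):
        assert _round_sig(0.0, 1) == 0.0
        assert _round_sig(31.0, 1) == 30.0
        assert _round_sig(0.347, 2) == 0.35


def test_fit_config_validation():
    with pytest.raises(ValueError):
        FitConfig(free_parameters=("tau_a",))  # competition params are not searchable
    with pytest.raises(ValueError):
        FitConfig(ga_population=2)
    with pytest.raises(ValueError):
        FitConfig(bounds={"sigma": (10.0, 5.0), "L": (0.05, 1.2)})
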