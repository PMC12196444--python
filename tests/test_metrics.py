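"""NUE indicators, model-fit statistics, synthetic observations, and
hydrolysis-coefficient calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paddynsim as ps
from paddynsim.metrics import (EvaluationReport, NUEInputs,
                               classify_performance, evaluation_metrics,
                               nue_indicators, straw_n_rate,
                               synthetic_observations)


def _brute_metrics(s, o):
    """Element-by-element reference implementation of the fit statistics."""
    n = len(o)
    obar = sum(o) / n
    sse = sum((si - oi) ** 2 for si, oi in zip(s, o))
    nrmse = math.sqrt(sse / n) / obar * 100
    ia = 1 - sse / sum((abs(si - obar) + abs(oi - obar)) ** 2
                       for si, oi in zip(s, o))
    nse = 1 - sse / sum((oi - obar) ** 2 for oi in o)
    return nrmse, ia, nse


class TestNUE:
    def test_equal_yields_zero_ae(self):
        res = nue_indicators(NUEInputs(3.5, 3.5, 120.0, 60.0, 150.0, 40.0))
        assert res.ae == 0.0

    def test_hand_arithmetic_example(self, params):
        """150 kg urea N + 3 t straw (0.42% N) -> rate 162.6; AE ~18.45."""
        rate = 150.0 + straw_n_rate(3.0, params)
        assert rate == pytest.approx(162.6)
        res = nue_indicators(NUEInputs(6.5, 3.5, 150.0, 60.0, rate, 45.0))
        assert res.ae == pytest.approx(3000.0 / 162.6, rel=1e-12)
        assert res.pfp == pytest.approx(6500.0 / 162.6, rel=1e-12)
        assert res.pe == pytest.approx(3000.0 / 90.0, rel=1e-12)

    def test_yield_scaled_nh3_reporting_scale(self):
        res = nue_indicators(NUEInputs(6.5, 3.5, 150.0, 60.0, 162.6, 45.0))
        # 45 kg NH3-N over 6.5 t grain = 6.92 in 1e-3 kg/kg
        assert res.yield_scaled_nh3 == pytest.approx(45e3 / 6500.0, rel=1e-12)
        assert 6.8 < res.yield_scaled_nh3 < 7.0

    def test_pe_undefined_for_equal_uptake(self):
        with pytest.raises(ZeroDivisionError):
            nue_indicators(NUEInputs(6.5, 3.5, 90.0, 90.0, 150.0, 40.0))

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            nue_indicators(NUEInputs(6.5, 3.5, 150.0, 60.0, 0.0, 40.0))

    @settings(max_examples=50, deadline=None)
    @given(yn=st.floats(0.1, 12), yck=st.floats(0.1, 12),
           rate=st.floats(10, 400))
    def test_pfp_minus_ae_identity(self, yn, yck, rate):
        """PFP - AE = Yield_CK / N rate, algebraically."""
        res = nue_indicators(NUEInputs(yn, yck, 120.0, 50.0, rate, 10.0))
        assert res.pfp - res.ae == pytest.approx(yck * 1000.0 / rate,
                                                 rel=1e-9, abs=1e-9)


class TestEvaluationMetrics:
    def test_perfect_fit(self):
        r = evaluation_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.nrmse, r.ia, r.nse) == (0.0, 1.0, 1.0)

    def test_constant_predictor_has_zero_nse(self):
        o = [1.0, 2.0, 3.0, 4.0]
        s = [2.5] * 4
        assert evaluation_metrics(s, o).nse == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_matches_brute_force(self):
        o = [1.0, 2.0, 3.0, 4.0]
        s = [1.2, 1.9, 3.3, 3.8]
        r = evaluation_metrics(s, o)
        nrmse, ia, nse = _brute_metrics(s, o)
        assert r.nrmse == pytest.approx(nrmse, abs=1e-12)
        assert r.ia == pytest.approx(ia, abs=1e-12)
        assert r.nse == pytest.approx(nse, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        o = rng.uniform(1.0, 10.0, size=rng.integers(2, 40))
        s = o + rng.normal(0, 1.0, size=o.size)
        r = evaluation_metrics(s, o)
        nrmse, ia, nse = _brute_metrics(list(s), list(o))
        assert r.nrmse == pytest.approx(nrmse, abs=1e-10)
        assert r.ia == pytest.approx(ia, abs=1e-12)
        assert r.nse == pytest.approx(nse, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluation_metrics([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            evaluation_metrics([1.0], [1.0])
        with pytest.raises(ValueError):
            evaluation_metrics([1.0, 2.0], [3.0, 3.0])


class TestClassification:
    @pytest.mark.parametrize("nrmse,rating", [
        (7.2, "good"), (14.99, "good"), (15.0, "moderate"),
        (30.0, "moderate"), (30.01, "poor"),
    ])
    def test_nrmse_bands(self, nrmse, rating):
        report = EvaluationReport(nrmse=nrmse, ia=0.95, nse=0.8, n=10)
        assert classify_performance(report, "n_output")["rating"] == rating

    def test_published_quality_fit_passes_n_output(self):
        report = EvaluationReport(nrmse=7.2, ia=0.99, nse=0.94, n=16)
        flags = classify_performance(report, "n_output")
        assert flags == {"rating": "good", "ia_pass": True, "nse_pass": True}

    def test_crop_class_thresholds_stricter(self):
        report = EvaluationReport(nrmse=10.0, ia=0.74, nse=-0.5, n=8)
        crop = classify_performance(report, "crop_growth")
        n_out = classify_performance(report, "n_output")
        assert not crop["ia_pass"] and n_out["ia_pass"]
        assert not crop["nse_pass"] and n_out["nse_pass"]

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            classify_performance(
                EvaluationReport(5.0, 0.9, 0.9, 4), "weather")


class TestSyntheticObservations:
    def test_cv_zero_is_identity(self):
        truth = np.array([1.0, 5.0, 0.0, 2.5])
        out = synthetic_observations(truth, 0.0, seed=1)
        assert np.array_equal(out, truth)

    def test_deterministic_per_seed(self):
        truth = np.linspace(1, 10, 20)
        a = synthetic_observations(truth, 0.1, seed=5)
        b = synthetic_observations(truth, 0.1, seed=5)
        c = synthetic_observations(truth, 0.1, seed=6)
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_sample_cv_matches_target(self):
        truth = np.full(1, 10.0)
        draws = np.array([synthetic_observations(truth, 0.1, seed=s)[0]
                          for s in range(4000)])
        cv = draws.std() / draws.mean()
        assert abs(cv - 0.1) < 0.02

    def test_composition_with_metrics_is_perfect_fit(self, season_nsr0):
        truth = season_nsr0.daily["nh3_kgha"].to_numpy()
        obs = synthetic_observations(truth, 0.0, seed=0)
        r = evaluation_metrics(truth, obs)
        assert (r.nrmse, r.ia, r.nse) == (0.0, 1.0, 1.0)


class TestCalibration:
    def test_self_consistency_recovers_ui_kh(self, season_nsr0_ui):
        """Noiseless series generated at Kh_UI = 0.007 is recovered exactly
        when 0.007 is in the grid."""
        truth = season_nsr0_ui.daily["nh3_kgha"].to_numpy()
        grid = [0.003, 0.007, 0.02, 0.05]
        best, profile = ps.calibrate_kh(truth, season_nsr0_ui.spec, grid=grid)
        assert best == 0.007
        assert len(profile) == len(grid)
        assert min(obj for _, obj in profile) == pytest.approx(0.0, abs=1e-9)

    def test_empty_grid_rejected(self, season_nsr0):
        with pytest.raises(ValueError):
            ps.calibrate_kh(season_nsr0.daily["nh3_kgha"].to_numpy(),
                            season_nsr0.spec, grid=[])

    def test_misaligned_series_rejected(self, season_nsr0):
        with pytest.raises(ValueError, match="length"):
            ps.calibrate_kh(np.ones(10), season_nsr0.spec, grid=[0.05])
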