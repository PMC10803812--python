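"""ISS/NSS number balances: worked examples, conservation, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquage import (
    BiofilmSample,
    InsufficientDataError,
    OutOfRangeError,
    ReactorConfig,
    WaterSample,
    balance_series,
    interval_average,
    ngtr_instantaneous,
    ngtr_nonsteady,
    tap_to_ngtr_ratio,
)
from aquage.synthetic import SeriesScenario, simulate_reactor_series

conc = st.floats(min_value=0.0, max_value=1e7, allow_nan=False)


class TestInstantaneous:
    @pytest.mark.parametrize(
        "c_tap,c_ar,expected",
        [
            (990.0, 2.2e4, 6.35e7),   # phase-average tap vs bulk ICC
            (1.3e5, 1.3e5, 0.0),
            (2.5e3, 1.3e5, 3.86e8),
        ],
    )
    def test_examples(self, c_tap, c_ar, expected, config):
        est = ngtr_instantaneous(c_tap, c_ar, config)
        assert est.ngtr == pytest.approx(expected, rel=2e-3)

    def test_negative_concentration_rejected(self, config):
        with pytest.raises(OutOfRangeError):
            ngtr_instantaneous(-1.0, 10.0, config)

    def test_negative_ngtr_reported_not_clamped(self, config):
        est = ngtr_instantaneous(1e4, 1e3, config)
        assert est.ngtr < 0
        assert est.ratio_tap_to_ngtr is None

    @given(c_tap=conc, c_ar=conc, k=st.floats(min_value=1e-3, max_value=1e3))
    def test_homogeneity_in_concentration(self, c_tap, c_ar, k):
        cfg = ReactorConfig()
        base = ngtr_instantaneous(c_tap, c_ar, cfg).ngtr
        scaled = ngtr_instantaneous(k * c_tap, k * c_ar, cfg).ngtr
        assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-6)

    @given(c_tap=conc, c_ar=conc)
    def test_balance_identity(self, c_tap, c_ar):
        est = ngtr_instantaneous(c_tap, c_ar, ReactorConfig())
        scale = max(abs(est.tap_input), abs(est.effluent_output), 1.0)
        assert abs(est.residual()) <= 1e-9 * scale


def _sample(day, icc, source="AR1"):
    return WaterSample(day=day, source=source, icc=icc)


class TestIntervalAverage:
    def test_mean_of_two(self):
        series = [_sample(1, 10), _sample(2, 20)]
        assert interval_average(series, 0, 2) == 15

    def test_single_event_identity(self):
        assert interval_average([_sample(1.5, 42)], 0, 2) == 42

    def test_half_open_window_excludes_t1_includes_t2(self):
        series = [_sample(0.5, 8), _sample(1.5, 12), _sample(2.5, 100)]
        assert interval_average(series, 0, 2) == 10
        # event exactly at t1 is excluded, at t2 included
        series2 = [_sample(0.0, 99), _sample(2.0, 7)]
        assert interval_average(series2, 0, 2) == 7

    def test_empty_window_raises(self):
        with pytest.raises(InsufficientDataError):
            interval_average([_sample(5, 1)], 0, 2)


class TestNonSteady:
    def _hand_example(self, config):
        bulk = [
            _sample(5.0, 1e3, source="tapres"),
            _sample(2.0, 1e4),
            _sample(10.0, 2e4),
        ]
        bf1 = BiofilmSample(day=0.0, reactor="AR1", icc_area=1e5)
        bf2 = BiofilmSample(day=10.0, reactor="AR1", icc_area=2e5)
        return ngtr_nonsteady(bulk, bf1, bf2, config)

    def test_hand_arithmetic(self, config):
        est = self._hand_example(config)
        assert est.accumulation == pytest.approx(2.908e6, rel=1e-3)
        assert est.ngtr == pytest.approx(4.524e7, rel=1e-3)
        assert tap_to_ngtr_ratio(est) == pytest.approx(0.0668, rel=2e-3)

    def test_balance_identity_holds(self, config):
        est = self._hand_example(config)
        assert abs(est.residual()) <= 1e-9 * abs(est.ngtr)

    def test_no_change_and_matched_concentrations_give_zero(self, config):
        bulk = [
            _sample(5.0, 1e4, source="tapres"),
            _sample(0.0, 1e4),
            _sample(5.0, 1e4),
            _sample(10.0, 1e4),
        ]
        bf1 = BiofilmSample(day=0.0, reactor="AR1", icc_area=5e4)
        bf2 = BiofilmSample(day=10.0, reactor="AR1", icc_area=5e4)
        est = ngtr_nonsteady(bulk, bf1, bf2, config)
        assert est.ngtr == pytest.approx(0.0, abs=1e-6)

    def test_missing_bulk_near_biofilm_day_raises(self, config):
        bulk = [_sample(5.0, 1e3, source="tapres"), _sample(5.0, 1e4)]
        bf1 = BiofilmSample(day=0.0, reactor="AR1", icc_area=1e5)
        bf2 = BiofilmSample(day=10.0, reactor="AR1", icc_area=2e5)
        with pytest.raises(InsufficientDataError):
            ngtr_nonsteady(bulk, bf1, bf2, config)

    def test_mismatched_reactors_rejected(self, config):
        bf1 = BiofilmSample(day=0.0, reactor="AR1", icc_area=1e5)
        bf2 = BiofilmSample(day=10.0, reactor="AR2", icc_area=2e5)
        with pytest.raises(OutOfRangeError):
            ngtr_nonsteady([], bf1, bf2, config)


class TestBalanceSeries:
    def _series(self, n_bulk=5, n_bf=3):
        bulk = []
        for d in range(n_bulk):
            bulk.append(_sample(float(d), 1e3, source="tapres"))
            bulk.append(_sample(float(d), 2e4))
        biofilm = [
            BiofilmSample(day=float(2 * i), reactor="AR1", icc_area=1e5 * (i + 1))
            for i in range(n_bf)
        ]
        return bulk, biofilm

    def test_counts(self, config):
        bulk, biofilm = self._series()
        estimates = balance_series(bulk, biofilm, config)
        methods = [e.method for e in estimates]
        assert methods.count("ISS") == 5
        assert methods.count("NSS") == 2

    def test_iss_only_without_biofilm(self, config):
        bulk, _ = self._series()
        estimates = balance_series(bulk, [], config)
        assert all(e.method == "ISS" for e in estimates)

    def test_unpaired_reactor_days_skipped(self, config):
        bulk = [
            _sample(0.0, 1e3, source="tapres"),
            _sample(0.0, 2e4),
            _sample(30.0, 2e4),  # no tap event nearby
        ]
        estimates = balance_series(bulk, [], config)
        assert len(estimates) == 1 and estimates[0].t2 == 0.0


class TestEstimatorsOnSyntheticTruth:
    def test_iss_and_nss_agree_at_true_steady_state(self, config):
        scn = SeriesScenario(
            duration_days=10, sample_interval_days=0.25,
            ngtr_profile=5e7, biofilm_accum_profile=0.0,
            noise_gcv=0.0, seed=1,
        )
        sim = simulate_reactor_series(scn)
        nss = ngtr_nonsteady(sim.bulk, sim.biofilm[0], sim.biofilm[-1],
                             scn.config)
        tap = [s for s in sim.bulk if s.source == "tapres"][-1]
        ar = [s for s in sim.bulk if s.source == "AR1"][-1]
        iss = ngtr_instantaneous(tap.icc, ar.icc, scn.config)
        assert nss.accumulation == pytest.approx(0.0, abs=1e-3 * abs(nss.ngtr))
        assert nss.ngtr == pytest.approx(5e7, rel=1e-6)
        assert iss.ngtr == pytest.approx(5e7, rel=1e-6)

    def test_step_change_visible_in_iss_series(self, config):
        scn = SeriesScenario(
            duration_days=10, sample_interval_days=0.1,
            ngtr_profile=lambda d: 5e7 if d < 5 else 5e8,
            biofilm_accum_profile=0.0, noise_gcv=0.0, seed=1,
        )
        sim = simulate_reactor_series(scn)
        estimates = balance_series(sim.bulk, [], scn.config,
                                   iss_pair_tolerance_days=0.01)
        iss = {e.t2: e.ngtr for e in estimates if e.method == "ISS"}
        # fully relaxed at the end of each segment (HRT = 1/3 day)
        assert iss[5.0] == pytest.approx(5e7, rel=1e-2)
        assert iss[10.0] == pytest.approx(5e8, rel=1e-2)

    def test_recovery_error_shrinks_with_sampling_density(self, config):
        errors = {}
        for dt in (0.2, 0.02):
            scn = SeriesScenario(
                duration_days=10, sample_interval_days=dt,
                ngtr_profile=lambda d: 5e7 if d < 5 else 5e8,
                biofilm_accum_profile=0.0, noise_gcv=0.0, seed=1,
            )
            sim = simulate_reactor_series(scn)
            bf = {b.day: b for b in sim.biofilm}
            est = ngtr_nonsteady(sim.bulk, bf[5.0], bf[10.0], scn.config)
            truth = sim.truth.mean_ngtr(5.0, 10.0)
            errors[dt] = abs(est.ngtr - truth) / truth
        assert errors[0.02] < errors[0.2]
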