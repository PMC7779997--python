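"""End-tidal CO2 / Doppler processing, calibration and screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcsmc.physio import (PhysioTrace, envelope, group_average_trimmed,
                          lag_calibration, process_petco2, process_tcd,
                          relative_change, screen_measurement, synthesize_etcd)
from dcsmc.synth import generate_physio


def sine_trace(a=1.0, c=0.0, f=0.25, fs=100.0, t_end=60.0):
    t = np.arange(0.0, t_end, 1.0 / fs)
    return PhysioTrace(t, c + a * np.sin(2 * np.pi * f * t), fs, "test")


class TestEnvelope:
    def test_upper_envelope_of_sinusoid(self):
        tr = sine_trace(a=2.0, c=5.0)
        env = envelope(tr, "upper", min_cycle_s=2.0)
        mid = env.values[(tr.time > 5) & (tr.time < 55)]
        np.testing.assert_allclose(mid, 7.0, rtol=0.02)

    def test_lower_envelope_of_sinusoid(self):
        env = envelope(sine_trace(a=2.0, c=5.0), "lower", min_cycle_s=2.0)
        mid = env.values[(env.time > 5) & (env.time < 55)]
        np.testing.assert_allclose(mid, 3.0, rtol=0.05)

    def test_constant_trace_unchanged(self):
        t = np.arange(0.0, 30.0, 0.01)
        tr = PhysioTrace(t, np.full_like(t, 4.2), 100.0, "const")
        env = envelope(tr, "upper")
        np.testing.assert_array_equal(env.values, tr.values)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            envelope(sine_trace(t_end=3.0), "upper", min_cycle_s=2.0)


class TestPetco2:
    def test_step_plateau_recovered(self):
        petco2, _, _, truth = generate_physio(seed=3)
        dpet = process_petco2(petco2)
        plateau = dpet.values[(dpet.time > 130) & (dpet.time < 175)]
        assert np.mean(plateau) == pytest.approx(truth.co2_step_mmhg, abs=0.5)
        # protocol target band: +10 +/- 2 mmHg
        assert 8.0 <= np.mean(plateau) <= 12.0

    def test_baseline_only_trace_is_near_zero(self):
        t = np.arange(0.0, 120.0, 1e-3)
        vals = 3.0 + 33.0 / (1.0 + np.exp(-8 * np.sin(2 * np.pi * 0.25 * t)))
        dpet = process_petco2(PhysioTrace(t, vals, 1000.0, "PETCO2"))
        assert abs(dpet.values[(dpet.time > 60)].mean()) < 0.5


class TestTcd:
    def test_plateau_recovered_through_ripple(self):
        _, lmca, rmca, truth = generate_physio(seed=5)
        out = process_tcd(lmca, rmca)
        plateau = out.values[(out.time > 140) & (out.time < 175)]
        want = truth.slope * truth.co2_step_mmhg + truth.intercept
        assert np.mean(plateau) == pytest.approx(want, abs=2.0)

    def test_scale_invariance(self):
        _, lmca, rmca, _ = generate_physio(seed=5)
        out1 = process_tcd(lmca, None)
        scaled = PhysioTrace(lmca.time, 3.7 * lmca.values,
                             lmca.sampling_rate_hz, "LMCA")
        out2 = process_tcd(scaled, None)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-8)

    def test_one_sided_equals_that_side(self):
        _, lmca, rmca, _ = generate_physio(seed=6)
        both = process_tcd(lmca, None)
        again = process_tcd(lmca, None)
        np.testing.assert_array_equal(both.values, again.values)
        with pytest.raises(ValueError):
            process_tcd(None, None)


class TestLagCalibration:
    def test_recovers_constructed_affine_relation(self):
        # constructed directly in the processed domain: tcd is an advanced,
        # scaled copy of the end-tidal change
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 300.0, 0.01)
        dpet = np.interp(t, [0, 60, 100, 180, 220, 300], [0, 0, 11, 11, 0, 0])
        tcd_vals = 3.2 * np.interp(t + 5.0, t, dpet) - 0.4 \
            + rng.normal(0, 0.05, t.size)
        calib = lag_calibration(PhysioTrace(t, tcd_vals, 100.0, "tcd"),
                                PhysioTrace(t, dpet, 100.0, "dpet"),
                                match_filter_hz=None)
        assert calib.lag_s == 5.0
        assert calib.slope == pytest.approx(3.2, rel=0.01)
        assert calib.intercept == pytest.approx(-0.4, abs=0.05)
        assert calib.r2 > 0.99

    def test_zero_lag_construction_picks_boundary_lag(self):
        t = np.arange(0.0, 300.0, 0.01)
        dpet = np.interp(t, [0, 60, 100, 180, 220, 300], [0, 0, 11, 11, 0, 0])
        tcd = PhysioTrace(t, 3.2 * dpet - 0.4, 100.0, "tcd")
        calib = lag_calibration(tcd, PhysioTrace(t, dpet, 100.0, "dpet"),
                                match_filter_hz=None)
        # the searched grid starts at 1 s; boundary choice is documented
        assert calib.lag_s == 1.0

    def test_exact_linear_relation_gives_r2_one(self):
        t = np.arange(0.0, 300.0, 0.01)
        dpet = np.interp(t, [0, 60, 100, 180, 220, 300], [0, 0, 11, 11, 0, 0])
        tcd_vals = 2.0 * np.interp(t + 3.0, t, dpet) + 1.0
        calib = lag_calibration(PhysioTrace(t, tcd_vals, 100.0, "tcd"),
                                PhysioTrace(t, dpet, 100.0, "dpet"),
                                lags_s=[3], match_filter_hz=None)
        assert calib.r2 == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_constant_regressor_skipped(self):
        t = np.arange(0.0, 300.0, 0.01)
        with pytest.raises(ValueError):
            lag_calibration(PhysioTrace(t, np.sin(t / 40), 100.0, "tcd"),
                            PhysioTrace(t, np.zeros_like(t), 100.0, "dpet"))


class TestEtcd:
    @pytest.mark.parametrize("x,want", [(0.0, -0.4), (10.0, 31.6), (11.5, 36.4)])
    def test_pointwise_values(self, x, want):
        assert synthesize_etcd(np.array([x]))[0] == pytest.approx(want)

    @settings(derandomize=True, max_examples=60)
    @given(a=st.floats(-20, 20), b=st.floats(-20, 20))
    def test_exactly_affine(self, a, b):
        ea, eb = synthesize_etcd(np.array([a]))[0], synthesize_etcd(np.array([b]))[0]
        assert ea - eb == pytest.approx(3.2 * (a - b), rel=1e-9, abs=1e-9)


class TestRelativeChange:
    def test_examples(self):
        x = np.full(5, 2.0)
        np.testing.assert_allclose(relative_change(x, x > 0), 0.0)
        x = np.array([1e-6, 1e-6, 1.2e-6])
        base = np.array([True, True, False])
        assert relative_change(x, base)[2] == pytest.approx(20.0)
        assert relative_change(2 * x, base)[2] == pytest.approx(20.0)

    def test_round_trip_through_inverse_affine(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 2.0, 50)
        base = np.zeros(50, bool)
        base[:10] = True
        pct = relative_change(x, base)
        back = (pct / 100.0 + 1.0) * x[:10].mean()
        np.testing.assert_allclose(back, x, rtol=1e-12)

    def test_bad_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(np.ones(5), np.zeros(5, bool))
        with pytest.raises(ValueError):
            relative_change(np.zeros(5), np.ones(5, bool))


class TestGroupAverage:
    def test_identical_series(self):
        series = [np.arange(5.0)] * 4
        out = group_average_trimmed(series)
        np.testing.assert_allclose(out["mean"], np.arange(5.0))
        np.testing.assert_allclose(out["se"], 0.0)

    def test_spike_removed_from_trimmed_mean(self):
        base = [np.ones(10) * k for k in (1.0, 2.0, 3.0, 4.0, 5.0)]
        base[2] = base[2].copy()
        base[2][4] = 100.0          # spike at t=4 in one series
        out = group_average_trimmed(base)
        assert out["mean"][4] == pytest.approx(out["mean"][3], abs=1.0)
        assert out["mean"][4] < 10.0

    def test_quartiles_of_trimmed_values(self):
        series = [np.full(3, v) for v in (1.0, 2.0, 3.0, 4.0, 5.0)]
        out = group_average_trimmed(series)
        # trimming leaves {2,3,4}: quartiles by linear interpolation
        np.testing.assert_allclose(out["q25"], 2.5)
        np.testing.assert_allclose(out["q75"], 3.5)

    def test_requires_three_series(self):
        with pytest.raises(ValueError):
            group_average_trimmed([np.ones(4), np.ones(4)])


class TestScreening:
    def _args(self, **kw):
        t = np.arange(5.0, 300.0, 10.0)
        d5 = np.interp(t, [0, 60, 200, 300], [0, 0, 40, 30])
        dl = np.interp(t, [0, 60, 180, 250, 300], [0, 0, 30, 5, 2])
        args = dict(count_rate_30mm_hz=12_000.0, baseline_cov=0.10,
                    time_s=t, drbfi_5mm_pct=d5, drbfi_long_pct=dl,
                    co2_end_s=180.0)
        args.update(kw)
        return args

    def test_contaminated_session_passes_all_gates(self):
        report = screen_measurement(**self._args())
        assert report.passed and not report.reasons

    def test_count_rate_boundary(self):
        report = screen_measurement(**self._args(count_rate_30mm_hz=4999.0))
        assert not report.passed
        assert any("count-rate" in r for r in report.reasons)
        assert screen_measurement(**self._args(count_rate_30mm_hz=5000.0)).passed

    def test_cov_threshold_is_strict(self):
        report = screen_measurement(**self._args(baseline_cov=0.25))
        assert not report.passed
        assert any("baseline-cov" in r for r in report.reasons)

    def test_mirror_profile_flags_low_sensitivity(self):
        t = np.arange(5.0, 300.0, 10.0)
        d5 = np.interp(t, [0, 60, 200, 300], [0, 0, 40, 30])
        report = screen_measurement(**self._args(drbfi_long_pct=d5.copy()))
        assert not report.passed
        assert any("distinct-profile" in r for r in report.reasons)
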