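"""Analysis-layer tests on synthetic traces with known answers."""

import numpy as np
import pytest

from sanfib import metrics
from sanfib.cellmodels.singlecell import ThresholdCurve


def _sawtooth(period_ms=800.0, n_beats=6, dt=0.2, peak=20.0, base=-60.0):
    """Sawtooth-like AP train with peaks at exact multiples of the period."""
    t = np.arange(0, period_ms * n_beats, dt)
    v = np.full_like(t, base)
    for k in range(n_beats):
        t0 = k * period_ms + 40.0
        rise = (t >= t0 - 16.0) & (t <= t0)
        fall = (t > t0) & (t < t0 + period_ms - 16.0)
        frac = (t[rise] - t0 + 16.0) / 16.0
        v[rise] = base + (peak - base) * (3 * frac ** 2 - 2 * frac ** 3)
        v[fall] = np.maximum(base, peak - (peak - base) * (t[fall] - t0) / 600.0)
    return t, v


class TestCycleLengths:
    def test_sawtooth_period_recovered_both_modes(self):
        t, v = _sawtooth(800.0)
        for mode in ("SAN", "ATRIUM"):
            cls = metrics.detect_cycle_lengths(t, v, mode)
            assert len(cls) >= 4
            assert np.allclose(cls, 800.0, atol=1.0)

    def test_single_ap_gives_empty(self):
        t = np.arange(0, 400, 0.2)
        v = np.full_like(t, -70.0)
        v[(t > 100) & (t < 110)] = 20.0
        assert len(metrics.detect_cycle_lengths(t, v, "SAN")) == 0

    def test_flat_trace_gives_empty(self):
        t = np.arange(0, 1000, 0.2)
        assert len(metrics.detect_cycle_lengths(t, np.full_like(t, -74.0),
                                                "ATRIUM")) == 0

    def test_periodic_trace_has_zero_cl_dispersion(self):
        t, v = _sawtooth(650.0, n_beats=8)
        cls = metrics.detect_cycle_lengths(t, v, "SAN")
        assert np.std(cls) < 0.5

    def test_subthreshold_deflections_rejected_in_atrial_mode(self):
        t = np.arange(0, 3000, 0.2)
        v = -74.0 + 5.0 * np.sin(2 * np.pi * t / 500.0)  # slow, small
        assert len(metrics.detect_cycle_lengths(t, v, "ATRIUM")) == 0


def _flat_curve(q=2.0):
    d = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
    return ThresholdCurve(d, np.full_like(d, q))


class TestSafetyFactor:
    def test_rectangular_pulse_identity(self):
        # Qgap exactly equal to Qthr -> SF = 1
        t = np.arange(0, 20.0, 0.005)
        igap = np.zeros_like(t)
        igap[(t >= 5.0) & (t < 7.0)] = -1.0       # 2 ms x 1 nA = 2 pC
        curve = _flat_curve(2.0)
        sf = metrics.safety_factor(t, igap, curve)
        assert sf == pytest.approx(1.0, rel=0.02)

    def test_triangular_pulse_matches_analytic_area(self):
        t = np.arange(0, 30.0, 0.005)
        igap = np.zeros_like(t)
        rise = (t >= 10.0) & (t < 12.0)
        fall = (t >= 12.0) & (t < 14.0)
        igap[rise] = -(t[rise] - 10.0) / 2.0
        igap[fall] = -(14.0 - t[fall]) / 2.0
        # analytic area: 0.5 * base(4 ms) * height(1 nA) = 2 pC
        curve = _flat_curve(1.0)
        sf = metrics.safety_factor(t, igap, curve)
        assert sf == pytest.approx(2.0, rel=1e-3)

    def test_long_pulse_uses_saturated_threshold(self):
        # ta = 9 ms -> denominator must be Qthr(4 ms), not an extrapolation
        t = np.arange(0, 30.0, 0.005)
        igap = np.zeros_like(t)
        igap[(t >= 5.0) & (t < 14.0)] = -1.0
        d = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        curve = ThresholdCurve(d, 1.0 * d)        # Qthr = ta, saturating at 4
        sf = metrics.safety_factor(t, igap, curve)
        assert sf == pytest.approx(9.0 / curve.qthr(9.0), rel=0.01)
        assert curve.qthr(9.0) == pytest.approx(curve.qthr(4.0))

    def test_time_shift_invariance_and_linear_scaling(self):
        t = np.arange(0, 40.0, 0.005)
        igap = np.zeros_like(t)
        seg = (t >= 8.0) & (t < 11.0)
        igap[seg] = -np.sin(np.pi * (t[seg] - 8.0) / 3.0)
        curve = _flat_curve(1.5)
        sf0 = metrics.safety_factor(t, igap, curve)
        sf_shift = metrics.safety_factor(t + 123.4, igap, curve)
        sf_scaled = metrics.safety_factor(t, 2.5 * igap, curve)
        assert sf_shift == pytest.approx(sf0, rel=1e-12)
        assert sf_scaled == pytest.approx(2.5 * sf0, rel=1e-9)

    def test_no_depolarising_phase_is_nan(self):
        t = np.arange(0, 10.0, 0.01)
        sf = metrics.safety_factor(t, np.abs(np.sin(t)), _flat_curve())
        assert np.isnan(sf)


def _ap_train(times_of_aps, total_ms=50000.0, dt=0.2):
    t = np.arange(0, total_ms, dt)
    v = np.full_like(t, -74.0)
    for t0 in times_of_aps:
        up = (t >= t0) & (t < t0 + 2.0)
        v[up] = -74.0 + (t[up] - t0) / 2.0 * 95.0
        plateau = (t >= t0 + 2.0) & (t < t0 + 200.0)
        v[plateau] = 21.0 - (t[plateau] - t0 - 2.0) / 198.0 * 95.0
    return t, v


class TestSNRT:
    def test_printed_uniform_example(self):
        # last stimulus at 41,500 ms, first recovery upstroke at 42,602 ms
        t, v = _ap_train([40500.0, 41501.0, 42600.0], total_ms=44000.0)
        snrt, corr = metrics.sinus_node_recovery_time(t, v, 41500.0,
                                                      basal_cl_ms=814.0)
        assert snrt == pytest.approx(1102.0, abs=5.0)
        assert corr == pytest.approx(1102.0 - 814.0, abs=5.0)

    def test_recovery_after_exactly_one_basal_cl_gives_zero_corrected(self):
        t, v = _ap_train([41501.0, 42314.0], total_ms=43500.0)
        snrt, corr = metrics.sinus_node_recovery_time(t, v, 41500.0,
                                                      basal_cl_ms=814.0)
        assert corr == pytest.approx(0.0, abs=5.0)

    def test_no_recovery_reported_as_nan(self):
        t = np.arange(0, 50000.0, 0.2)
        v = np.full_like(t, -74.0)
        snrt, corr = metrics.sinus_node_recovery_time(t, v, 41500.0, 814.0)
        assert np.isnan(snrt) and np.isnan(corr)

    def test_dysfunction_flag_threshold(self):
        assert metrics.is_nodal_dysfunction(526.0)
        assert not metrics.is_nodal_dysfunction(288.0)


class TestConduction:
    def test_printed_pathway_example(self):
        # 20-cell path with CT = 380 ms -> CV = 0.35 cm/s
        act = np.linspace(0.0, 380.0, 20)
        cv, ct = metrics.conduction_velocity(act)
        assert ct == pytest.approx(380.0)
        assert cv == pytest.approx(20 * 67e-4 / 0.380, rel=1e-12)
        assert round(cv, 2) == 0.35

    def test_linear_ramp_matches_analytic_velocity(self):
        # 1 ms per cell at 67 um -> 6.7 cm/s
        act = np.arange(30) * 1.0
        cv, ct = metrics.conduction_velocity(act)
        assert cv == pytest.approx(30 * 67e-4 / (29e-3), rel=1e-12)

    def test_degenerate_and_nonmonotone_guarded(self):
        with pytest.raises(ValueError):
            metrics.conduction_velocity(np.zeros(10))
        with pytest.raises(ValueError):
            metrics.conduction_velocity(np.array([5.0, 1.0, np.nan]))


class TestActivationMap:
    def test_synchronous_patch_has_zero_spread(self):
        t, v = _sawtooth(800.0, n_beats=4)
        volts = np.tile(v[:, None], (1, 6))
        act = metrics.activation_map(t, volts, np.ones(6, dtype=bool))
        assert np.nanmax(act) - np.nanmin(act) == pytest.approx(0.0, abs=0.5)

    def test_wavefront_ordering_recovered(self):
        t = np.arange(0, 2000.0, 0.2)
        delays = np.array([0.0, 40.0, 80.0, 120.0])
        volts = np.empty((t.size, 4))
        for i, d0 in enumerate(delays):
            _, v = _ap_train([700.0 + d0], total_ms=2000.0)
            volts[:, i] = v
        act = metrics.activation_times(t, volts, np.zeros(4, dtype=bool),
                                       (600.0, 1200.0))
        assert np.all(np.diff(act) > 0)
        assert act[-1] - act[0] == pytest.approx(120.0, abs=2.0)

    def test_leading_pathway_earliest_and_tiebreak(self):
        act = np.array([100.0, 50.0, 50.0, np.nan])
        assert metrics.leading_sep(act, {1: [0], 2: [1], 3: [2]}) == 2
        assert metrics.leading_sep(act, {5: [3]}) is None


class TestCompareSetups:
    def test_identical_samples_guarded_to_p_one(self):
        df = metrics.compare_setups({"H": [1.0, 1.0, 1.0],
                                     "UF": [1.0, 1.0, 1.0]})
        row = df[(df.setup_a == "H") & (df.setup_b == "UF")].iloc[0]
        assert row.p == 1.0 and not row.significant

    def test_one_sample_t_matches_closed_form(self):
        vals = np.array([1.58, 1.62, 1.55, 1.60, 1.65])
        u = 1.45
        df = metrics.compare_setups({"U": u, "H": vals})
        row = df[(df.setup_a == "H") & (df.setup_b == "U")].iloc[0]
        t_expected = (vals.mean() - u) / (vals.std(ddof=1) / np.sqrt(5))
        assert row.t == pytest.approx(t_expected, rel=1e-9)
        assert row.significant

    def test_paired_t_on_shifted_samples(self):
        a = np.array([1.0, 1.1, 0.9, 1.05, 0.95])
        b = a + 0.2
        df = metrics.compare_setups({"H": a, "HF": b})
        row = df[(df.setup_a == "H") & (df.setup_b == "HF")].iloc[0]
        assert row.p < 1e-6 and row.significant

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            metrics.compare_setups({"U": 1.0, "H": [1.2]})
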