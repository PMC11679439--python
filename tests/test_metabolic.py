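import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smartdrive import metabolic as mb
from smartdrive.traces import Phase, SensorTrace, SessionDescriptor


def _session(cabin=3.0e6, phases=None):
    phases = phases or [Phase("parked", 0.0, 600.0)]
    return SessionDescriptor("s", phases, cabin_volume_ml=cabin)


# ---------------------------------------------------------------------------
# scalar pieces
# ---------------------------------------------------------------------------


def test_air_exchange_trendline_values():
    """Calibrated exchange-rate line: intercept at standstill, affine in speed."""
    assert mb.lambda_from_speed(0.0) == pytest.approx(10.323, abs=0)
    assert mb.lambda_from_speed(10.0) == pytest.approx(12.857, abs=1e-9)
    speeds = np.linspace(0, 25, 11)
    lam = mb.lambda_from_speed(speeds)
    assert np.all(np.diff(lam) > 0)
    assert mb.lambda_from_speed(1.0) - mb.lambda_from_speed(0.0) == pytest.approx(0.2534)


def test_lambda_rejects_negative_speed():
    with pytest.raises(ValueError):
        mb.lambda_from_speed(-1.0)


def test_stpd_identity_point():
    """Dry air at 760 mmHg and 0 degC needs no correction."""
    assert mb.stpd_factor(mb.StpdInputs(0.0, 760.0, 0.0)) == 1.0


def test_stpd_hand_computed_value():
    # Antoine at 25 degC: Psat = 10**(8.07131 - 1730.63/258.426) = 23.68 mmHg;
    # P_H2O = 0.30 * Psat = 7.105; CF = (700-7.105)/760 * 273/298 = 0.8352
    assert mb.stpd_factor(mb.StpdInputs(25.0, 700.0, 30.0)) == pytest.approx(0.8352, abs=2e-4)


@given(st.floats(1.0, 45.0), st.floats(650.0, 790.0), st.floats(0.0, 100.0))
def test_stpd_monotone_decreasing_in_temperature(t, p, rh):
    a = mb.stpd_factor(mb.StpdInputs(t, p, rh))
    b = mb.stpd_factor(mb.StpdInputs(t + 1.0, p, rh))
    assert b < a


def test_stpd_input_validation():
    with pytest.raises(ValueError):
        mb.StpdInputs(-300.0, 760.0, 0.0)
    with pytest.raises(ValueError):
        mb.StpdInputs(20.0, 760.0, 130.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _forward_segment(k_gen=4000.0, lam=10.323, c_i=600.0, c0=450.0, n=300, rate=1.0):
    t = np.arange(n, dtype=float) / rate
    y = mb.co2_closed_form(t, c0, c_i, k_gen, lam)
    return SensorTrace("co2", t, y, "ppm", rate)


def test_fit_recovers_kgen_noiseless():
    seg = _forward_segment()
    fit = mb.fit_kgen(seg, 10.323, 450.0)
    assert abs(fit.k_gen - 4000.0) / 4000.0 < 1e-6
    assert fit.params.co2_initial == pytest.approx(600.0, abs=1e-3)
    assert fit.rmse_ppm < 1e-6


def test_fit_recovers_kgen_under_noise():
    """95th-percentile relative error < 5 % with 1 % multiplicative noise."""
    errs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        seg = _forward_segment()
        noisy = SensorTrace(
            "co2", seg.timestamps, seg.values * (1 + rng.normal(0, 0.01, len(seg))),
            "ppm", 1.0,
        )
        fit = mb.fit_kgen(noisy, 10.323, 450.0)
        errs.append(abs(fit.k_gen - 4000.0) / 4000.0)
    assert np.quantile(errs, 0.95) < 0.05


def test_fit_flat_segment_gives_zero_kgen():
    t = np.arange(120.0)
    seg = SensorTrace("co2", t, np.full(120, 450.0), "ppm", 1.0)
    fit = mb.fit_kgen(seg, 10.323, 450.0)
    assert fit.k_gen == pytest.approx(0.0, abs=1e-6)


def test_fit_rejects_short_segment():
    seg = _forward_segment(n=5)
    with pytest.raises(ValueError, match="short"):
        mb.fit_kgen(seg, 10.323)


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------


def test_rising_parked_trace_one_segment():
    seg = _forward_segment(n=600)
    session = _session()
    out = mb.extract_accumulation_segments(seg, [], session)
    assert len(out) == 1
    phase, s = out[0]
    assert phase == "parked"
    assert s.timestamps[0] >= 10.0  # leading transient trimmed


def test_purge_splits_phase_into_two_segments():
    t = np.arange(900.0)
    up1 = mb.co2_closed_form(t[:400], 450, 600, 4000, 10.3)
    down = np.linspace(up1[-1], 600.0, 100)
    up2 = mb.co2_closed_form(t[:400], 450, 600, 4000, 10.3)
    y = np.concatenate([up1, down, up2])
    trace = SensorTrace("co2", t, y, "ppm", 1.0)
    session = _session(phases=[Phase("parked", 0.0, 900.0)])
    log = [(400.0, "purging"), (500.0, "recirculating")]
    out = mb.extract_accumulation_segments(trace, log, session)
    assert len(out) == 2


def test_decreasing_trace_yields_no_segments():
    t = np.arange(300.0)
    trace = SensorTrace("co2", t, 900.0 - 0.5 * t, "ppm", 1.0)
    out = mb.extract_accumulation_segments(trace, [], _session(phases=[Phase("parked", 0, 300)]))
    assert out == []


# ---------------------------------------------------------------------------
# energy expenditure chain
# ---------------------------------------------------------------------------


def test_vco2_from_kgen_worked_example():
    """4000 ppm/hr in a 3.0e6 mL cabin at CF_STPD=1 gives 228.6 mL/min."""
    params = mb.Co2ModelParams(450.0, 600.0, 4000.0, 10.323)
    est = mb.ee_from_kgen(params, _session(), stpd=1.0)
    assert est.k_gen_prime == pytest.approx(4000.0 * 1.143)
    assert est.vco2 == pytest.approx(228.6, abs=0.01)
    assert est.vo2 == pytest.approx(est.vco2 / 0.85)


def test_weir_worked_example():
    """EE(200 mL/min, RQ 0.85) = 3.941*200/0.85 + 1.106*200 = 1148.5."""
    assert mb.weir_ee(200.0) == pytest.approx(1148.49, abs=0.01)
    assert mb.weir_ee(0.0) == 0.0


def test_weir_day_factor_flag():
    c = mb.MetabolicConstants(include_144_factor=True)
    assert mb.weir_ee(200.0, c) == pytest.approx(1.44 * 1148.49, abs=0.1)


def test_ee_linear_in_kgen():
    session = _session()
    stpd = 0.9
    c = mb.MetabolicConstants()
    slope = c.cf_env * 1e-6 * session.cabin_volume_ml * stpd / 60.0 * c.weir_slope
    for k in (1000.0, 3000.0, 8000.0):
        est = mb.ee_from_kgen(mb.Co2ModelParams(450, 600, k, 10.323), session, stpd, c)
        assert est.ee == pytest.approx(slope * k, rel=1e-12)


def test_ee_inversion_roundtrip_scalar():
    c = mb.MetabolicConstants()
    k = mb.kgen_from_ee(1700.0, 3.0e6, 0.88, c)
    est = mb.ee_from_kgen(mb.Co2ModelParams(450, 600, k, 11.0), _session(), 0.88, c)
    assert est.ee == pytest.approx(1700.0, rel=1e-12)


def test_phase_ee_change_arithmetic():
    def est(phase, ee):
        return mb.MetabolicEstimate(phase, 0, 0, 0, 0, ee, 0, (0, 0))

    ind = mb.phase_ee_change({"normal": est("normal", 1000.0), "aggressive": est("aggressive", 1200.0)})
    assert ind.ee_change_pct == pytest.approx(20.0)
    ind = mb.phase_ee_change({"normal": est("normal", 1000.0), "aggressive": est("aggressive", 1000.0)})
    assert ind.ee_change_pct == 0.0
    ind = mb.phase_ee_change({"normal": est("normal", 1000.0), "aggressive": est("aggressive", 900.0)})
    assert ind.ee_change_pct == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        mb.phase_ee_change({"normal": est("normal", 0.0), "aggressive": est("aggressive", 1.0)})


def test_hybrid_indicator_boundary_and_additivity():
    ind = mb.hybrid_indicators(8.0, 20.0)
    assert ind.speed_x_ee == pytest.approx(mb.SPEED_EE_THRESHOLD)
    # fraction reading: speed^2*ee/(0.1*speed) = 10*speed*ee
    ind = mb.hybrid_indicators(16.0, 18.0, 0.0)
    assert ind.eq_feature == pytest.approx(2880.0)
    d = 7.5
    with_dev = mb.hybrid_indicators(16.0, 18.0, d)
    assert with_dev.eq_feature - ind.eq_feature == pytest.approx(d)
    with pytest.raises(ValueError):
        mb.hybrid_indicators(10.0, 0.0)


def test_end_to_end_ee_roundtrip_noiseless():
    """EE* -> k_gen -> simulated trace -> segments -> fit -> EE within 0.1 %."""
    target = 1500.0
    c = mb.MetabolicConstants()
    session = _session()
    stpd = mb.stpd_factor(mb.StpdInputs(25.0, 740.0, 30.0), c)
    k = mb.kgen_from_ee(target, session.cabin_volume_ml, stpd, c)
    t = np.arange(600.0)
    y = mb.co2_closed_form(t, c.co2_outdoor_ppm, 600.0, k, mb.lambda_from_speed(0.0, c))
    trace = SensorTrace("co2", t, y, "ppm", 1.0)
    segments = mb.extract_accumulation_segments(trace, [], session)
    assert len(segments) == 1
    fit = mb.fit_kgen(segments[0][1], mb.lambda_from_speed(0.0, c), c.co2_outdoor_ppm)
    est = mb.ee_from_kgen(fit.params, session, stpd, c)
    assert abs(est.ee - target) / target < 1e-3
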