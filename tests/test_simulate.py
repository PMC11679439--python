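import math
from collections import Counter

import numpy as np
import pytest

from smartdrive import metabolic
from smartdrive.circuit import TURN_SEQUENCE, CircuitGeometry
from smartdrive.simulate import (
    CabinEnvironment,
    DriverProfile,
    NoiseConfig,
    designated_path_from_kinematics,
    generate_cohort,
    inject_path_errors,
    sample_error_counts,
    simulate_cabin_co2,
    simulate_kinematics,
    simulate_subject,
)
from smartdrive.traces import Phase, SensorTrace, SessionDescriptor
from smartdrive.ventilation import VentController


def _pulse_masks(kin):
    for m in kin.schedule:
        if m.kind != "straight":
            yield m, (kin.gyro.timestamps >= m.t_start - 1e-9) & (
                kin.gyro.timestamps <= m.t_end + 1e-9
            )


def test_lap_pulse_count_and_signs(noiseless_lap):
    """One lap: 8 pulses, signs + + + + + - - - with a +pi U-turn."""
    kinds = [m.kind for m, _ in _pulse_masks(noiseless_lap)]
    assert kinds == list(TURN_SEQUENCE)
    signs = [np.sign(m.dtheta) for m, _ in _pulse_masks(noiseless_lap)]
    assert signs == [1, 1, 1, 1, 1, -1, -1, -1]


def test_corner_pulse_integrates_to_corner_angle(noiseless_lap):
    """The sampled 10 Hz pulse integrates to the exact corner angle."""
    for m, mask in _pulse_masks(noiseless_lap):
        integral = np.trapezoid(
            noiseless_lap.gyro.values[mask], noiseless_lap.gyro.timestamps[mask]
        )
        assert integral == pytest.approx(m.dtheta, abs=1e-6)


def test_lap_length_conserved(noiseless_lap, one_lap_geometry):
    d = np.sum(np.linalg.norm(np.diff(noiseless_lap.path_xy, axis=0), axis=1))
    assert abs(d - one_lap_geometry.lap_length_m) < 0.5


def test_simulation_deterministic():
    p = DriverProfile()
    g = CircuitGeometry(lap_count=2)
    a = simulate_kinematics(p, g, "normal", noise=NoiseConfig(), seed=5)
    b = simulate_kinematics(p, g, "normal", noise=NoiseConfig(), seed=5)
    assert np.array_equal(a.gyro.values, b.gyro.values)
    assert np.array_equal(a.gps.xy, b.gps.xy)


def test_gps_positions_near_path():
    kin = simulate_kinematics(
        DriverProfile(), CircuitGeometry(lap_count=1), "normal",
        noise=NoiseConfig(gps_sd_m=1.0, gyro_sd=0.0, speed_sd_mph=0.0), seed=2,
    )
    # noisy fixes scatter about the noiseless trajectory with ~1 m per axis
    clean = simulate_kinematics(
        DriverProfile(), CircuitGeometry(lap_count=1), "normal",
        noise=NoiseConfig.none(), seed=2,
    )
    resid = kin.gps.xy - clean.gps.xy
    assert 0.5 < np.std(resid) < 1.5


def test_zero_speed_rejected():
    p = DriverProfile(speed_normal_mph=0.0)
    with pytest.raises(ValueError, match="zero speed"):
        simulate_kinematics(p, CircuitGeometry(lap_count=1), "normal")


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


def test_inject_zero_rates_identity(noiseless_session, designated_path):
    rng = np.random.default_rng(0)
    out, ledger = inject_path_errors(
        noiseless_session, designated_path, {}, rng
    )
    assert ledger == []
    assert np.array_equal(out.gyro.values, noiseless_session.gyro.values)
    assert np.array_equal(out.gps.xy, noiseless_session.gps.xy)


def test_inject_off_path_geometry(noiseless_session, designated_path):
    rng = np.random.default_rng(3)
    out, ledger = inject_path_errors(
        noiseless_session, designated_path, {"off_path": 2}, rng
    )
    assert [e.kind for e in ledger] == ["off_path", "off_path"]
    line = designated_path.linestring
    import shapely

    d = shapely.distance(shapely.points(out.gps.xy), line)
    assert np.max(d) >= 8.0  # at least one fix beyond eight GPS-error radii
    assert all(e.magnitude_m >= 8.0 for e in ledger)


def test_inject_exited_path_leaves_perimeter(noiseless_session, designated_path):
    rng = np.random.default_rng(4)
    out, ledger = inject_path_errors(
        noiseless_session, designated_path, {"exited_path": 1}, rng
    )
    import shapely

    inside = shapely.covers(designated_path.perimeter, shapely.points(out.gps.xy))
    assert not np.all(inside)


def test_sample_error_counts_poisson_seeded():
    rng = np.random.default_rng(0)
    c1 = sample_error_counts({"off_path": 2.0}, np.random.default_rng(9))
    c2 = sample_error_counts({"off_path": 2.0}, np.random.default_rng(9))
    assert c1 == c2
    assert set(c1) == {
        "uturns_missed", "uturns_unplanned", "uturns_consecutive", "off_path", "exited_path",
    }


def test_heading_conservation_with_injection(noiseless_session, designated_path):
    """Integrated gyro = chained-lap heading change plus injected U-turn angles."""
    rng = np.random.default_rng(8)
    out, ledger = inject_path_errors(
        noiseless_session, designated_path, {"uturns_unplanned": 1, "uturns_missed": 1}, rng
    )
    base = np.trapezoid(noiseless_session.gyro.values, noiseless_session.gyro.timestamps)
    total = np.trapezoid(out.gyro.values, out.gyro.timestamps)
    expected = base + math.pi - math.pi  # one inserted +pi, one deleted +pi
    assert total == pytest.approx(expected, abs=1e-3)


# ---------------------------------------------------------------------------
# cabin CO2
# ---------------------------------------------------------------------------


def _parked_session(duration=600.0):
    return SessionDescriptor("s", [Phase("parked", 0.0, duration)], cabin_volume_ml=3.0e6)


def _zero_speed(duration=600.0):
    t = np.arange(0.0, duration + 0.5)
    return SensorTrace("speed", t, np.zeros_like(t), "mph", 1.0)


def test_co2_matches_closed_form_at_constant_speed():
    """Forward integration equals the analytic accumulation profile."""
    session = _parked_session()
    prof = DriverProfile()
    env = CabinEnvironment()
    co2 = simulate_cabin_co2(session, prof, _zero_speed(), 1, None, env, co2_initial=600.0)
    c = metabolic.MetabolicConstants()
    cf = metabolic.stpd_factor(env.stpd_inputs(), c)
    k = metabolic.kgen_from_ee(prof.base_ee, session.cabin_volume_ml, cf, c)
    lam = metabolic.lambda_from_speed(0.0, c)
    expected = metabolic.co2_closed_form(co2.timestamps, c.co2_outdoor_ppm, 600.0, k, lam)
    assert np.allclose(co2.values, expected, rtol=1e-9)


def test_co2_steady_state_limit():
    """With the controller off the concentration approaches C0 + k/lambda."""
    session = _parked_session(4 * 3600.0)
    prof = DriverProfile()
    env = CabinEnvironment()
    co2 = simulate_cabin_co2(
        session, prof, _zero_speed(4 * 3600.0), 1, None, env, co2_initial=600.0
    )
    c = metabolic.MetabolicConstants()
    cf = metabolic.stpd_factor(env.stpd_inputs(), c)
    k = metabolic.kgen_from_ee(prof.base_ee, session.cabin_volume_ml, cf, c)
    steady = c.co2_outdoor_ppm + k / metabolic.lambda_from_speed(0.0, c)
    assert co2.values[-1] == pytest.approx(steady, abs=1.0)
    assert np.all(np.diff(co2.values) >= -1e-9)  # monotone rise toward steady state


def test_doubling_occupants_doubles_excess():
    session = _parked_session(7200.0)
    prof = DriverProfile()
    env = CabinEnvironment()
    kw = dict(vent=None, env=env, co2_initial=450.0)
    c1 = simulate_cabin_co2(session, prof, _zero_speed(7200.0), 1, None, env, co2_initial=450.0)
    c2 = simulate_cabin_co2(session, prof, _zero_speed(7200.0), 2, None, env, co2_initial=450.0)
    c0 = metabolic.MetabolicConstants().co2_outdoor_ppm
    assert (c2.values[-1] - c0) == pytest.approx(2 * (c1.values[-1] - c0), rel=1e-6)


def test_vent_controller_purges_and_recovers():
    """Crossing the max threshold triggers a purge that drains to the min."""
    session = _parked_session(3600.0)
    prof = DriverProfile(base_ee=2000.0)  # strong source to force actuation
    env = CabinEnvironment()
    vent = VentController(600.0, 900.0)
    co2 = simulate_cabin_co2(
        session, prof, _zero_speed(3600.0), 1, vent, env, co2_initial=600.0
    )
    states = [s for _t, s in vent.actuation_log]
    assert "purging" in states and "recirculating" in states
    assert states == [("purging" if i % 2 == 0 else "recirculating") for i in range(len(states))]
    assert np.max(co2.values) < 950.0  # held near the band


def test_cohort_manifest_shape_and_determinism(tmp_path):
    subs, man = generate_cohort(2, 1, seed=7, out_dir=tmp_path / "c")
    assert len(subs) == 3 and len(man) == 3
    assert sorted(man["cognition"]) == ["mci", "normal", "normal"]
    assert (tmp_path / "c" / "manifest.csv").exists()
    assert (tmp_path / "c" / "S000" / "gyro_normal.csv").exists()
    _subs2, man2 = generate_cohort(2, 1, seed=7)
    assert man.equals(man2)


def test_empty_cohort():
    subs, man = generate_cohort(0, 0, seed=1)
    assert subs == [] and len(man) == 0


def test_profile_validation():
    with pytest.raises(ValueError, match="cognition"):
        DriverProfile(cognition="other")
    with pytest.raises(ValueError, match="rates"):
        DriverProfile(path_error_rates={"off_path": -1.0})
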