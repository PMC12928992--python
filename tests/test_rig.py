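"""Physics of the two-resistor circuit and the seeded stream simulator."""

import math

import numpy as np
import pytest

from peekflow.calibration import height_to_pressure
from peekflow.rig import (
    CircuitConfig,
    DegenerateFlowError,
    FaultSpec,
    SensorSpec,
    SensorStream,
    simulate_backpressure_phase,
    simulate_displacement_series,
    simulate_measurement,
    simulate_stream,
    steady_state_solution,
)
from peekflow.water import water_density


def brute_force_solution(cfg):
    """Independent oracle: solve the series network as a 2x2 linear system
    in (Q, P_down) instead of using the closed form."""
    from peekflow.water import WATER
    t = cfg.mean_temperature_c
    scale = float(WATER.viscosity_ratio_to_25c(t))
    p_head = height_to_pressure(cfg.height_cm, t)
    # P_head - P_down = Q * R_t ;  P_down - bp = Q * R_s
    a = np.array([[cfg.r_tubing * scale, 1.0], [-cfg.r_sample * scale, 1.0]])
    b = np.array([p_head, cfg.backpressure_kpa])
    q, p_down = np.linalg.solve(a, b)
    return {"Q": q, "P_up": p_head, "P_down": p_down}


class TestSteadyState:
    def test_matched_resistances_give_half_ratio(self, blue_circuit):
        s = steady_state_solution(blue_circuit)
        assert s["P_down"] / s["P_up"] == pytest.approx(0.5, abs=1e-12)

    def test_blocked_sample_has_no_flow(self):
        cfg = CircuitConfig(height_cm=25, r_tubing=10, r_sample=math.inf)
        s = steady_state_solution(cfg)
        assert s["Q"] == 0.0
        assert s["P_down"] == s["P_up"]

    def test_hand_evaluated_example(self, blue_circuit):
        # 25 cm head at 25 degC: P_head = rho * g * 0.25 m = 2.4444 kPa;
        # Q = P_head / (10 + 10); P_down = P_head - Q * 10
        p_head = water_density(25.0) * 9.80665 * 0.25 / 1000.0
        s = steady_state_solution(blue_circuit)
        assert s["P_up"] == pytest.approx(p_head, rel=1e-12)
        assert s["Q"] == pytest.approx(p_head / 20.0, rel=1e-12)
        assert s["P_down"] == pytest.approx(p_head / 2.0, rel=1e-12)
        assert s["P_down"] == pytest.approx(1.222, abs=0.001)

    def test_series_identity_holds(self, blue_circuit):
        s = steady_state_solution(blue_circuit)
        assert s["P_down"] == pytest.approx(
            blue_circuit.backpressure_kpa + s["Q"] * blue_circuit.r_sample,
            rel=1e-12)

    def test_agrees_with_network_solve_on_random_configs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            cfg = CircuitConfig(
                height_cm=rng.uniform(5, 50),
                r_tubing=rng.uniform(0.5, 50),
                r_sample=rng.uniform(0.5, 50),
                backpressure_kpa=rng.uniform(0, 0.4),
                temperature_c=rng.uniform(15, 35),
            )
            a = steady_state_solution(cfg)
            b = brute_force_solution(cfg)
            assert abs(a["Q"] - b["Q"]) <= 1e-10 * abs(b["Q"])
            assert abs(a["P_down"] - b["P_down"]) <= 1e-10 * abs(b["P_down"])

    def test_ratio_monotone_in_resistance_ratio(self):
        ratios = []
        for r_sample in (2.0, 5.0, 10.0, 20.0, 50.0):
            s = steady_state_solution(
                CircuitConfig(height_cm=25, r_tubing=10, r_sample=r_sample))
            ratios.append(s["P_down"] / s["P_up"])
        assert ratios == sorted(ratios)

    def test_head_below_backpressure_degenerate(self):
        cfg = CircuitConfig(height_cm=1.0, r_tubing=10, r_sample=10,
                            backpressure_kpa=0.5)
        with pytest.raises(DegenerateFlowError):
            steady_state_solution(cfg)


class TestSimulateStream:
    def test_zero_noise_matches_steady_state(self, blue_circuit, ideal_sensor):
        stream = simulate_stream(blue_circuit, ideal_sensor, ideal_sensor, seed=1)
        s = steady_state_solution(blue_circuit)
        assert np.allclose(stream.p_up, s["P_up"], rtol=1e-12)
        assert np.allclose(stream.p_down, s["P_down"], rtol=1e-12)
        assert len(stream.t) == 600

    def test_same_seed_bit_identical(self, blue_circuit):
        a = simulate_stream(blue_circuit, seed=7)
        b = simulate_stream(blue_circuit, seed=7)
        assert np.array_equal(a.p_up, b.p_up)
        assert np.array_equal(a.p_down, b.p_down)
        c = simulate_stream(blue_circuit, seed=8)
        assert not np.array_equal(a.p_down, c.p_down)

    def test_flow_continuity_within_noise(self, blue_circuit):
        # per-reading noise only: continuity is a property of the circuit,
        # and random noise must average out over the stream
        sensor = SensorSpec(relative_accuracy=0.0, noise_sd_kpa=0.005)
        stream = simulate_stream(blue_circuit, sensor, sensor, seed=3)
        q_tubing = (stream.p_up - stream.p_down) / blue_circuit.r_tubing
        q_sample = (stream.p_down - blue_circuit.backpressure_kpa) / blue_circuit.r_sample
        assert np.mean(q_tubing) == pytest.approx(np.mean(q_sample), rel=0.05)

    def test_leak_inflates_apparent_conductance(self, blue_circuit, ideal_sensor):
        g_leak = 0.05
        stream = simulate_stream(
            blue_circuit, ideal_sensor, ideal_sensor,
            faults=[FaultSpec(kind="leak", magnitude=g_leak)], seed=1)
        # apparent K' from the noiseless faulted stream
        k = (stream.p_up - stream.p_down) / (
            blue_circuit.r_tubing * (stream.p_down - blue_circuit.backpressure_kpa))
        assert np.allclose(k, 1.0 / blue_circuit.r_sample + g_leak, rtol=1e-10)

    def test_overlapping_sensor_offset_faults_rejected(self, blue_circuit):
        faults = [
            FaultSpec(kind="sensor_offset", magnitude=0.1, onset_s=0, duration_s=100),
            FaultSpec(kind="sensor_offset", magnitude=0.2, onset_s=50, duration_s=100),
        ]
        with pytest.raises(ValueError):
            simulate_stream(blue_circuit, faults=faults, seed=0)

    def test_csv_round_trip(self, tmp_path, blue_circuit):
        stream = simulate_stream(blue_circuit, seed=5, meta={"device": "X1"})
        path = tmp_path / "stream.csv"
        stream.to_csv(path)
        assert path.read_text().splitlines()[0] == "t_s,P_up_kPa,P_down_kPa,T_C"
        back = SensorStream.from_csv(path)
        assert np.allclose(back.p_up, stream.p_up)
        assert back.meta["device"] == "X1"


class TestBackpressurePhase:
    def test_zero_backpressure_zero_noise(self, blue_circuit, ideal_sensor):
        phase = simulate_backpressure_phase(blue_circuit, ideal_sensor, seed=0)
        assert np.all(phase == 0.0)

    def test_reads_static_head_exactly(self, ideal_sensor):
        cfg = CircuitConfig(height_cm=25, r_tubing=10, r_sample=10,
                            backpressure_kpa=0.3)
        phase = simulate_backpressure_phase(cfg, ideal_sensor, seed=0)
        assert np.allclose(phase, 0.3)

    def test_stopcock_error_reads_flow_phase_pressure(self, blue_circuit, ideal_sensor):
        fault = [FaultSpec(kind="stopcock_error")]
        phase = simulate_backpressure_phase(
            blue_circuit, ideal_sensor, seed=0, faults=fault)
        s = steady_state_solution(blue_circuit)
        assert np.allclose(phase, s["P_down"])

    def test_shared_downstream_offset_across_phases(self, blue_circuit):
        # within one measurement the downstream sensor's accuracy offset is
        # common to both phases, so the backpressure correction cancels it
        sensor = SensorSpec(relative_accuracy=0.0025, noise_sd_kpa=0.0)
        stream, phase = simulate_measurement(
            blue_circuit, SensorSpec.ideal(), sensor, seed=11)
        s = steady_state_solution(blue_circuit)
        offset_flow = np.mean(stream.p_down) - s["P_down"]
        offset_static = np.mean(phase) - blue_circuit.backpressure_kpa
        assert offset_flow == pytest.approx(offset_static, abs=1e-12)
        assert offset_flow != 0.0


class TestDisplacementSeries:
    def test_default_heights(self, ):
        series = simulate_displacement_series(r_true=10.0, seed=0)
        assert [h for h, *_ in series] == [45.0, 35.0, 25.0, 15.0, 5.0]

    def test_doubling_resistance_halves_volume_at_fixed_time(self):
        a = simulate_displacement_series(r_true=10.0, elapsed_s=30.0, seed=0)
        b = simulate_displacement_series(r_true=20.0, elapsed_s=30.0, seed=0)
        for (_, va, *_), (_, vb, *_) in zip(a, b):
            assert vb == pytest.approx(va / 2.0, rel=1e-12)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            simulate_displacement_series(r_true=0.0, seed=0)
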