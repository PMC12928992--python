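"""Synthetic flow-meter rig: physics model and seeded sensor-stream simulator.

The hydraulic circuit is two resistors in series: an upstream reservoir at a
defined water-column head drives flow through the meter's internal PEEK
tubing (resistance ``r_tubing``) and then through the sample (``r_sample``)
into a downstream reservoir whose immersion depth produces a static
backpressure.  Two pressure sensors sit upstream and downstream of the
internal tubing.  At steady state the flow through tubing and sample is
equal, which is what lets the measurement pipeline infer sample conductance
from the two pressure drops.

The simulator perturbs the noiseless steady-state solution with per-reading
Gaussian sensor noise, a per-stream accuracy offset drawn from the sensor's
0.25 %-of-full-scale accuracy specification, gain/offset miscalibration, and
optional injected faults (leak, bubble, sensor offset, stopcock error).
Everything is reproducible from an explicit integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calibration import height_to_pressure
from .water import WATER, EnvConstants

FAULT_KINDS = ("leak", "bubble", "sensor_offset", "stopcock_error")

#: water-column heights used for daily sensor calibration (cm)
CALIBRATION_HEIGHTS_CM = tuple(range(5, 55, 5))
#: reservoir heights used for water-displacement reference characterization (cm)
DISPLACEMENT_HEIGHTS_CM = (45.0, 35.0, 25.0, 15.0, 5.0)


class DegenerateFlowError(ValueError):
    """Raised when the head cannot drive any flow (P_head <= backpressure)."""


@dataclass
class CircuitConfig:
    """One measurement configuration of the two-resistor hydraulic circuit.

    Resistances are hydraulic resistances at 25 degC in kPa s kg^-1; the
    simulator scales them by mu(T)/mu(25) at the stream temperature.
    ``temperature_c`` may be a scalar or a (start, end) pair describing a
    linear drift over the stream.
    """

    height_cm: float
    r_tubing: float
    r_sample: float
    backpressure_kpa: float = 0.0
    temperature_c: float | tuple[float, float] = 25.0
    duration_s: float = 600.0
    sample_rate_hz: float = 1.0

    def __post_init__(self):
        if self.height_cm <= 0:
            raise ValueError("height_cm must be > 0")
        if self.r_tubing <= 0:
            raise ValueError("r_tubing must be > 0")
        if not self.r_sample > 0:  # math.inf allowed (blocked sample)
            raise ValueError("r_sample must be > 0")
        if self.backpressure_kpa < 0:
            raise ValueError("backpressure_kpa must be >= 0")
        if self.duration_s < 300:
            raise ValueError("duration_s must be >= 300 s (QC window)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    @property
    def mean_temperature_c(self) -> float:
        t = self.temperature_c
        return float(np.mean(t)) if isinstance(t, (tuple, list)) else float(t)


@dataclass
class SensorSpec:
    """Error model of one pressure sensor.

    ``relative_accuracy`` is the fractional full-scale accuracy bound from the
    sensor datasheet (0.25 % of ~7 kPa / 1 psi by default); it is realized as
    a per-stream constant offset drawn N(0, relative_accuracy * full_scale).
    ``noise_sd_kpa`` is the per-reading random noise of the digitized output.
    ``gain`` and ``offset_kpa`` model residual miscalibration.
    """

    relative_accuracy: float = 0.0025
    full_scale_kpa: float = 7.0
    offset_kpa: float = 0.0
    gain: float = 1.0
    noise_sd_kpa: float = 0.005

    def __post_init__(self):
        if self.relative_accuracy < 0:
            raise ValueError("relative_accuracy must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd_kpa < 0:
            raise ValueError("noise_sd_kpa must be >= 0")

    @classmethod
    def ideal(cls) -> "SensorSpec":
        """A perfect sensor: no noise, no accuracy offset, unit gain."""
        return cls(relative_accuracy=0.0, noise_sd_kpa=0.0)

    def accuracy_sd_kpa(self) -> float:
        return self.relative_accuracy * self.full_scale_kpa


@dataclass
class FaultSpec:
    """One injected fault.

    kind:
      ``leak``           magnitude = parallel leak conductance (kg s^-1 kPa^-1)
                         from the downstream node to the downstream reservoir,
                         inflating apparent sample conductance by ~magnitude;
      ``bubble``         magnitude = multiplicative factor on sample resistance
                         during [onset, onset+duration] (transient blockage);
      ``sensor_offset``  magnitude = additive offset (kPa) on ``sensor``
                         during the window;
      ``stopcock_error`` the backpressure phase reads the flow-phase
                         downstream pressure instead of the true static head
                         (stopcocks mishandled); magnitude unused.
    """

    kind: str
    magnitude: float = 0.0
    onset_s: float = 0.0
    duration_s: float = math.inf
    sensor: str = "down"  # for sensor_offset: "up" or "down"

    def __post_init__(self):
        if self.kind not in FAULT_KINDS:
            raise ValueError(f"unknown fault kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.onset_s < 0:
            raise ValueError("onset_s must be within the stream")
        if self.sensor not in ("up", "down"):
            raise ValueError("sensor must be 'up' or 'down'")

    def active(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.onset_s) & (t < self.onset_s + self.duration_s)


@dataclass
class SensorStream:
    """Time series of calibrated pressures and solution temperature."""

    t: np.ndarray  # seconds since start, strictly increasing
    p_up: np.ndarray  # kPa
    p_down: np.ndarray  # kPa
    temperature_c: np.ndarray  # degC
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.p_up = np.asarray(self.p_up, dtype=float)
        self.p_down = np.asarray(self.p_down, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        """Write `t_s,P_up_kPa,P_down_kPa,T_C` plus a JSON metadata sidecar."""
        path = Path(path)
        arr = np.column_stack([self.t, self.p_up, self.p_down, self.temperature_c])
        np.savetxt(
            path, arr, delimiter=",", comments="",
            header="t_s,P_up_kPa,P_down_kPa,T_C", fmt="%.10g",
        )
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "SensorStream":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], meta)


def steady_state_solution(cfg: CircuitConfig, env: EnvConstants = WATER) -> dict:
    """Noiseless steady state of the series circuit.

    Returns ``{"Q", "P_up", "P_down", "P_head"}`` where
    Q = (P_head - backpressure) / (R_tubing + R_sample) and
    P_down = P_head - Q * R_tubing, with resistances scaled to the stream
    temperature.  When the tubing and sample resistances match and the
    backpressure is zero, P_down / P_up = 0.5 exactly — the optimum operating
    point of a pressure-drop flow meter.
    """
    t = cfg.mean_temperature_c
    p_head = height_to_pressure(cfg.height_cm, t, env)
    if p_head <= cfg.backpressure_kpa:
        raise DegenerateFlowError(
            f"head pressure {p_head:.4g} kPa <= backpressure "
            f"{cfg.backpressure_kpa:.4g} kPa: no flow"
        )
    scale = float(env.viscosity_ratio_to_25c(t))
    r_total = (cfg.r_tubing + cfg.r_sample) * scale
    q = 0.0 if math.isinf(r_total) else (p_head - cfg.backpressure_kpa) / r_total
    p_down = p_head - q * cfg.r_tubing * scale
    return {"Q": q, "P_up": p_head, "P_down": p_down, "P_head": p_head}


def _temperature_profile(cfg: CircuitConfig, t: np.ndarray) -> np.ndarray:
    temp = cfg.temperature_c
    if isinstance(temp, (tuple, list)):
        start, end = temp
        return start + (end - start) * (t - t[0]) / max(t[-1] - t[0], 1e-12)
    return np.full_like(t, float(temp))


def _check_faults(faults: Sequence[FaultSpec], duration_s: float) -> None:
    for f in faults:
        if f.onset_s >= duration_s:
            raise ValueError(f"fault onset {f.onset_s} s beyond stream end")
    offs = [f for f in faults if f.kind == "sensor_offset"]
    for i, a in enumerate(offs):
        for b in offs[i + 1:]:
            if a.sensor == b.sensor and a.onset_s < b.onset_s + b.duration_s \
                    and b.onset_s < a.onset_s + a.duration_s:
                raise ValueError(
                    "overlapping sensor_offset faults on the same sensor"
                )


def _solve_series(p_head, bp, r_tubing_eff, r_sample_eff):
    """Vectorized steady solution with possibly time-varying resistances."""
    q = (p_head - bp) / (r_tubing_eff + r_sample_eff)
    p_down = p_head - q * r_tubing_eff
    return q, p_down


def simulate_stream(
    cfg: CircuitConfig,
    up_sensor: SensorSpec | None = None,
    down_sensor: SensorSpec | None = None,
    faults: Sequence[FaultSpec] = (),
    seed: int = 0,
    env: EnvConstants = WATER,
    meta: dict | None = None,
    _down_accuracy_offset: float | None = None,
) -> SensorStream:
    """Simulate one flow-phase acquisition.

    The noiseless per-sample circuit solution (with leak/bubble faults folded
    into the effective sample resistance) is read by each sensor as
    ``gain * P + offset + accuracy_offset + noise``.  Identical (cfg, seed)
    yield bit-identical streams.
    """
    up_sensor = up_sensor or SensorSpec()
    down_sensor = down_sensor or SensorSpec()
    _check_faults(faults, cfg.duration_s)

    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n, dtype=float) / cfg.sample_rate_hz
    temp = _temperature_profile(cfg, t)
    scale = env.viscosity_ratio_to_25c(temp)
    p_head = height_to_pressure(cfg.height_cm, temp, env)
    if np.any(p_head <= cfg.backpressure_kpa):
        raise DegenerateFlowError("head pressure <= backpressure: no flow")

    # fold circuit faults into an effective time-varying sample resistance
    k_sample = np.full(n, 0.0 if math.isinf(cfg.r_sample) else 1.0 / cfg.r_sample)
    r_mult = np.ones(n)
    for f in faults:
        if f.kind == "leak":
            k_sample = k_sample + f.magnitude * f.active(t)
        elif f.kind == "bubble":
            m = f.active(t)
            r_mult = np.where(m, r_mult * f.magnitude, r_mult)
    with np.errstate(divide="ignore"):
        r_sample_eff = np.where(k_sample > 0, r_mult / np.maximum(k_sample, 1e-300),
                                np.inf)
    q, p_down = _solve_series(
        p_head, cfg.backpressure_kpa, cfg.r_tubing * scale, r_sample_eff * scale
    )
    p_up = p_head

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    up_off = rng.normal(0.0, up_sensor.accuracy_sd_kpa()) \
        if up_sensor.accuracy_sd_kpa() > 0 else 0.0
    down_off = rng.normal(0.0, down_sensor.accuracy_sd_kpa()) \
        if down_sensor.accuracy_sd_kpa() > 0 else 0.0
    if _down_accuracy_offset is not None:
        down_off = _down_accuracy_offset
    read_up = up_sensor.gain * p_up + up_sensor.offset_kpa + up_off
    read_down = down_sensor.gain * p_down + down_sensor.offset_kpa + down_off
    if up_sensor.noise_sd_kpa > 0:
        read_up = read_up + rng.normal(0.0, up_sensor.noise_sd_kpa, n)
    if down_sensor.noise_sd_kpa > 0:
        read_down = read_down + rng.normal(0.0, down_sensor.noise_sd_kpa, n)
    for f in faults:
        if f.kind == "sensor_offset":
            target = read_up if f.sensor == "up" else read_down
            target += f.magnitude * f.active(t)

    m = dict(meta or {})
    m.setdefault("seed", int(seed))
    m.setdefault("height_cm", cfg.height_cm)
    m.setdefault("sample_rate_hz", cfg.sample_rate_hz)
    return SensorStream(t, read_up, read_down, temp, m)


def simulate_backpressure_phase(
    cfg: CircuitConfig,
    down_sensor: SensorSpec | None = None,
    seed: int = 0,
    duration_s: float = 60.0,
    faults: Sequence[FaultSpec] = (),
    env: EnvConstants = WATER,
    _accuracy_offset: float | None = None,
) -> np.ndarray:
    """Static downstream readings with the sample isolated by stopcocks.

    Normally the readings scatter around the true static backpressure; under
    a ``stopcock_error`` fault the sensor keeps seeing the flow-phase
    downstream pressure, which inflates the backpressure estimate and hence
    the apparent sample conductance.
    """
    down_sensor = down_sensor or SensorSpec()
    n = max(int(round(duration_s * cfg.sample_rate_hz)), 1)
    truth = cfg.backpressure_kpa
    if any(f.kind == "stopcock_error" for f in faults):
        truth = steady_state_solution(cfg, env)["P_down"]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    off = _accuracy_offset
    if off is None:
        off = rng.normal(0.0, down_sensor.accuracy_sd_kpa()) \
            if down_sensor.accuracy_sd_kpa() > 0 else 0.0
    readings = down_sensor.gain * truth + down_sensor.offset_kpa + off
    readings = np.full(n, readings, dtype=float)
    if down_sensor.noise_sd_kpa > 0:
        readings = readings + rng.normal(0.0, down_sensor.noise_sd_kpa, n)
    return readings


def simulate_measurement(
    cfg: CircuitConfig,
    up_sensor: SensorSpec | None = None,
    down_sensor: SensorSpec | None = None,
    faults: Sequence[FaultSpec] = (),
    seed: int = 0,
    env: EnvConstants = WATER,
    meta: dict | None = None,
) -> tuple[SensorStream, np.ndarray]:
    """Flow phase plus backpressure phase sharing one downstream sensor.

    The downstream sensor's accuracy offset is drawn once and applied to both
    phases, as for a real device within one measurement — which is what makes
    the backpressure correction cancel that offset in the pipeline.
    """
    down_sensor = down_sensor or SensorSpec()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    down_off = rng.normal(0.0, down_sensor.accuracy_sd_kpa()) \
        if down_sensor.accuracy_sd_kpa() > 0 else 0.0
    stream = simulate_stream(
        cfg, up_sensor, down_sensor, faults, seed, env, meta,
        _down_accuracy_offset=down_off,
    )
    phase = simulate_backpressure_phase(
        cfg, down_sensor, seed, faults=faults, env=env,
        _accuracy_offset=down_off,
    )
    return stream, phase


def simulate_calibration_series(
    heights: Iterable[float] = CALIBRATION_HEIGHTS_CM,
    sensor: SensorSpec | None = None,
    seed: int = 0,
    temperature_c: float = 25.0,
    env: EnvConstants = WATER,
) -> list[tuple[float, float]]:
    """Raw readings for a stepped-height calibration ladder.

    Raw reading = gain * true pressure + offset + accuracy offset + noise,
    in sensor units (kPa-scaled by default).
    """
    heights = list(heights)
    if len(set(heights)) < 3:
        raise ValueError("need at least 3 distinct calibration heights")
    sensor = sensor or SensorSpec()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    off = rng.normal(0.0, sensor.accuracy_sd_kpa()) \
        if sensor.accuracy_sd_kpa() > 0 else 0.0
    out = []
    for h in heights:
        p = height_to_pressure(h, temperature_c, env)
        raw = sensor.gain * p + sensor.offset_kpa + off
        if sensor.noise_sd_kpa > 0:
            raw += rng.normal(0.0, sensor.noise_sd_kpa)
        out.append((float(h), float(raw)))
    return out


def simulate_displacement_series(
    heights: Iterable[float] = DISPLACEMENT_HEIGHTS_CM,
    r_true: float = 10.0,
    temperature_c: float = 25.0,
    seed: int = 0,
    volume_ml: float = 0.5,
    elapsed_s: float | None = None,
    volume_noise_rel: float = 0.0,
    env: EnvConstants = WATER,
) -> list[tuple[float, float, float, float]]:
    """Water-displacement reference records: (height_cm, volume_mL, elapsed_s, T_C).

    ``r_true`` is the tubing resistance at 25 degC (kPa s kg^-1); the flow at
    temperature T is Q = P(height, T) / (r_true * mu(T)/mu(25)).  Either the
    displaced volume is fixed (default 0.5 mL, elapsed time derived) or a
    fixed ``elapsed_s`` is given and the volume is derived.  Pipette-reading
    noise is a relative Gaussian on the volume.
    """
    if r_true <= 0:
        raise ValueError("r_true must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    scale = float(env.viscosity_ratio_to_25c(temperature_c))
    rho = float(env.rho_fn(temperature_c))
    out = []
    for h in heights:
        p = height_to_pressure(h, temperature_c, env)
        q = p / (r_true * scale)  # kg s^-1
        if elapsed_s is None:
            vol = volume_ml
            dt = rho * vol * 1e-6 / q
        else:
            dt = elapsed_s
            vol = q * dt / (rho * 1e-6)
        if volume_noise_rel > 0:
            vol = vol * (1.0 + rng.normal(0.0, volume_noise_rel))
        out.append((float(h), float(vol), float(dt), float(temperature_c)))
    return out
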