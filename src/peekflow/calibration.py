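"""Sensor calibration from stepped-height series.

Each pressure sensor is calibrated daily by bypassing the internal PEEK
tubing and applying a ladder of known water-column heights (5-50 cm in 5 cm
steps by default).  An ordinary least-squares fit of true applied pressure on
raw sensor output yields the calibration model; the fit is accepted only if
R^2 > 0.99.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .water import WATER, EnvConstants

#: R^2 above which a calibration fit is accepted
R2_THRESHOLD = 0.99


def height_to_pressure(height_cm, temperature_c=25.0, env: EnvConstants = WATER):
    """Convert a water-column height (cm) to hydrostatic pressure (kPa).

    P = rho(T) * g * h.  1 cm of water at 25 degC is ~0.0978 kPa, i.e. the
    rule-of-thumb 0.001 bar per cm.  Accepts scalars or arrays; negative
    heights raise ValueError.
    """
    h = np.asarray(height_cm, dtype=float)
    if np.any(h < 0):
        raise ValueError("height_cm must be non-negative")
    p_kpa = env.rho_fn(temperature_c) * env.g * (h * 0.01) / 1000.0
    return p_kpa if p_kpa.ndim else float(p_kpa)


@dataclass
class CalibrationModel:
    """Affine map from raw sensor output to pressure in kPa.

    ``passed`` is True iff the calibration regression achieved R^2 > 0.99.
    """

    slope: float  # kPa per raw unit
    intercept: float  # kPa
    r_squared: float
    passed: bool

    def apply(self, raw):
        """Convert raw sensor readings to calibrated pressure (kPa)."""
        return self.slope * np.asarray(raw, dtype=float) + self.intercept


def fit_calibration(
    series: Sequence[tuple[float, float]],
    temperature_c: float = 25.0,
    env: EnvConstants = WATER,
) -> CalibrationModel:
    """Fit a calibration model from (height_cm, raw_reading) pairs.

    True pressures are computed from the heights at the given temperature and
    regressed on the raw readings, so the fitted model applies directly to
    subsequent raw streams.  Requires >= 3 points over >= 2 distinct heights
    and non-constant readings.
    """
    if len(series) < 3:
        raise ValueError("calibration needs at least 3 points")
    heights = np.array([p[0] for p in series], dtype=float)
    raw = np.array([p[1] for p in series], dtype=float)
    if np.unique(heights).size < 2:
        raise ValueError("calibration needs at least 2 distinct heights")
    if np.ptp(raw) == 0:
        raise ValueError("constant sensor readings: cannot calibrate")
    truth = height_to_pressure(heights, temperature_c, env)
    res = sps.linregress(raw, truth)
    r2 = float(res.rvalue**2)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        passed=r2 > R2_THRESHOLD,
    )


def write_calibration_report(models: dict[str, CalibrationModel], path) -> None:
    """Write one CSV row per sensor: sensor_id,slope,intercept,r2,passed."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sensor_id", "slope", "intercept", "r2", "passed"])
        for sensor_id, m in models.items():
            w.writerow([sensor_id, m.slope, m.intercept, m.r_squared, m.passed])
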