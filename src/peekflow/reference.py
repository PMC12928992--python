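"""Reference characterization of PEEK tubing.

Each tubing specimen's hydraulic resistance is determined by the water
displacement method: flow is driven through the tubing at a ladder of known
reservoir heights, the displaced volume per unit time gives the mass flow,
and resistance is the slope of a zero-intercept regression of applied
pressure on (viscosity-adjusted) flow.  Reference conductance is the inverse
of resistance.  Hagen-Poiseuille values from nominal diameters serve only as
an order-of-magnitude cross-check — manufacturing variation in diameter
(fourth-power law) makes per-specimen characterization essential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import height_to_pressure
from .water import WATER, EnvConstants

#: nominal internal diameters (mm) by PEEK tubing colour code
NOMINAL_DIAMETER_MM = {"yellow": 0.175, "blue": 0.250, "orange": 0.500}


@dataclass
class TubingSpec:
    """Identity and reference characterization of one PEEK tubing specimen."""

    tubing_id: str
    color: str
    lab: str = "DRF"
    nominal_diameter_mm: float | None = None
    length_m: float | None = None
    r_ref: float | None = None  # kPa s kg^-1, at 25 degC
    n_ref: int = 0

    def __post_init__(self):
        if self.nominal_diameter_mm is None and self.color in NOMINAL_DIAMETER_MM:
            self.nominal_diameter_mm = NOMINAL_DIAMETER_MM[self.color]

    @property
    def k_ref(self) -> float | None:
        """Reference conductance, the inverse of the reference resistance."""
        return None if self.r_ref is None else 1.0 / self.r_ref


@dataclass
class ReferenceInterval:
    """Colour- and lab-specific acceptance band: mean +/- full range.

    The full (max - min) range of the per-specimen reference conductances is
    added on both sides of their mean, a deliberately conservative band that
    absorbs displacement-measurement uncertainty.
    """

    color: str
    lab: str
    mean: float
    full_range: float

    @property
    def lower(self) -> float:
        return self.mean - self.full_range

    @property
    def upper(self) -> float:
        return self.mean + self.full_range

    def contains(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.lower) & (v <= self.upper)


def displacement_resistance(records, env: EnvConstants = WATER) -> dict:
    """Resistance at 25 degC from (height_cm, volume_mL, elapsed_s, T_C) records.

    Mass flow Q = rho(T) * volume / elapsed is viscosity-adjusted to 25 degC,
    then resistance is the slope of the zero-intercept least-squares fit of
    applied pressure on flow (using every height at once).  Per-height
    resistances are returned for diagnostics.

    Returns ``{"r_ref", "k_ref", "per_height": DataFrame}``.
    """
    records = list(records)
    if len({r[0] for r in records}) < 3:
        raise ValueError("displacement fit needs at least 3 distinct heights")
    rows = []
    for height_cm, volume_ml, elapsed_s, t_c in records:
        if volume_ml <= 0 or elapsed_s <= 0:
            raise ValueError("volume and elapsed time must be positive")
        p = height_to_pressure(height_cm, t_c, env)  # kPa
        q = float(env.rho_fn(t_c)) * volume_ml * 1e-6 / elapsed_s  # kg s^-1
        q25 = q * float(env.viscosity_ratio_to_25c(t_c))
        rows.append({
            "height_cm": height_cm, "pressure_kPa": p, "Q25_kg_s": q25,
            "R_kPa_s_kg": p / q25,
        })
    per_height = pd.DataFrame(rows)
    p_vec = per_height["pressure_kPa"].to_numpy()
    q_vec = per_height["Q25_kg_s"].to_numpy()
    r_ref = float(np.dot(p_vec, q_vec) / np.dot(q_vec, q_vec))
    return {"r_ref": r_ref, "k_ref": 1.0 / r_ref, "per_height": per_height}


def hagen_poiseuille_conductance(
    diameter_mm: float,
    length_m: float,
    temperature_c: float = 25.0,
    env: EnvConstants = WATER,
) -> float:
    """Theoretical laminar-flow conductance of a capillary, kg s^-1 kPa^-1.

    K = rho * pi * d^4 / (128 * mu(T) * L), converted from per-Pa to per-kPa.
    Scales with the fourth power of diameter, which is why nominal-diameter
    predictions overshoot observed cross-colour conductance ratios.
    """
    if diameter_mm <= 0 or length_m <= 0:
        raise ValueError("diameter and length must be positive")
    d = diameter_mm * 1e-3
    rho = float(env.rho_fn(temperature_c))
    mu = float(env.mu_fn(temperature_c))
    k_per_pa = rho * math.pi * d**4 / (128.0 * mu * length_m)
    return k_per_pa * 1000.0


def build_reference_interval(values, color: str = "", lab: str = "") -> ReferenceInterval:
    """Mean +/- full-range interval from per-specimen reference conductances.

    The interval necessarily contains every input value.  Identical inputs
    give a zero-width range, which is rejected as degenerate.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 reference values")
    full_range = float(np.max(v) - np.min(v))
    if full_range <= 0:
        raise ValueError("degenerate reference set: zero full range")
    return ReferenceInterval(color=color, lab=lab, mean=float(np.mean(v)),
                             full_range=full_range)


def range_intersection(a, b):
    """Intersection of two ordered [min, max] ranges, or None if disjoint."""
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("ranges must be ordered [min, max]")
    lo, hi = max(a_lo, b_lo), min(a_hi, b_hi)
    return (lo, hi) if lo <= hi else None
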