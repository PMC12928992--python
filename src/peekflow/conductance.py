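"""From calibrated sensor streams to QC-gated conductance measurements.

At steady state the flow through the meter's internal PEEK tubing equals the
flow through the sample, so the sample's hydraulic conductance is

    K' = Q / dP_sample = dP_tubing / (R_tubing * dP_sample)

with dP_tubing the pressure drop across the internal tubing, dP_sample the
downstream pressure minus the static backpressure, and R_tubing the tubing's
reference resistance.  K' is then normalized to 25 degC through the
viscosity ratio.  A measurement is accepted only if (i) the downstream-to-
upstream pressure ratio lies in [0.2, 0.8] (optimum 0.5), (ii) the
instantaneous conductance stayed steady (CV < 0.05) over the final 300 s,
(iii) the recording lasted at least 300 s, and (iv) the value sits below a
colour-specific plausibility threshold derived from reference values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rig import SensorStream
from .water import WATER, EnvConstants

QC_RATIO = "ratio_out_of_range"
QC_UNSTABLE = "unstable"
QC_SHORT = "too_short"
QC_OVER_COLOR = "over_color_threshold"


@dataclass
class QCThresholds:
    """Acceptance thresholds applied to every measurement.

    ``k_max_by_color`` maps (color, lab) -> upper conductance bound in
    kg s^-1 kPa^-1; values at or above the bound are rejected as physically
    implausible overestimates (leaks, stopcock errors).  The orange bound is
    lab-specific because reference conductances differ between laboratories.
    """

    ratio_min: float = 0.2
    ratio_max: float = 0.8
    cv_max: float = 0.05
    min_duration_s: float = 300.0
    k_max_by_color: dict = field(default_factory=lambda: {
        "yellow": {"DRF": 0.1, "UQAM": 0.1},
        "blue": {"DRF": 0.15, "UQAM": 0.15},
        "orange": {"DRF": 1.5, "UQAM": 1.65},
    })

    def __post_init__(self):
        if not 0 < self.ratio_min < self.ratio_max < 1:
            raise ValueError("need 0 < ratio_min < ratio_max < 1")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be > 0")

    def k_max(self, color: str, lab: str = "DRF") -> float:
        try:
            by_lab = self.k_max_by_color[color]
        except KeyError:
            raise ValueError(f"unknown tubing color {color!r}") from None
        if isinstance(by_lab, dict):
            return by_lab.get(lab, max(by_lab.values()))
        return float(by_lab)


@dataclass
class Measurement:
    """One QC-annotated conductance determination."""

    k_raw: float  # conductance at stream temperature, kg s^-1 kPa^-1
    k25: float  # viscosity-normalized conductance, kg s^-1 kPa^-1
    dp_tubing: float  # mean P_up - P_down over the window, kPa
    dp_sample: float  # mean P_down - backpressure, kPa
    ratio: float  # mean downstream/upstream pressure ratio
    backpressure_kpa: float
    cv_steady: float  # CV of instantaneous conductance, final window
    duration_s: float
    qc_flags: frozenset = frozenset()
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return not self.qc_flags


def record_duration(stream: SensorStream) -> float:
    """Recorded duration in seconds: sample count times the sample period."""
    dt = float(stream.t[1] - stream.t[0]) if stream.t.size > 1 else 1.0
    return stream.duration_s + dt


def detect_steady_state(
    stream: SensorStream,
    r_tubing: float,
    backpressure_kpa: float = 0.0,
    window_s: float = 300.0,
    cv_max: float = 0.05,
) -> dict:
    """Stability of the instantaneous conductance over the final window.

    Returns ``{"start_index", "cv_steady", "stable"}``.  The CV (SD/mean) is
    computed on the per-sample conductance
    (P_up - P_down) / (R_tubing * (P_down - backpressure)); a stream shorter
    than the window is reported unstable-by-duration (stable=False, cv=nan)
    rather than raising.
    """
    if record_duration(stream) < window_s - 1e-9:
        return {"start_index": 0, "cv_steady": math.nan, "stable": False}
    start = int(np.searchsorted(stream.t, stream.t[-1] - window_s))
    pu = stream.p_up[start:]
    pd_ = stream.p_down[start:]
    dps = pd_ - backpressure_kpa
    if np.any(dps <= 0):
        return {"start_index": start, "cv_steady": math.inf, "stable": False}
    k = (pu - pd_) / (r_tubing * dps)
    mean = float(np.mean(k))
    if mean == 0:
        return {"start_index": start, "cv_steady": math.inf, "stable": False}
    cv = float(np.std(k, ddof=1) / abs(mean)) if k.size > 1 else 0.0
    return {"start_index": start, "cv_steady": cv, "stable": cv < cv_max}


def estimate_backpressure(phase_record) -> float:
    """Mean of the stopcock-isolated downstream readings, kPa."""
    arr = np.asarray(phase_record, dtype=float)
    if arr.size == 0:
        raise ValueError("empty backpressure phase record")
    return float(np.mean(arr))


def compute_conductance(dp_tubing: float, dp_sample: float, r_tubing: float) -> float:
    """K' = dP_tubing / (R_tubing * dP_sample), kg s^-1 kPa^-1."""
    if r_tubing <= 0:
        raise ValueError("r_tubing must be > 0")
    if dp_sample <= 0:
        raise ValueError(
            "dp_sample <= 0: backpressure at or above downstream pressure (no flow)"
        )
    return dp_tubing / (r_tubing * dp_sample)


def normalize_to_25c(k_t: float, temperature_c: float, env: EnvConstants = WATER) -> float:
    """Convert a conductance at T to its 25 degC equivalent: K25 = K_T * mu(T)/mu(25)."""
    if not 0 < temperature_c < 50:
        raise ValueError("temperature outside 0-50 degC viscosity-fit validity")
    return k_t * float(env.viscosity_ratio_to_25c(temperature_c))


def qc_validate(
    m: Measurement,
    thresholds: QCThresholds | None = None,
    color: str = "blue",
    lab: str = "DRF",
) -> Measurement:
    """Return the measurement with its QC flag set populated."""
    th = thresholds or QCThresholds()
    flags = set(m.qc_flags)
    if m.duration_s < th.min_duration_s:
        flags.add(QC_SHORT)
    if not (math.isfinite(m.cv_steady) and m.cv_steady < th.cv_max):
        flags.add(QC_UNSTABLE)
    if not (th.ratio_min <= m.ratio <= th.ratio_max):
        flags.add(QC_RATIO)
    bound = th.k_max(color, lab)
    if not (math.isfinite(m.k25) and 0 < m.k25 < bound):
        flags.add(QC_OVER_COLOR)
    m.qc_flags = frozenset(flags)
    return m


def measure(
    stream: SensorStream,
    backpressure_phase,
    r_tubing: float,
    thresholds: QCThresholds | None = None,
    color: str = "blue",
    lab: str = "DRF",
    window_s: float = 300.0,
    env: EnvConstants = WATER,
) -> Measurement:
    """Full pipeline: stream + backpressure phase -> QC-annotated Measurement.

    Window statistics use arithmetic means of the pressures over the final
    steady window before applying the conductance relation, which keeps the
    per-sample noise from amplifying through the ratio.
    """
    th = thresholds or QCThresholds()
    bp = estimate_backpressure(backpressure_phase)
    temp = float(np.mean(stream.temperature_c))
    # r_tubing is the 25 degC reference; the tubing's actual resistance at
    # the stream temperature carries the same viscosity factor the final
    # normalisation removes, so scale it before applying the relation
    r_tubing_t = r_tubing * float(env.viscosity_ratio_to_25c(temp))
    ss = detect_steady_state(stream, r_tubing_t, bp, window_s, th.cv_max)
    start = ss["start_index"]
    pu = float(np.mean(stream.p_up[start:]))
    pd_ = float(np.mean(stream.p_down[start:]))
    dp_tubing = pu - pd_
    dp_sample = pd_ - bp
    ratio = float(np.mean(stream.p_down[start:] / stream.p_up[start:]))
    if dp_sample > 0:
        k_raw = compute_conductance(dp_tubing, dp_sample, r_tubing_t)
        k25 = normalize_to_25c(k_raw, temp, env)
    else:
        # backpressure >= downstream pressure: no resolvable flow; report an
        # infinite apparent conductance so the colour threshold rejects it
        k_raw = math.inf
        k25 = math.inf
    m = Measurement(
        k_raw=k_raw,
        k25=k25,
        dp_tubing=dp_tubing,
        dp_sample=dp_sample,
        ratio=ratio,
        backpressure_kpa=bp,
        cv_steady=ss["cv_steady"],
        duration_s=record_duration(stream),
        meta=dict(stream.meta, color=color, lab=lab),
    )
    return qc_validate(m, th, color, lab)


MEASUREMENT_COLUMNS = [
    "lab", "device", "tubing_internal", "tubing_sample", "color", "height_cm",
    "K25", "ratio", "cv_steady", "backpressure_kPa", "valid", "flags",
]


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Tidy one-row-per-measurement table with QC provenance."""
    rows = []
    for m in measurements:
        meta = m.meta
        rows.append({
            "lab": meta.get("lab"),
            "device": meta.get("device"),
            "tubing_internal": meta.get("tubing_internal"),
            "tubing_sample": meta.get("tubing_sample"),
            "color": meta.get("color"),
            "height_cm": meta.get("height_cm"),
            "K25": m.k25,
            "K_raw": m.k_raw,
            "ratio": m.ratio,
            "cv_steady": m.cv_steady,
            "backpressure_kPa": m.backpressure_kpa,
            "valid": m.valid,
            "flags": ";".join(sorted(m.qc_flags)),
            "K_ref": meta.get("k_ref"),
            "K_true": meta.get("k_true"),
        })
    return pd.DataFrame(rows)
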