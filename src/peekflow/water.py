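"""Temperature-dependent properties of the perfusing solution.

The driving pressure of a gravity-fed flow meter is a water-column head, and
hydraulic conductance scales inversely with dynamic viscosity, so both the
head-to-pressure conversion and the normalisation of conductance to 25 °C
need density and viscosity as functions of solution temperature.  The
perfusing solution (ultrapure water + 10 mM KCl + 1 mM CaCl2) is close enough
to pure water that pure-water correlations are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

#: standard gravitational acceleration, m s^-2
G = 9.80665

# Valid range of the property correlations, degrees C.
T_MIN_C = 0.0
T_MAX_C = 50.0


def water_density(temperature_c):
    """Density of air-free water, kg m^-3 (Kell polynomial, 0-100 degC).

    At 25 degC this evaluates to ~997.05 kg m^-3.
    """
    t = np.asarray(temperature_c, dtype=float)
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.87985e-3 * t)


def water_viscosity(temperature_c):
    """Dynamic viscosity of water, Pa s (Vogel three-parameter fit).

    mu(T) = 1e-3 * exp(A + B / (C + T_K)) with A=-3.7188, B=578.919,
    C=-137.546; good to a few tenths of a percent over 0-50 degC.
    """
    t_k = np.asarray(temperature_c, dtype=float) + 273.15
    return 1e-3 * np.exp(-3.7188 + 578.919 / (-137.546 + t_k))


@dataclass(frozen=True)
class EnvConstants:
    """Physical constants and property correlations used throughout.

    Attributes
    ----------
    g : gravitational acceleration, m s^-2.
    rho_fn : water density as a function of temperature (degC -> kg m^-3).
    mu_fn : dynamic viscosity as a function of temperature (degC -> Pa s).
    """

    g: float = G
    rho_fn: Callable = field(default=water_density)
    mu_fn: Callable = field(default=water_viscosity)

    def viscosity_ratio_to_25c(self, temperature_c):
        """mu(T) / mu(25 degC) — the factor that converts a conductance
        measured at T to its 25 degC equivalent."""
        return self.mu_fn(temperature_c) / self.mu_fn(25.0)


#: default environment (pure-water correlations, standard gravity)
WATER = EnvConstants()
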