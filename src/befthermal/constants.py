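"""Physical constants and shared unit helpers."""

import numpy as np

#: Boltzmann constant in eV/K, at the precision conventional in the
#: thermal-performance literature.
BOLTZMANN_EV = 8.62e-5

#: Offset between degrees Celsius and Kelvin.
CELSIUS_OFFSET = 273.15


def as_kelvin(temperature):
    """Coerce temperatures to Kelvin.

    Values below 200 are interpreted as degrees Celsius (no assay in this
    domain runs below -73 degC or above 200 K ambiguity range) and shifted
    by 273.15; values at or above 200 are assumed to already be Kelvin.
    Works elementwise on arrays.
    """
    t = np.asarray(temperature, dtype=float)
    out = np.where(t < 200.0, t + CELSIUS_OFFSET, t)
    if np.ndim(temperature) == 0:
        return float(out)
    return out


def as_celsius(temperature_K):
    """Convert Kelvin to degrees Celsius."""
    return np.asarray(temperature_K, dtype=float) - CELSIUS_OFFSET
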