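"""Unit conversion between unitless correction strengths and kcal/mol.

The trainable hydrogen-bond correction strengths (lambda) are unitless;
energies are reported externally as k_B*T*lambda in kcal/mol at the
simulation temperature.  Conversion happens only at I/O boundaries.
"""

from scipy.constants import R, calorie

#: Boltzmann constant in kcal/(mol K) (gas constant per mole).
KB_KCAL_PER_MOL_K = R / (1000.0 * calorie)

#: Default simulation temperature in K.
DEFAULT_TEMPERATURE = 298.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature


#: Default half-width of the box constraint, unitless: 1 kcal/mol at 298 K.
DEFAULT_LAM_MAX = 1.0 / kbt(DEFAULT_TEMPERATURE)
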