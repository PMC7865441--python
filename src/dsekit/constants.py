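"""Physical constants and the empirical coefficients of the hydrodynamic-size model."""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kcal mol-1 K-1 (energies throughout are in kcal mol-1).
R_KCAL: float = 1.9872e-3

#: Standard one-letter codes of the 20 common amino acids.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RhCoefficients:
    """Empirical coefficients of the power-law hydrodynamic-size model.

    ``rh = r_o * N**(v_o + a * ln(1 - f_ppii)) + charge_slope * |Q_net|
    + charge_intercept * sqrt(N)``

    The defaults are the calibration against hard-sphere ensemble simulations
    and a reference set of IDP hydrodynamic radii. ``charge_slope`` and
    ``charge_intercept`` are zero in the charge-free (power-law only) form of
    the model; the screening module refits them per dataset.
    """

    r_o: float = 2.16          # pre-factor, Angstrom
    v_o: float = 0.503         # scaling exponent of the unbiased coil
    a: float = -0.11           # exponent sensitivity to ln(1 - f_ppii)
    charge_slope: float = 0.26       # Angstrom per unit |Q_net|
    charge_intercept: float = -0.29  # Angstrom per sqrt(residue)


DEFAULT_COEFFS = RhCoefficients()


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15
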