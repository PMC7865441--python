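"""Three-state PPII / alpha-helix / unordered population model.

A generic unfolded polypeptide is modelled as an equilibrium between three
backbone states with the unordered state as reference. At temperature T the
PPII and helix propensities are first moved from their anchors by the
integrated van't Hoff equation, then converted to free energies

    dG_x(T) = -R T ln( p_x / (1 - p_x) )

and populations follow from the partition function
Q = 1 + exp(-dG_alpha/RT) + exp(-dG_PPII/RT):
unordered = 1/Q, alpha = exp(-dG_alpha/RT)/Q, PPII = exp(-dG_PPII/RT)/Q.

Defaults anchor the PPII propensity at 0.35 (25 C, the mean of the
calorimetric peptide scale) and the helix propensity at 0.29 (0 C, the mean of
the alanine-host helix scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .thermo import TransitionThermo, propensity_at_t

__all__ = ["ThreeStateModel", "default_model", "populations_at",
           "population_curve"]

_CLAMP = 1e-12


@dataclass(frozen=True)
class ThreeStateModel:
    """Thermodynamic description of the PPII and alpha transitions."""

    ppii: TransitionThermo
    alpha: TransitionThermo


def default_model(dh_ppii: float = 10.0, dh_alpha: float = 11.0,
                  ppii_anchor_p: float = 0.35, ppii_anchor_t: float = 298.15,
                  alpha_anchor_p: float = 0.29, alpha_anchor_t: float = 273.15
                  ) -> ThreeStateModel:
    """Generic-polypeptide model; enthalpies in kcal mol-1."""
    return ThreeStateModel(
        ppii=TransitionThermo(dh=dh_ppii, anchor_p=ppii_anchor_p,
                              anchor_t=ppii_anchor_t),
        alpha=TransitionThermo(dh=dh_alpha, anchor_p=alpha_anchor_p,
                               anchor_t=alpha_anchor_t),
    )


def _weight(thermo: TransitionThermo, temperature: float) -> float:
    """Statistical weight p/(1-p) of a state relative to unordered at T."""
    p = propensity_at_t(thermo, temperature)
    if p <= _CLAMP or p >= 1.0 - _CLAMP:
        warnings.warn(
            f"propensity at {temperature} K reached the numerical boundary; "
            f"clamped to [{_CLAMP}, {1 - _CLAMP}]", stacklevel=3)
        p = min(max(p, _CLAMP), 1.0 - _CLAMP)
    return p / (1.0 - p)


def populations_at(model: ThreeStateModel, temperature: float
                   ) -> tuple[float, float, float]:
    """(unordered, alpha, PPII) fractions at ``temperature`` (kelvin).

    The three fractions sum to 1; the unordered fraction is exactly 1/Q.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    w_alpha = _weight(model.alpha, temperature)
    w_ppii = _weight(model.ppii, temperature)
    q = 1.0 + w_alpha + w_ppii
    return 1.0 / q, w_alpha / q, w_ppii / q


def population_curve(model: ThreeStateModel, temperatures: Sequence[float]
                     ) -> list[tuple[float, float, float, float]]:
    """Rows of (T, unordered, alpha, PPII) over a temperature ladder."""
    return [(t, *populations_at(model, t)) for t in temperatures]
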