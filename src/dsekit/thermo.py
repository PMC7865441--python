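"""Van't Hoff temperature dependence of conformational propensities.

A residue's bias for a conformer (PPII, helix) is an equilibrium between the
conformer and everything else, K = (1 - p) / p in the conformer -> non-conformer
direction. Assuming a temperature-independent transition enthalpy dH, the
integrated van't Hoff equation moves that equilibrium from the temperature at
which a propensity was measured (its anchor) to any other temperature:

    ln K(T) = (dH / R) * (1 / T_anchor - 1 / T) + ln K(T_anchor)

With dH > 0 (heat absorbed leaving the conformer... i.e. the conformer is
enthalpically favoured) heating depletes the conformer. The same machinery
propagates a whole propensity scale to temperature T and predicts the
temperature dependence of the hydrodynamic radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .constants import DEFAULT_COEFFS, R_KCAL, RhCoefficients
from .rh import rh_eq2
from .scales import PropensityScale
from .sequences import SequenceRecord, f_ppii, q_net

__all__ = ["TransitionThermo", "k_deform", "propensity_at_t",
           "transition_entropy", "shift_scale", "rh_temperature_curve"]


@dataclass(frozen=True)
class TransitionThermo:
    """Two-state conformational transition pinned at an anchor temperature.

    Parameters
    ----------
    dh : float
        Transition enthalpy in kcal mol-1, in the conformer -> non-conformer
        direction (positive when the conformer is enthalpically favoured).
    anchor_p : float
        Propensity (conformer fraction) at ``anchor_t``, strictly in (0, 1).
    anchor_t : float
        Anchor temperature in kelvin.
    """

    dh: float
    anchor_p: float
    anchor_t: float

    def __post_init__(self):
        if not (0.0 < self.anchor_p < 1.0):
            raise ValueError(f"anchor propensity must be in (0, 1), got {self.anchor_p}")
        if self.anchor_t <= 0:
            raise ValueError(f"anchor temperature must be positive, got {self.anchor_t}")


def k_deform(p: float) -> float:
    """Deformation equilibrium constant K = (1 - p) / p of a propensity."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"propensity must be strictly inside (0, 1), got {p}")
    return (1.0 - p) / p


def propensity_at_t(thermo: TransitionThermo, temperature: float) -> float:
    """Propensity at ``temperature`` by the integrated van't Hoff equation.

    ``ln K(T) = (dH/R)(1/T_anchor - 1/T) + ln K(T_anchor)``; the returned
    propensity is ``1 / (1 + K(T))``. Exact at the anchor.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    ln_k = (math.log(k_deform(thermo.anchor_p))
            + (thermo.dh / R_KCAL) * (1.0 / thermo.anchor_t - 1.0 / temperature))
    return 1.0 / (1.0 + math.exp(ln_k))


def transition_entropy(thermo: TransitionThermo, temperature: float) -> float:
    """Transition entropy in cal mol-1 K-1 at ``temperature``.

    From dG(T) = -R T ln K(T) and (dG/dT)_P = -S: dS = (dH - dG) / T.
    Reported in calories (the enthalpy input stays in kcal mol-1).
    """
    p = propensity_at_t(thermo, temperature)
    dg = -R_KCAL * temperature * math.log(k_deform(p))
    return (thermo.dh - dg) / temperature * 1000.0


def shift_scale(scale: PropensityScale, dh: float | Mapping[str, float],
                temperature: float) -> PropensityScale:
    """Propagate every propensity in a scale from its anchor to ``temperature``.

    ``dh`` is a single per-residue transition enthalpy in kcal mol-1, or a
    per-amino-acid mapping. Propensities of exactly 0 or 1 have no finite
    equilibrium constant and are left fixed (a 0/1 propensity is
    temperature-insensitive in this two-state picture).
    """
    values = {}
    for code, p in scale.values.items():
        dh_i = dh[code] if isinstance(dh, Mapping) else dh
        if p <= 0.0 or p >= 1.0:
            values[code] = p
            continue
        values[code] = propensity_at_t(
            TransitionThermo(dh=dh_i, anchor_p=p, anchor_t=scale.anchor_t),
            temperature)
    return PropensityScale(name=f"{scale.name}@{temperature:g}K", values=values,
                           anchor_t=temperature, source=scale.source,
                           approx=scale.approx)


def rh_temperature_curve(record: SequenceRecord, scale: PropensityScale,
                         dh_ppii: float, temperatures: Sequence[float],
                         coeffs: RhCoefficients = DEFAULT_COEFFS
                         ) -> list[tuple[float, float]]:
    """Predicted (T, Rh) curve for a sequence.

    At each temperature the scale is shifted by the van't Hoff equation from
    its anchor, f_PPII recomputed, and Rh evaluated with the charge-corrected
    model. The net charge is held constant across temperature.
    """
    q = q_net(record)
    out = []
    for t in temperatures:
        shifted = shift_scale(scale, dh_ppii, t)
        f = f_ppii(record, shifted)
        out.append((t, rh_eq2(len(record), f, q, coeffs).rh))
    return out
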