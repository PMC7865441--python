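"""Hydrodynamic-size model for disordered chains.

The mean hydrodynamic radius of a disordered ensemble follows a power law in
chain length, Rh = Ro * N**v, with an exponent that grows logarithmically with
the chain's PPII content:

    Rh = 2.16 * N**(0.503 - 0.11 * ln(1 - f_PPII))                (power law)
    Rh = (power law) + 0.26 * |Q_net| - 0.29 * sqrt(N)            (with charge)

This module evaluates both forms, inverts them to recover f_PPII from a
measured Rh, extracts per-site PPII bias changes from mutational Rh pairs, and
fits power-law and exponent-vs-bias relationships to data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_COEFFS, RhCoefficients

__all__ = [
    "RhPrediction",
    "PowerLawFit",
    "BiasExponentFit",
    "rh_eq1",
    "rh_eq2",
    "invert_fppii",
    "per_site_delta_ppii",
    "fit_power_law",
    "fit_exponent_vs_bias",
]


@dataclass(frozen=True)
class RhPrediction:
    """A hydrodynamic-radius prediction split into its two additive terms."""

    rh: float            # Angstrom
    exponent: float      # chain-length scaling exponent actually used
    powerlaw_term: float  # Ro * N**v, Angstrom
    charge_term: float    # net-charge correction, Angstrom (0 in power-law mode)


@dataclass(frozen=True)
class PowerLawFit:
    r_o: float
    v: float
    residual_norm: float


@dataclass(frozen=True)
class BiasExponentFit:
    v_o: float
    a: float


def _check_inputs(n_residues: int, f_ppii: float) -> None:
    if n_residues < 1:
        raise ValueError(f"n_residues must be >= 1, got {n_residues}")
    if f_ppii < 0:
        raise ValueError(f"f_ppii must be non-negative, got {f_ppii}")
    if f_ppii >= 1:
        raise ValueError(
            f"f_ppii must be < 1 (log singular at 1), got {f_ppii}")


def rh_eq1(n_residues: int, f_ppii: float,
           coeffs: RhCoefficients = DEFAULT_COEFFS) -> RhPrediction:
    """Charge-free power-law prediction of Rh in Angstrom."""
    _check_inputs(n_residues, f_ppii)
    v = coeffs.v_o + coeffs.a * math.log(1.0 - f_ppii)
    rh = coeffs.r_o * n_residues ** v
    return RhPrediction(rh=rh, exponent=v, powerlaw_term=rh, charge_term=0.0)


def rh_eq2(n_residues: int, f_ppii: float, q_net: int,
           coeffs: RhCoefficients = DEFAULT_COEFFS) -> RhPrediction:
    """Power-law prediction amended for net-charge effects on size."""
    base = rh_eq1(n_residues, f_ppii, coeffs)
    charge = (coeffs.charge_slope * abs(q_net)
              + coeffs.charge_intercept * math.sqrt(n_residues))
    return RhPrediction(rh=base.rh + charge, exponent=base.exponent,
                        powerlaw_term=base.rh, charge_term=charge)


def invert_fppii(rh: float, n_residues: int, q_net: int = 0,
                 charge_corrected: bool = True,
                 coeffs: RhCoefficients = DEFAULT_COEFFS) -> float:
    """Closed-form inverse: PPII fraction implied by a measured Rh.

    With ``charge_corrected`` the net-charge terms are removed before solving
    the power law; otherwise the charge-free form is inverted (appropriate for
    mutational analyses done directly against the power-law curve).
    Round-trips with :func:`rh_eq2` / :func:`rh_eq1` to <= 1e-9.
    """
    if n_residues <= 1:
        raise ValueError("inversion needs n_residues >= 2 (ln N = 0 at N = 1)")
    powerlaw = rh
    if charge_corrected:
        powerlaw = rh - (coeffs.charge_slope * abs(q_net)
                         + coeffs.charge_intercept * math.sqrt(n_residues))
    if powerlaw <= 0:
        raise ValueError(
            f"Rh = {rh} Angstrom leaves a non-positive power-law term "
            f"({powerlaw:.3g}) after charge correction; not invertible")
    v_obs = math.log(powerlaw / coeffs.r_o) / math.log(n_residues)
    f = 1.0 - math.exp((v_obs - coeffs.v_o) / coeffs.a)
    if -1e-3 < f < 0.0:
        f = 0.0  # rounding noise in a tabulated Rh just below the coil floor
    if not (0.0 <= f < 1.0):
        raise ValueError(
            f"implied f_ppii = {f:.4g} outside [0, 1): observed exponent "
            f"{v_obs:.4g} vs zero-bias floor {coeffs.v_o}")
    return f


def per_site_delta_ppii(rh_wt: float, rh_mut: float, n_residues: int,
                        n_substituted: int, q_net_wt: int = 0,
                        q_net_mut: int = 0, charge_corrected: bool = True,
                        coeffs: RhCoefficients = DEFAULT_COEFFS) -> float:
    """Average per-site PPII bias change implied by a mutational Rh pair.

    For a variant with ``n_substituted`` positions changed (e.g. all P->G),
    the chain-level change in f_PPII is re-expressed per substituted site:
    ``(f_wt - f_mut) * N / n_substituted``.
    """
    if n_substituted < 1:
        raise ValueError("n_substituted must be >= 1")
    f_wt = invert_fppii(rh_wt, n_residues, q_net_wt, charge_corrected, coeffs)
    f_mut = invert_fppii(rh_mut, n_residues, q_net_mut, charge_corrected, coeffs)
    return (f_wt - f_mut) * n_residues / n_substituted


def fit_power_law(points: Iterable[tuple[float, float]],
                  fix_ro: float | None = None) -> PowerLawFit:
    """Nonlinear least-squares fit of Rh = Ro * N**v.

    ``fix_ro`` holds the pre-factor constant and fits only the exponent.
    Deterministic: a fixed multi-start grid (Ro in {1, 2, 4}, v in {0.4, 0.6})
    guards against local minima.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n_residues, rh) pairs")
    n, rh = pts[:, 0], pts[:, 1]
    if np.any(rh <= 0) or np.any(n < 1):
        raise ValueError("all rh must be > 0 and all n_residues >= 1")
    distinct = np.unique(n).size
    min_distinct = 2 if fix_ro is not None else 3
    if distinct < min_distinct:
        raise ValueError(
            f"need >= {min_distinct} distinct chain lengths, got {distinct}")

    logn = np.log(n)
    if fix_ro is not None:
        def resid(theta):
            return fix_ro * np.exp(theta[0] * logn) - rh
        starts = [[0.4], [0.6]]
    else:
        def resid(theta):
            return theta[0] * np.exp(theta[1] * logn) - rh
        starts = [[ro, v] for ro in (1.0, 2.0, 4.0) for v in (0.4, 0.6)]

    best = None
    for x0 in starts:
        sol = least_squares(resid, x0=x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if fix_ro is not None:
        r_o, v = fix_ro, best.x[0]
    else:
        r_o, v = best.x
    if r_o <= 0:
        raise ValueError(f"fit produced non-positive pre-factor {r_o:.3g}")
    return PowerLawFit(r_o=float(r_o), v=float(v),
                       residual_norm=float(np.linalg.norm(resid(best.x))))


def fit_exponent_vs_bias(points: Iterable[tuple[float, float]]) -> BiasExponentFit:
    """Least-squares fit of v = v_o + a * ln(1 - S_PPII).

    Linear in ln(1 - S_PPII); requires >= 2 points and at least two distinct
    sampling biases, all strictly below 1.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >= 2 (s_ppii, v) pairs")
    s, v = pts[:, 0], pts[:, 1]
    if np.any(s >= 1):
        raise ValueError("all s_ppii must be < 1 (log singular at 1)")
    x = np.log1p(-s)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all s_ppii equal, slope indeterminate")
    a, v_o = np.polyfit(x, v, 1)
    return BiasExponentFit(v_o=float(v_o), a=float(a))
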