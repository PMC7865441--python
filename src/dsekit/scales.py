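"""Amino-acid conformational propensity scales.

Ships the peptide-measured PPII propensity scales (proline-host, glycine-host
and calorimetric host--guest systems), a coil-library PPII scale, and the
alanine-host helix-formation free energies, together with the conversion
between free energy and propensity, averaging, and missing-value fill-in.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from .constants import R_KCAL, STANDARD_AA

__all__ = [
    "PropensityScale",
    "FreeEnergyScale",
    "BUILTIN_SCALE_IDS",
    "builtin_scale",
    "dg_to_propensity",
    "scale_average",
    "fill_missing",
    "load_scale_csv",
]


def _check_codes(values: Mapping[str, float]) -> None:
    bad = sorted(set(values) - set(STANDARD_AA))
    if bad:
        raise ValueError(f"non-standard amino-acid codes in scale: {bad}")


@dataclass(frozen=True)
class PropensityScale:
    """Per-amino-acid conformational propensity (equilibrium fraction).

    Parameters
    ----------
    name : str
        Short identifier of the scale.
    values : mapping of one-letter code to float
        Propensities in [0, 1]; amino acids a scale did not measure are
        simply absent.
    anchor_t : float
        Temperature in kelvin at which the propensities were measured.
    source : str
        Free-form citation label.
    approx : frozenset of str
        Codes whose stored value is an approximate reading of the original
        report rather than an exact one.
    """

    name: str
    values: Mapping[str, float]
    anchor_t: float
    source: str = ""
    approx: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        _check_codes(self.values)
        for code, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"propensity for {code} outside [0, 1]: {v}")
        if self.anchor_t <= 0:
            raise ValueError(f"anchor temperature must be positive, got {self.anchor_t}")

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def __len__(self) -> int:
        return len(self.values)

    @property
    def residues(self) -> frozenset:
        return frozenset(self.values)

    def is_complete(self) -> bool:
        return self.residues == frozenset(STANDARD_AA)


@dataclass(frozen=True)
class FreeEnergyScale:
    """Per-amino-acid free energy of conformer formation, kcal mol-1."""

    name: str
    values: Mapping[str, float]
    anchor_t: float
    source: str = ""
    approx: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        _check_codes(self.values)
        if self.anchor_t <= 0:
            raise ValueError(f"anchor temperature must be positive, got {self.anchor_t}")

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def to_propensity(self, temperature: float | None = None) -> PropensityScale:
        """Convert every free energy to a propensity at ``temperature``.

        Defaults to the scale's own anchor temperature.
        """
        t = self.anchor_t if temperature is None else temperature
        vals = {c: dg_to_propensity(g, t) for c, g in self.values.items()}
        return PropensityScale(
            name=self.name.replace("_dg", ""),
            values=vals,
            anchor_t=t,
            source=self.source,
            approx=self.approx,
        )


def dg_to_propensity(dg: float, temperature: float) -> float:
    """Propensity ``K/(1+K)`` with ``K = exp(-dg / (R*T))``.

    ``dg`` is the free energy of forming the conformer in kcal mol-1;
    the result is strictly inside (0, 1).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    k = math.exp(-dg / (R_KCAL * temperature))
    return k / (1.0 + k)


# registry: id -> (csv resource, anchor T in K, is free-energy scale, source)
_REGISTRY = {
    "creamer_ppii": ("creamer_ppii.csv", 278.15, False,
                     "PPII propensity, proline host Ac-(Pro)3-X-(Pro)3-Gly-Tyr-NH2, 5 C"),
    "kallenbach_ppii": ("kallenbach_ppii.csv", 293.15, False,
                        "PPII propensity, glycine host Ac-(Gly)2-X-(Gly)2-NH2, 20 C"),
    "hilser_ppii": ("hilser_ppii.csv", 298.15, False,
                    "PPII propensity, calorimetric SH3/Sos host-guest system, 25 C"),
    "coil_ppii": ("coil_ppii.csv", 298.15, False,
                  "PPII propensity counted in a restricted protein coil library"),
    "baldwin_alpha_dg": ("baldwin_alpha_dg.csv", 273.15, True,
                         "helix-formation free energy, alanine-rich host, 0 C"),
}

BUILTIN_SCALE_IDS = tuple(_REGISTRY) + ("baldwin_alpha",)


def _read_csv_rows(handle) -> tuple[dict, frozenset]:
    values: dict[str, float] = {}
    approx = set()
    reader = csv.DictReader(handle)
    for row in reader:
        code = row["code"].strip().upper()
        if code in values:
            raise ValueError(f"duplicate code {code} in scale CSV")
        values[code] = float(row["value"])
        if (row.get("approx") or "").strip():
            approx.add(code)
    if not values:
        raise ValueError("scale CSV contains no values")
    return values, frozenset(approx)


def load_scale_csv(path: str | Path, name: str, anchor_t: float,
                   source: str = "") -> PropensityScale:
    """Load a user propensity scale from a CSV with columns code,value[,approx]."""
    with open(path, newline="") as fh:
        values, approx = _read_csv_rows(fh)
    return PropensityScale(name=name, values=values, anchor_t=anchor_t,
                           source=source, approx=approx)


def builtin_scale(scale_id: str) -> PropensityScale | FreeEnergyScale:
    """Return a built-in scale by identifier.

    ``baldwin_alpha`` is the helix free-energy scale converted to propensities
    at its 273.15 K anchor; ``baldwin_alpha_dg`` is the free energies themselves.
    """
    if scale_id == "baldwin_alpha":
        return builtin_scale("baldwin_alpha_dg").to_propensity()
    try:
        fname, anchor_t, is_dg, source = _REGISTRY[scale_id]
    except KeyError:
        raise KeyError(
            f"unknown scale id {scale_id!r}; valid ids: {', '.join(BUILTIN_SCALE_IDS)}"
        ) from None
    ref = resources.files("dsekit.data").joinpath(fname)
    with ref.open(newline="") as fh:
        values, approx = _read_csv_rows(fh)
    cls = FreeEnergyScale if is_dg else PropensityScale
    return cls(name=scale_id, values=values, anchor_t=anchor_t,
               source=source, approx=approx)


def scale_average(scale: PropensityScale | FreeEnergyScale) -> float:
    """Arithmetic mean over the values present in the scale."""
    if len(scale.values) == 0:
        raise ValueError("cannot average an empty scale")
    return sum(scale.values.values()) / len(scale.values)


def fill_missing(scale: PropensityScale) -> PropensityScale:
    """Complete a scale to all 20 amino acids using the pre-fill average.

    Amino acids a host--guest system could not measure (aromatic CD overlap,
    host identity) are assigned the mean of the measured values, the same
    convention used when comparing incomplete peptide scales against full ones.
    Idempotent; present values are never altered.
    """
    missing = set(STANDARD_AA) - set(scale.values)
    if not missing:
        return scale
    avg = scale_average(scale)
    values = dict(scale.values)
    values.update({c: avg for c in missing})
    return replace(scale, values=values)
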