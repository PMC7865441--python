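"""Coil-library statistics: mesostates, Ramachandran basins, culling levels.

A protein coil library collects residues from solved structures that lie
outside regular secondary structure and uses them as a stand-in for the
denatured state. This module works from tabular per-residue dihedral records
(CSV with columns aa, phi, psi, ss_label, segment_id, position_in_segment,
segment_length) and provides the standard operations: 30x30-degree mesostate
indexing, basin assignment (alpha, beta, PPII, left-handed helix), the
increasingly stringent culling levels, per-amino-acid basin propensities, and
Ramachandran histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import STANDARD_AA

__all__ = [
    "ResidueRecord",
    "BasinDefinition",
    "DEFAULT_BASINS",
    "CULL_LEVELS",
    "read_records",
    "records_to_frame",
    "assign_mesostate",
    "assign_basin",
    "cull",
    "basin_propensities",
    "rama_histogram",
]

SS_LABELS = ("helix", "sheet", "turn", "coil")
CULL_LEVELS = ("full", "no_ss", "no_ss_turns", "internal_coil")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue observation from a structure set."""

    aa: str
    phi: float
    psi: float
    ss_label: str
    segment_id: str = ""
    position_in_segment: int = 0
    segment_length: int = 1

    def __post_init__(self):
        if self.aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid {self.aa!r}")
        for v in (self.phi, self.psi):
            if not (-180.0 <= v < 180.0):
                raise ValueError(f"dihedral {v} outside [-180, 180)")
        if self.ss_label not in SS_LABELS:
            raise ValueError(
                f"ss_label must be one of {SS_LABELS}, got {self.ss_label!r}")


@dataclass(frozen=True)
class BasinDefinition:
    """Axis-aligned Ramachandran basin, half-open on each axis."""

    label: str
    phi_range: tuple[float, float]
    psi_range: tuple[float, float]

    def contains(self, phi, psi):
        return ((phi >= self.phi_range[0]) & (phi < self.phi_range[1])
                & (psi >= self.psi_range[0]) & (psi < self.psi_range[1]))


#: Default basin boxes. The PPII and alpha centres follow the conventional
#: (-75, +145) and (-64, -41) locations; boxes are widened to literature-style
#: extents and must remain pairwise disjoint.
DEFAULT_BASINS = (
    BasinDefinition("ppii", (-110.0, -50.0), (110.0, 180.0)),
    BasinDefinition("alpha", (-100.0, -30.0), (-67.0, -7.0)),
    BasinDefinition("beta", (-180.0, -110.0), (110.0, 180.0)),
    BasinDefinition("alpha_L", (30.0, 100.0), (0.0, 80.0)),
)


def _check_disjoint(basins: Sequence[BasinDefinition]) -> None:
    for i, a in enumerate(basins):
        for b in basins[i + 1:]:
            if (a.phi_range[0] < b.phi_range[1] and b.phi_range[0] < a.phi_range[1]
                    and a.psi_range[0] < b.psi_range[1]
                    and b.psi_range[0] < a.psi_range[1]):
                raise ValueError(f"basins {a.label!r} and {b.label!r} overlap")


def read_records(path: str | Path) -> list[ResidueRecord]:
    """Load residue records from the CSV schema used throughout this module."""
    df = pd.read_csv(path)
    required = {"aa", "phi", "psi", "ss_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(ResidueRecord(
            aa=str(row.aa), phi=float(row.phi), psi=float(row.psi),
            ss_label=str(row.ss_label),
            segment_id=str(getattr(row, "segment_id", "")),
            position_in_segment=int(getattr(row, "position_in_segment", 0)),
            segment_length=int(getattr(row, "segment_length", 1))))
    return out


def records_to_frame(records: Iterable[ResidueRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def assign_mesostate(phi: float, psi: float) -> int:
    """Index of the 30x30-degree mesostate bin, 0..143.

    The origin bin starts at (-180, -180); the index runs row-major in phi:
    ``floor((phi+180)/30) + 12*floor((psi+180)/30)``.
    """
    if not (-180.0 <= phi < 180.0 and -180.0 <= psi < 180.0):
        raise ValueError(f"dihedrals ({phi}, {psi}) outside [-180, 180)")
    return int((phi + 180.0) // 30.0) + 12 * int((psi + 180.0) // 30.0)


def assign_basin(phi: float, psi: float,
                 basins: Sequence[BasinDefinition] = DEFAULT_BASINS) -> str:
    """Label of the basin containing (phi, psi), or ``"other"``."""
    _check_disjoint(basins)
    for basin in basins:
        if basin.contains(phi, psi):
            return basin.label
    return "other"


def cull(records: Sequence[ResidueRecord], level: str) -> list[ResidueRecord]:
    """Apply one of the increasingly stringent coil-library culls.

    ``full``
        everything except segment-terminal residues (position 0 or last);
    ``no_ss``
        additionally drops helix- and sheet-assigned residues;
    ``no_ss_turns``
        additionally drops hydrogen-bonded turns;
    ``internal_coil``
        additionally keeps only residues internal to contiguous coil
        stretches of four residues or more.

    Each level's output is a subset of the previous one. Records without a
    ``segment_id`` are treated as unannotated: they survive the first three
    levels but raise at ``internal_coil``, which needs segment positions.
    """
    if level not in CULL_LEVELS:
        raise ValueError(f"level must be one of {CULL_LEVELS}, got {level!r}")

    def is_terminal(r: ResidueRecord) -> bool:
        if not r.segment_id:
            return False
        return (r.position_in_segment == 0
                or r.position_in_segment == r.segment_length - 1)

    out = [r for r in records if not is_terminal(r)]
    if level == "full":
        return out
    out = [r for r in out if r.ss_label not in ("helix", "sheet")]
    if level == "no_ss":
        return out
    out = [r for r in out if r.ss_label != "turn"]
    if level == "no_ss_turns":
        return out
    for r in out:
        if not r.segment_id:
            raise ValueError(
                "internal_coil culling requires segment annotations "
                f"(unannotated record for {r.aa} at ({r.phi}, {r.psi}))")
    return [r for r in out if r.segment_length >= 4]


def basin_propensities(records: Sequence[ResidueRecord],
                       basins: Sequence[BasinDefinition] = DEFAULT_BASINS
                       ) -> pd.DataFrame:
    """Per-amino-acid fraction of records falling in each basin.

    Returns a DataFrame indexed by amino acid with one column per basin plus
    ``other``; rows sum to 1. Amino acids without records are absent rather
    than reported as zero.
    """
    _check_disjoint(basins)
    if not records:
        cols = [b.label for b in basins] + ["other", "n"]
        return pd.DataFrame(columns=cols)
    df = records_to_frame(records)
    labels = [b.label for b in basins]
    assigned = np.full(len(df), "other", dtype=object)
    for basin in basins:
        inside = basin.contains(df["phi"].to_numpy(), df["psi"].to_numpy())
        assigned[inside] = basin.label
    df = df.assign(basin=assigned)
    counts = (df.groupby("aa")["basin"].value_counts().unstack(fill_value=0)
              .reindex(columns=labels + ["other"], fill_value=0))
    n = counts.sum(axis=1)
    props = counts.div(n, axis=0)
    props["n"] = n
    return props


def rama_histogram(records: Sequence[ResidueRecord],
                   bin_deg: float = 10.0) -> np.ndarray:
    """2-D count grid over the Ramachandran plane.

    Grid shape is (360/bin, 360/bin) with phi as the first axis, starting at
    (-180, -180); the total count equals the number of records.
    """
    if 360.0 % bin_deg != 0:
        raise ValueError(f"bin width {bin_deg} does not divide 360")
    n = int(round(360.0 / bin_deg))
    grid = np.zeros((n, n), dtype=int)
    for r in records:
        i = int((r.phi + 180.0) // bin_deg)
        j = int((r.psi + 180.0) // bin_deg)
        grid[i, j] += 1
    return grid
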