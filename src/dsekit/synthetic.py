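"""Synthetic fixtures: IDP hydrodynamic-radius datasets and dihedral records.

The experimental inputs of the analyses here (curated IDP Rh tables, protein
coil libraries) are external datasets; these generators emulate them with
known ground truth so every stage of the pipeline can be exercised and
parameter recovery can be tested quantitatively.

The Rh generator draws IDP-like sequences (composition enriched in charged
and hydrophilic residues, depleted in aromatics and branched hydrophobics)
and produces radii from the charge-corrected power-law model under a known
"true" propensity scale plus Gaussian noise. The dihedral generator draws
(phi, psi) from prescribed basin weights for coil-library statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coil import DEFAULT_BASINS, BasinDefinition, ResidueRecord
from .constants import STANDARD_AA
from .rh import rh_eq1
from .scales import PropensityScale, fill_missing
from .screening import RhDataset
from .sequences import SequenceRecord, f_ppii, q_net

__all__ = ["SyntheticTruth", "DEFAULT_IDP_COMPOSITION",
           "generate_idp_dataset", "generate_dihedral_records"]

#: Per-amino-acid frequencies of the synthetic IDP sequences: enriched in
#: D/E/K/R/S/P/Q/G, depleted in W/C/F/I, loosely reflecting the hydrophilic,
#: aromatic-poor composition of disordered regions. Sums to 1.
DEFAULT_IDP_COMPOSITION: Mapping[str, float] = {
    "A": 0.060, "C": 0.005, "D": 0.080, "E": 0.110, "F": 0.010,
    "G": 0.090, "H": 0.020, "I": 0.015, "K": 0.090, "L": 0.040,
    "M": 0.015, "N": 0.040, "P": 0.090, "Q": 0.070, "R": 0.060,
    "S": 0.110, "T": 0.050, "V": 0.030, "W": 0.005, "Y": 0.010,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative ground truth of a synthetic Rh dataset."""

    true_scale: PropensityScale
    charge_slope: float = 0.26       # Angstrom per unit |Q_net|
    charge_intercept: float = -0.29  # Angstrom per sqrt(residue)
    noise_sd: float = 0.5            # Angstrom
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_idp_dataset(n_proteins: int = 34,
                         length_range: tuple[int, int] = (50, 200),
                         composition: Mapping[str, float] | None = None,
                         truth: SyntheticTruth | None = None,
                         temperature: float = 298.15,
                         ) -> tuple[RhDataset, SyntheticTruth]:
    """Synthetic IDP dataset with radii from the charge-corrected model.

    Sequences are i.i.d. draws from ``composition``; each radius is
    ``powerlaw(N, f_PPII | true_scale) + charge_slope*|Q_net|
    + charge_intercept*sqrt(N) + Normal(0, noise_sd)``.
    Returns the dataset together with the truth that generated it.
    """
    if truth is None:
        from .scales import builtin_scale
        truth = SyntheticTruth(true_scale=builtin_scale("hilser_ppii"))
    if composition is None:
        composition = DEFAULT_IDP_COMPOSITION
    codes = sorted(composition)
    probs = np.array([composition[c] for c in codes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {probs.sum():.6f}, not 1")
    if (probs < 0).any():
        raise ValueError("composition frequencies must be non-negative")
    bad = set(codes) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard codes in composition: {sorted(bad)}")
    lo, hi = length_range
    if lo < 10 or hi < lo:
        raise ValueError("length_range must satisfy 10 <= lo <= hi")

    rng = np.random.default_rng(truth.seed)
    scale = fill_missing(truth.true_scale)
    ids, seqs, rhs, temps = [], [], [], []
    for k in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(codes, size=n, p=probs))
        rec = SequenceRecord(id=f"synthetic_idp_{k}", residues=seq)
        rh = (rh_eq1(n, f_ppii(rec, scale)).rh
              + truth.charge_slope * abs(q_net(rec))
              + truth.charge_intercept * np.sqrt(n)
              + rng.normal(0.0, truth.noise_sd))
        ids.append(rec.id)
        seqs.append(seq)
        rhs.append(float(rh))
        temps.append(temperature)
    dataset = RhDataset(ids=tuple(ids), sequences=tuple(seqs),
                        rh_exp=tuple(rhs), temperatures=tuple(temps))
    return dataset, truth


def generate_dihedral_records(n_records: int,
                              basin_weights: Mapping[str, float],
                              ss_profile: Mapping[str, float] | None = None,
                              seed: int = 0,
                              basins: Sequence[BasinDefinition] = DEFAULT_BASINS,
                              ) -> list[ResidueRecord]:
    """Residue records with dihedrals drawn from prescribed basin weights.

    ``basin_weights`` maps basin labels (plus optionally ``"other"``) to
    fractions summing to 1; dihedrals are uniform within the chosen basin box,
    or uniform over the complement of all boxes for ``"other"``. Amino acids
    are drawn uniformly; secondary-structure labels follow ``ss_profile``
    (all-coil by default). Records are grouped into segments of six for the
    culling operations.
    """
    weights = dict(basin_weights)
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"basin weights sum to {total:.6f}, not 1")
    by_label = {b.label: b for b in basins}
    unknown = set(weights) - set(by_label) - {"other"}
    if unknown:
        raise ValueError(f"unknown basin labels: {sorted(unknown)}")
    if ss_profile is None:
        ss_profile = {"coil": 1.0}
    ss_labels = sorted(ss_profile)
    ss_probs = np.array([ss_profile[s] for s in ss_labels], dtype=float)
    if abs(ss_probs.sum() - 1.0) > 1e-9:
        raise ValueError("ss_profile fractions must sum to 1")

    rng = np.random.default_rng(seed)
    labels = sorted(weights)
    probs = np.array([weights[l] for l in labels])
    seg_len = 6
    out = []
    for k in range(n_records):
        label = labels[rng.choice(len(labels), p=probs)]
        if label == "other":
            while True:
                phi = rng.uniform(-180.0, 180.0)
                psi = rng.uniform(-180.0, 180.0)
                if not any(b.contains(phi, psi) for b in basins):
                    break
        else:
            box = by_label[label]
            phi = rng.uniform(*box.phi_range)
            psi = rng.uniform(*box.psi_range)
        out.append(ResidueRecord(
            aa=STANDARD_AA[rng.integers(0, 20)],
            phi=float(min(phi, np.nextafter(180.0, -180.0))),
            psi=float(min(psi, np.nextafter(180.0, -180.0))),
            ss_label=ss_labels[rng.choice(len(ss_labels), p=ss_probs)],
            segment_id=f"seg{k // seg_len}",
            position_in_segment=k % seg_len,
            segment_length=min(seg_len, n_records - seg_len * (k // seg_len)),
        ))
    return out
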