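"""Sequence input and the two sequence covariates of the size model.

The hydrodynamic-size model needs exactly three things from a sequence: its
length N, its mean PPII propensity f_PPII under some scale, and its net charge
Q_net counted as (#K + #R) - (#D + #E). Histidine and the chain termini are
ignored in the charge count.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

from Bio import SeqIO

from .constants import STANDARD_AA
from .scales import PropensityScale, scale_average

__all__ = ["SequenceRecord", "ChainFeatures", "read_fasta", "f_ppii", "q_net",
           "chain_features"]

_AMBIGUOUS = set("BZXUO")


@dataclass(frozen=True)
class SequenceRecord:
    """A named, validated protein sequence (uppercase one-letter codes)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ChainFeatures:
    """Sequence-derived covariates: length, mean PPII propensity, net charge."""

    n_residues: int
    f_ppii: float
    q_net: int

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if not (0.0 <= self.f_ppii <= 1.0):
            raise ValueError(f"f_ppii outside [0, 1]: {self.f_ppii}")


def _validate_residues(rec_id: str, seq: str, permissive: bool) -> str:
    seq = seq.upper()
    for pos, aa in enumerate(seq, start=1):
        if aa in STANDARD_AA:
            continue
        if permissive and aa in _AMBIGUOUS:
            continue
        raise ValueError(
            f"record {rec_id!r}: non-standard residue {aa!r} at position {pos}"
        )
    return seq


def read_fasta(source: str | Path | TextIO, permissive: bool = False) -> list[SequenceRecord]:
    """Parse FASTA into validated :class:`SequenceRecord` objects.

    Sequences are uppercased and record order is preserved. Non-standard codes
    (B, Z, X, U, O) are rejected unless ``permissive`` is set, in which case
    they survive validation and are substituted by the scale average inside
    :func:`f_ppii` (with a warning); silent substitution would bias f_PPII.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_fasta(fh, permissive=permissive)
    text = source.read()
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty FASTA input")
    if not stripped.startswith(">"):
        raise ValueError("FASTA input has sequence data before the first header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r}: header with no sequence")
        records.append(SequenceRecord(id=rec.id, residues=_validate_residues(rec.id, seq, permissive)))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def f_ppii(record: SequenceRecord, scale: PropensityScale) -> float:
    """Mean per-residue PPII propensity of the sequence under ``scale``.

    Every residue must be present in the scale (use ``fill_missing`` first for
    incomplete scales). Ambiguity codes that survived permissive parsing are
    mapped to the scale average, with a warning.
    """
    total = 0.0
    avg = None
    for pos, aa in enumerate(record.residues, start=1):
        if aa in scale:
            total += scale[aa]
        elif aa in _AMBIGUOUS:
            if avg is None:
                avg = scale_average(scale)
                warnings.warn(
                    f"record {record.id!r}: ambiguous residue(s) mapped to the "
                    f"scale average {avg:.3f}", stacklevel=2)
            total += avg
        else:
            raise KeyError(
                f"record {record.id!r}: residue {aa!r} at position {pos} "
                f"absent from scale {scale.name!r}")
    return total / len(record)


def q_net(record: SequenceRecord) -> int:
    """Net charge counted as (#K + #R) - (#D + #E); His and termini ignored."""
    s = record.residues
    return s.count("K") + s.count("R") - s.count("D") - s.count("E")


def chain_features(record: SequenceRecord, scale: PropensityScale) -> ChainFeatures:
    """Bundle the three covariates used by the size model."""
    return ChainFeatures(n_residues=len(record), f_ppii=f_ppii(record, scale),
                         q_net=q_net(record))
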