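"""Random-scale screening against a hydrodynamic-radius dataset.

The screening asks how much information a set of experimental IDP radii
carries about the per-amino-acid PPII propensities: candidate scales (usually
random ones) are scored by (i) how well the charge-free power-law model
predicts Rh from sequence under that scale, and (ii) how strongly the
size-normalized prediction error trends with size-normalized net charge.
The error-vs-charge regression also hands each scale its own empirical charge
correction (generalizing the published 0.26/-0.29 coefficients); scales that
pass both correlation thresholds and land below the mode of the corrected
error histogram are the "best" set, whose per-amino-acid mean is the
consensus scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_COEFFS, STANDARD_AA, RhCoefficients
from .scales import PropensityScale, fill_missing
from .sequences import SequenceRecord, q_net

__all__ = [
    "RhDataset",
    "ScaleMetrics",
    "ScreeningResult",
    "random_scale",
    "evaluate_scale",
    "select_best",
    "consensus",
    "run_screening",
]


@dataclass(frozen=True)
class RhDataset:
    """Experimental or synthetic (id, sequence, Rh, temperature) table."""

    ids: tuple
    sequences: tuple
    rh_exp: tuple          # Angstrom
    temperatures: tuple    # kelvin

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.sequences) == len(self.rh_exp)
                == len(self.temperatures) == n):
            raise ValueError("dataset columns must have equal length")
        for rh in self.rh_exp:
            if rh <= 0:
                raise ValueError(f"non-positive Rh {rh}")
        for seq in self.sequences:
            SequenceRecord(id="x", residues=seq)  # validates non-empty
            bad = set(seq) - set(STANDARD_AA)
            if bad:
                raise ValueError(f"non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RhDataset":
        required = {"id", "sequence", "rh_A", "temp_K"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        return cls(ids=tuple(df["id"].astype(str)),
                   sequences=tuple(df["sequence"].astype(str).str.upper()),
                   rh_exp=tuple(df["rh_A"].astype(float)),
                   temperatures=tuple(df["temp_K"].astype(float)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RhDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sequence": self.sequences,
                             "rh_A": self.rh_exp, "temp_K": self.temperatures})


@dataclass(frozen=True)
class ScaleMetrics:
    """Fit statistics of one candidate scale against a dataset.

    ``slope`` and ``intercept`` are reported in the orientation of the
    charge-corrected model, rh = powerlaw + slope*|Q_net| + intercept*sqrt(N),
    so a dataset generated with coefficients (0.26, -0.29) is recovered as
    slope = 0.26, intercept = -0.29.
    """

    r2_pred: float
    slope: float
    intercept: float
    r2_charge: float
    mean_abs_err: float


@dataclass(frozen=True)
class ScreeningResult:
    n_scales: int
    metrics: tuple
    best_mask: np.ndarray
    consensus: PropensityScale | None
    consensus_sd: dict | None


def random_scale(rng: np.random.Generator, name: str = "random",
                 anchor_t: float = 298.15) -> PropensityScale:
    """A scale with 20 independent uniform [0, 1] propensities."""
    values = dict(zip(STANDARD_AA, rng.random(20)))
    return PropensityScale(name=name, values=values, anchor_t=anchor_t)


# ---------------------------------------------------------------------------
# vectorized evaluation

def _dataset_arrays(dataset: RhDataset):
    """(counts (P,20), N, |Q|, rh_exp) arrays for vectorized evaluation."""
    p = len(dataset)
    counts = np.zeros((p, 20))
    aa_index = {aa: k for k, aa in enumerate(STANDARD_AA)}
    for i, seq in enumerate(dataset.sequences):
        for aa in seq:
            counts[i, aa_index[aa]] += 1
    n = counts.sum(axis=1)
    abs_q = np.array([abs(q_net(SequenceRecord(id=i, residues=s)))
                      for i, s in zip(dataset.ids, dataset.sequences)], float)
    return counts, n, abs_q, np.asarray(dataset.rh_exp, float)


def _scale_vector(scale: PropensityScale) -> np.ndarray:
    scale = fill_missing(scale)
    return np.array([scale[aa] for aa in STANDARD_AA])


def _evaluate_matrix(scale_matrix: np.ndarray, counts, n, abs_q, rh_exp,
                     coeffs: RhCoefficients):
    """Metrics for many scales at once; scale_matrix is (S, 20)."""
    f = (scale_matrix @ counts.T) / n        # (S, P)
    exponent = coeffs.v_o + coeffs.a * np.log1p(-f)
    pred = coeffs.r_o * np.exp(exponent * np.log(n))
    sqrt_n = np.sqrt(n)
    x = abs_q / sqrt_n                       # (P,)
    y = (pred - rh_exp) / sqrt_n             # (S, P)

    if rh_exp.std() == 0:
        raise ValueError("degenerate dataset: experimental Rh is constant")

    # r2 of prediction vs experiment, per scale
    pc = pred - pred.mean(axis=1, keepdims=True)
    ec = rh_exp - rh_exp.mean()
    denom = np.sqrt((pc ** 2).sum(axis=1) * (ec ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_pred = np.where(denom > 0, (pc * ec).sum(axis=1) / denom, 0.0)
    r2_pred = r_pred ** 2

    # OLS of y on x, per scale
    var_x = x.var()
    if var_x > 0:
        xc = x - x.mean()
        m = (y * xc).sum(axis=1) / (xc ** 2).sum()
        b = y.mean(axis=1) - m * x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((yc ** 2).sum(axis=1) * (xc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r_chg = np.where(denom > 0, (yc * xc).sum(axis=1) / denom, 0.0)
        r2_charge = r_chg ** 2
    else:
        m = np.zeros(scale_matrix.shape[0])
        b = y.mean(axis=1)
        r2_charge = np.zeros(scale_matrix.shape[0])

    corrected = pred - np.outer(m, x * sqrt_n) - np.outer(b, sqrt_n)
    mae = np.abs(corrected - rh_exp).mean(axis=1)
    return r2_pred, -m, -b, r2_charge, mae


def evaluate_scale(scale: PropensityScale, dataset: RhDataset,
                   coeffs: RhCoefficients = DEFAULT_COEFFS) -> ScaleMetrics:
    """Score one scale against a dataset.

    Predicts Rh by the charge-free power law with the scale's f_PPII,
    regresses the size-normalized error (pred - exp)/sqrt(N) on the
    size-normalized charge |Q_net|/sqrt(N), and reports the corrected mean
    absolute error. Needs at least three entries.
    """
    if len(dataset) < 3:
        raise ValueError("need >= 3 dataset entries for the regressions")
    counts, n, abs_q, rh_exp = _dataset_arrays(dataset)
    r2p, slope, intercept, r2c, mae = _evaluate_matrix(
        _scale_vector(scale)[None, :], counts, n, abs_q, rh_exp, coeffs)
    return ScaleMetrics(r2_pred=float(r2p[0]), slope=float(slope[0]),
                        intercept=float(intercept[0]),
                        r2_charge=float(r2c[0]), mean_abs_err=float(mae[0]))


def select_best(metrics: Sequence[ScaleMetrics], r2_pred_min: float = 0.7,
                r2_charge_min: float = 0.4, err_bin: float = 0.1
                ) -> np.ndarray:
    """Flags for the "best" scales.

    A scale qualifies when r2_pred > ``r2_pred_min``, r2_charge >
    ``r2_charge_min``, and its corrected error lies below the mode of the
    error histogram of the threshold-passing subset (fixed ``err_bin``-wide
    bins anchored at zero; the mode is estimated as the centre of the most
    populated bin, ties broken toward the lower bin).
    """
    if len(metrics) == 0:
        raise ValueError("no metrics supplied")
    r2p = np.array([m.r2_pred for m in metrics])
    r2c = np.array([m.r2_charge for m in metrics])
    err = np.array([m.mean_abs_err for m in metrics])
    passing = (r2p > r2_pred_min) & (r2c > r2_charge_min)
    if not passing.any():
        warnings.warn("no scale passes the correlation thresholds",
                      stacklevel=2)
        return passing
    bins = np.floor(err[passing] / err_bin).astype(int)
    counts = np.bincount(bins)
    mode_value = (counts.argmax() + 0.5) * err_bin
    return passing & (err < mode_value)


def consensus(scales: Sequence[PropensityScale], mask: np.ndarray,
              rank_constraint: Sequence[str] | None = None
              ) -> tuple[PropensityScale, dict]:
    """Per-amino-acid mean (and sd) over the selected scales.

    ``rank_constraint`` is an ordered amino-acid list (highest propensity
    first); only selected scales whose values are non-increasing along it
    contribute.
    """
    mask = np.asarray(mask, dtype=bool)
    selected = [s for s, keep in zip(scales, mask) if keep]
    if not selected:
        raise ValueError("empty selection: no scales to average")
    if rank_constraint:
        bad = [aa for aa in rank_constraint if aa not in STANDARD_AA]
        if bad:
            raise ValueError(f"unknown amino acids in rank constraint: {bad}")

        def respects(s: PropensityScale) -> bool:
            vals = [s[aa] for aa in rank_constraint]
            return all(a >= b for a, b in zip(vals, vals[1:]))

        selected = [s for s in selected if respects(s)]
        if not selected:
            raise ValueError("no selected scale respects the rank constraint")
    matrix = np.array([_scale_vector(s) for s in selected])
    mean = dict(zip(STANDARD_AA, matrix.mean(axis=0)))
    sd = dict(zip(STANDARD_AA, matrix.std(axis=0)))
    anchor = selected[0].anchor_t
    return (PropensityScale(name="consensus", values=mean, anchor_t=anchor,
                            source=f"mean of {len(selected)} selected scales"),
            sd)


def run_screening(n_scales: int, dataset: RhDataset, seed: int,
                  r2_pred_min: float = 0.7, r2_charge_min: float = 0.4,
                  rank_constraint: Sequence[str] | None = None,
                  coeffs: RhCoefficients = DEFAULT_COEFFS) -> ScreeningResult:
    """Draw ``n_scales`` random scales, score, select, and average them.

    Deterministic given ``seed``. The consensus is None (with a warning) when
    no scale qualifies.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if len(dataset) < 3:
        raise ValueError("need >= 3 dataset entries for the regressions")
    rng = np.random.default_rng(seed)
    scale_matrix = rng.random((n_scales, 20))
    scales = [PropensityScale(name=f"random_{k}",
                              values=dict(zip(STANDARD_AA, row)),
                              anchor_t=298.15)
              for k, row in enumerate(scale_matrix)]
    counts, n, abs_q, rh_exp = _dataset_arrays(dataset)
    r2p, slope, intercept, r2c, mae = _evaluate_matrix(
        scale_matrix, counts, n, abs_q, rh_exp, coeffs)
    metrics = tuple(ScaleMetrics(float(a), float(b), float(c), float(d),
                                 float(e))
                    for a, b, c, d, e in zip(r2p, slope, intercept, r2c, mae))
    mask = select_best(metrics, r2_pred_min, r2_charge_min)
    if mask.any():
        try:
            cons, sd = consensus(scales, mask, rank_constraint)
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
            cons, sd = None, None
    else:
        cons, sd = None, None
    return ScreeningResult(n_scales=n_scales, metrics=metrics, best_mask=mask,
                           consensus=cons, consensus_sd=sd)
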