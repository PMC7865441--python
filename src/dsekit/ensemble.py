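"""Hard-sphere-collision conformer ensembles with PPII/alpha sampling biases.

Chains are built residue by residue from standard bond lengths and angles and
randomly drawn backbone dihedrals (phi, psi, omega). Each residue carries the
backbone atoms N, CA, C, O, a CB pseudo-side-chain (absent in glycine), the
alpha hydrogen, and the amide hydrogen (absent in proline and at the
N-terminus). Hard-sphere contact limits are the only scoring function: a drawn
chain is rejected outright if any pair of atoms that can move relative to each
other falls inside its limit, and accepted states are weighted uniformly.

Steric model. Pairs separated by more than three covalent bonds are scored
with the classic "normal" contact limits; 1-4 pairs (three bonds apart), whose
approach is governed by torsional strain rather than pure van der Waals
contact, use a relaxed table; pairs whose distance is fixed by the covalent
geometry and the peptide-bond torsion omega are not scored at all. Amide
hydrogens facing carbonyl oxygens are capped at the hydrogen-bond approach
distance (1.8 A) so that backbone hydrogen bonds - e.g. the O(i)..H(i+4)
contact of 2.17 A in an ideal alpha helix - are not treated as clashes. With
these defaults a random alanine tripeptide (all dihedrals uniform) is accepted
about 2% of the time, and the allowed map shows the familiar beta/PPII,
alpha-R and alpha-L islands.

A sampling bias places a residue's (phi, psi) inside the PPII window
(-75 +/- 10, +145 +/- 10) with probability ``s_ppii``, inside the alpha window
(-64 +/- 10, -41 +/- 10) with probability ``s_alpha``, and otherwise uniformly
over the sterically allowed Ramachandran region outside both windows
(precomputed on a 5-degree grid for a blocked central residue). The ensemble
size statistic is L, the maximum CA-CA distance of a state; <L>/2 approximates
the mean hydrodynamic radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BackboneGeometry",
    "DihedralWindow",
    "SimConfig",
    "Conformer",
    "EnsembleSummary",
    "DEFAULT_CONTACT_LIMITS",
    "DEFAULT_CONTACT_LIMITS_14",
    "PPII_WINDOW",
    "ALPHA_WINDOW",
    "build_chain",
    "clash_check",
    "rama_allowed_mask",
    "tripeptide_allowed",
    "allowed_fraction",
    "sample_conformer",
    "run_ensemble",
]


def _pair(a: str, b: str) -> frozenset:
    return frozenset({a, b})


#: Classic "normal" hard-sphere contact limits (Angstrom) for pairs more than
#: three covalent bonds apart.
DEFAULT_CONTACT_LIMITS: Mapping[frozenset, float] = {
    _pair("C", "C"): 3.20,
    _pair("C", "N"): 2.90,
    _pair("C", "O"): 2.80,
    _pair("N", "N"): 2.70,
    _pair("N", "O"): 2.70,
    _pair("O", "O"): 2.70,
    _pair("C", "H"): 2.40,
    # between the classic normal (2.40) and outer (2.20) values: the normal
    # limit scores the rigid amide H against the preceding backbone N at
    # psi > -36 deg, walling off the upper quarter of the alpha-helix basin
    _pair("N", "H"): 2.30,
    _pair("O", "H"): 2.40,
    _pair("H", "H"): 2.00,
}

#: Relaxed limits for 1-4 pairs (exactly three bonds apart).
DEFAULT_CONTACT_LIMITS_14: Mapping[frozenset, float] = {
    _pair("C", "C"): 2.90,
    _pair("C", "N"): 2.80,
    _pair("C", "O"): 2.70,
    _pair("N", "N"): 2.60,
    _pair("N", "O"): 2.60,
    _pair("O", "O"): 2.60,
    _pair("C", "H"): 2.20,
    _pair("N", "H"): 2.20,
    _pair("O", "H"): 2.20,
    _pair("H", "H"): 1.90,
}

_ELEMENTS = ("C", "N", "O", "H")
_ATOM_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
                 "HA": "H", "H": "H"}


@dataclass(frozen=True)
class BackboneGeometry:
    """Standard backbone covalent geometry (Angstrom, degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.521
    n_h: float = 1.00
    ca_ha: float = 1.09
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.6
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_n_ca_cb: float = 110.4
    ang_c_n_h: float = 119.0
    ang_n_ca_ha: float = 109.0
    #: improper torsion C-N-CA-CB fixing the L-configuration of the side chain
    tor_c_n_ca_cb: float = -122.6
    tor_c_n_ca_ha: float = 118.3


@dataclass(frozen=True)
class DihedralWindow:
    """An axis-aligned (phi, psi) box in degrees, half-open on each axis."""

    phi_min: float
    phi_max: float
    psi_min: float
    psi_max: float

    def __post_init__(self):
        for v in (self.phi_min, self.phi_max, self.psi_min, self.psi_max):
            if not (-180.0 <= v <= 180.0):
                raise ValueError(f"window bound {v} outside [-180, 180]")
        if self.phi_min >= self.phi_max or self.psi_min >= self.psi_max:
            raise ValueError("window bounds must be increasing")

    def contains(self, phi, psi):
        return ((phi >= self.phi_min) & (phi < self.phi_max)
                & (psi >= self.psi_min) & (psi < self.psi_max))

    def sample(self, rng: np.random.Generator, size: int):
        phi = rng.uniform(self.phi_min, self.phi_max, size)
        psi = rng.uniform(self.psi_min, self.psi_max, size)
        return phi, psi


PPII_WINDOW = DihedralWindow(-85.0, -65.0, 135.0, 155.0)
ALPHA_WINDOW = DihedralWindow(-74.0, -54.0, -51.0, -31.0)


@dataclass(frozen=True)
class SimConfig:
    """Sampling biases, steric tables and geometry of a simulation run."""

    s_ppii: float = 0.0
    s_alpha: float = 0.0
    ppii_window: DihedralWindow = PPII_WINDOW
    alpha_window: DihedralWindow = ALPHA_WINDOW
    cis_pro_rate: float = 0.06
    radii: Mapping[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_LIMITS))
    radii_14: Mapping[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_LIMITS_14))
    hbond_limit: float = 1.80
    geometry: BackboneGeometry = BackboneGeometry()
    seed: int | None = None
    max_rejections: int = 200_000
    grid_deg: float = 5.0

    def __post_init__(self):
        if not (0.0 <= self.s_ppii <= 1.0 and 0.0 <= self.s_alpha <= 1.0):
            raise ValueError("sampling biases must be in [0, 1]")
        if self.s_ppii + self.s_alpha > 1.0 + 1e-12:
            raise ValueError(
                f"s_ppii + s_alpha must be <= 1, got {self.s_ppii + self.s_alpha}")
        if not (0.0 <= self.cis_pro_rate <= 1.0):
            raise ValueError("cis_pro_rate must be in [0, 1]")
        if 360.0 % self.grid_deg != 0:
            raise ValueError("grid_deg must divide 360")

    def _steric_key(self):
        return (tuple(sorted((tuple(sorted(k)), v) for k, v in self.radii.items())),
                tuple(sorted((tuple(sorted(k)), v) for k, v in self.radii_14.items())),
                self.hbond_limit, self.geometry, self.grid_deg)


@dataclass(frozen=True)
class Conformer:
    """A single clash-free chain state."""

    phi: np.ndarray     # degrees, per residue (phi[0] has no meaning)
    psi: np.ndarray     # degrees
    omega: np.ndarray   # degrees, omega[i] is the bond preceding residue i
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    atoms: tuple        # (residue index, atom name) per row of coords
    l: float            # max CA-CA distance, Angstrom


@dataclass(frozen=True)
class EnsembleSummary:
    n_states: int
    mean_l: float
    rh: float
    realized_f_ppii: float
    sd_l: float = 0.0
    converged: bool | None = None
    n_attempts: int = 0


# ---------------------------------------------------------------------------
# chain construction

def _place(a, b, c, bond, angle_deg, torsion):
    """NeRF placement: atom bonded to ``c`` with angle(b,c,d), torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = np.deg2rad(np.asarray(torsion, dtype=float))
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = (-math.cos(ang) * bc
         + (math.sin(ang) * np.cos(tor))[..., None] * m
         + (math.sin(ang) * np.sin(tor))[..., None] * n)
    return c + bond * d


def _atom_layout(sequence: str) -> tuple[tuple, np.ndarray]:
    """Per-atom (residue, name) rows and element indices for a sequence."""
    atoms = []
    for i, aa in enumerate(sequence):
        atoms.append((i, "N"))
        atoms.append((i, "CA"))
        atoms.append((i, "C"))
        atoms.append((i, "O"))
        if aa != "G":
            atoms.append((i, "CB"))
        atoms.append((i, "HA"))
        if i > 0 and aa != "P":
            atoms.append((i, "H"))
    elem = np.array([_ELEMENTS.index(_ATOM_ELEMENT[name]) for _, name in atoms])
    return tuple(atoms), elem


def _build_batch(phi, psi, omega, sequence: str, geom: BackboneGeometry):
    """Build a batch of chains; phi/psi/omega are (B, N) degrees.

    Returns coords of shape (B, n_atoms, 3) in the atom layout order.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    if not (phi.shape == psi.shape == omega.shape):
        raise ValueError("phi, psi, omega must have matching shapes")
    b, n = phi.shape
    if n < 2:
        raise ValueError("need at least 2 residues")
    if len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != {n} residues")

    npos = np.zeros((n, b, 3))
    capos = np.zeros((n, b, 3))
    cpos = np.zeros((n, b, 3))
    capos[0, :, 0] = geom.n_ca
    ang = math.radians(geom.ang_n_ca_c)
    cpos[0] = capos[0] + geom.ca_c * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        npos[i] = _place(npos[i - 1], capos[i - 1], cpos[i - 1],
                         geom.c_n, geom.ang_ca_c_n, psi[:, i - 1])
        capos[i] = _place(capos[i - 1], cpos[i - 1], npos[i],
                          geom.n_ca, geom.ang_c_n_ca, omega[:, i])
        cpos[i] = _place(cpos[i - 1], npos[i], capos[i],
                         geom.ca_c, geom.ang_n_ca_c, phi[:, i])

    rows = []
    prev_o = None
    for i, aa in enumerate(sequence):
        o = _place(npos[i], capos[i], cpos[i],
                   geom.c_o, geom.ang_ca_c_o, psi[:, i] + 180.0)
        rows.extend([npos[i], capos[i], cpos[i], o])
        if aa != "G":
            rows.append(_place(cpos[i], npos[i], capos[i],
                               geom.ca_cb, geom.ang_n_ca_cb, geom.tor_c_n_ca_cb))
        rows.append(_place(cpos[i], npos[i], capos[i],
                           geom.ca_ha, geom.ang_n_ca_ha, geom.tor_c_n_ca_ha))
        if i > 0 and aa != "P":
            # amide H is rigid in the peptide plane, anti to the carbonyl O
            rows.append(_place(prev_o, cpos[i - 1], npos[i],
                               geom.n_h, geom.ang_c_n_h, 180.0))
        prev_o = o
    return np.stack(rows, axis=1)  # (B, n_atoms, 3)


def build_chain(phi: Sequence[float], psi: Sequence[float],
                omega: Sequence[float] | None = None,
                sequence: str | None = None,
                geometry: BackboneGeometry = BackboneGeometry()):
    """Deterministic coordinates for one chain from its dihedrals.

    ``omega`` defaults to all-trans (180 degrees); ``sequence`` defaults to
    poly-alanine. Returns ``(coords, atoms)`` with coords of shape
    (n_atoms, 3) and atoms the (residue, name) row labels.
    """
    phi = np.asarray(phi, dtype=float)
    if omega is None:
        omega = np.full_like(phi, 180.0)
    if sequence is None:
        sequence = "A" * len(phi)
    coords = _build_batch(phi[None, :], np.asarray(psi, float)[None, :],
                          np.asarray(omega, float)[None, :], sequence, geometry)
    atoms, _ = _atom_layout(sequence)
    return coords[0], atoms


# ---------------------------------------------------------------------------
# steric filter

_BONDS_WITHIN = (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                 ("CA", "HA"), ("N", "H"))
#: 1-4 pairs across a peptide bond whose distance is fixed given omega
_OMEGA_RIGID = ((("CA",), ("CA",)), (("O",), ("CA",)), (("O",), ("H",)),
                (("CA",), ("H",)))

_PAIR_CACHE: dict = {}


def _pair_masks(sequence: str):
    """(excluded, one-four) boolean matrices for a sequence's atom layout."""
    cached = _PAIR_CACHE.get(sequence)
    if cached is not None:
        return cached
    atoms, _ = _atom_layout(sequence)
    index = {key: k for k, key in enumerate(atoms)}
    n_atoms = len(atoms)
    adj = np.zeros((n_atoms, n_atoms), dtype=bool)

    def bond(a, b):
        if a in index and b in index:
            adj[index[a], index[b]] = adj[index[b], index[a]] = True

    n_res = len(sequence)
    for i in range(n_res):
        for x, y in _BONDS_WITHIN:
            bond((i, x), (i, y))
        if i + 1 < n_res:
            bond((i, "C"), (i + 1, "N"))

    two = adj | (adj @ adj)
    three = two | (two @ adj)
    excl = two | np.eye(n_atoms, dtype=bool)
    onefour = three & ~excl
    for i in range(n_res - 1):
        for (xa,), (xb,) in _OMEGA_RIGID:
            a, b = (i, xa), (i + 1, xb)
            if a in index and b in index:
                excl[index[a], index[b]] = excl[index[b], index[a]] = True
                onefour[index[a], index[b]] = onefour[index[b], index[a]] = False
    _PAIR_CACHE[sequence] = (excl, onefour)
    return excl, onefour


def _limit_table(radii: Mapping[frozenset, float]) -> np.ndarray:
    table = np.zeros((len(_ELEMENTS), len(_ELEMENTS)))
    for i, ei in enumerate(_ELEMENTS):
        for j, ej in enumerate(_ELEMENTS):
            table[i, j] = radii[_pair(ei, ej)]
    return table


_LIMIT_CACHE: dict = {}


def _limit_matrix(sequence: str, config: SimConfig) -> np.ndarray:
    """Per-atom-pair contact limits; zero marks unscored pairs."""
    key = (sequence, config._steric_key())
    cached = _LIMIT_CACHE.get(key)
    if cached is not None:
        return cached
    atoms, elem = _atom_layout(sequence)
    excl, onefour = _pair_masks(sequence)
    far = _limit_table(config.radii)[elem[:, None], elem[None, :]]
    near = _limit_table(config.radii_14)[elem[:, None], elem[None, :]]
    limits = np.where(onefour, near, far)
    limits[excl] = 0.0
    # hydrogen-bond exception: amide H approaching carbonyl O
    is_h = np.array([name == "H" for _, name in atoms])
    is_o = np.array([name == "O" for _, name in atoms])
    hb = (is_h[:, None] & is_o[None, :]) | (is_o[:, None] & is_h[None, :])
    limits[hb] = np.minimum(limits[hb], config.hbond_limit)
    _LIMIT_CACHE[key] = limits
    return limits


def clash_check(coords: np.ndarray, sequence: str,
                config: SimConfig | None = None) -> tuple[bool, tuple | None]:
    """Hard-sphere check of one chain.

    Returns ``(passes, first_violating_pair)`` where the pair is given as
    (residue, atom name) labels, or None when the chain is clash-free.
    """
    config = config or SimConfig()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    atoms, _ = _atom_layout(sequence)
    if coords.shape[0] != len(atoms):
        raise ValueError(
            f"expected {len(atoms)} atoms for sequence, got {coords.shape[0]}")
    limits = np.triu(_limit_matrix(sequence, config), k=1)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    viol = (dist < limits) & (limits > 0)
    if not viol.any():
        return True, None
    i, j = np.argwhere(viol)[0]
    return False, (atoms[i], atoms[j])


def _clash_free_batch(coords: np.ndarray, sequence: str,
                      config: SimConfig) -> np.ndarray:
    """Boolean clash-free flag per chain for a (B, n_atoms, 3) batch."""
    limits = np.triu(_limit_matrix(sequence, config), k=1)
    ii, jj = np.nonzero(limits > 0)
    lim2 = limits[ii, jj] ** 2
    diff = coords[:, ii, :] - coords[:, jj, :]
    d2 = np.einsum("bpk,bpk->bp", diff, diff)
    return ~(d2 < lim2).any(axis=1)


# ---------------------------------------------------------------------------
# Ramachandran admissibility

_FRAGMENT = ((0, "C"), (0, "O"), (1, "N"), (1, "H"), (1, "CA"), (1, "HA"),
             (1, "CB"), (1, "C"), (1, "O"), (2, "N"), (2, "H"), (2, "CA"))


def tripeptide_allowed(phi, psi, config: SimConfig | None = None) -> np.ndarray:
    """Steric admissibility of central (phi, psi) pairs in a blocked residue.

    Builds an alanine tripeptide per pair and scores only the fragment whose
    internal distances depend on the central dihedrals (preceding carbonyl
    through following N-CA unit), so the result is independent of the flanking
    residues' dihedrals. Returns a boolean array.
    """
    config = config or SimConfig()
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    b = phi.size
    seq = "AAA"
    phis = np.column_stack([np.zeros(b), phi, np.zeros(b)])
    psis = np.column_stack([np.full(b, 140.0), psi, np.full(b, 140.0)])
    coords = _build_batch(phis, psis, np.full((b, 3), 180.0), seq,
                          config.geometry)
    atoms, _ = _atom_layout(seq)
    index = {key: k for k, key in enumerate(atoms)}
    sel = np.zeros(len(atoms), dtype=bool)
    sel[[index[a] for a in _FRAGMENT]] = True
    limits = np.triu(_limit_matrix(seq, config), k=1)
    limits = limits * (sel[:, None] & sel[None, :])
    ii, jj = np.nonzero(limits > 0)
    lim2 = limits[ii, jj] ** 2
    diff = coords[:, ii, :] - coords[:, jj, :]
    d2 = np.einsum("bpk,bpk->bp", diff, diff)
    return ~(d2 < lim2).any(axis=1)


_MASK_CACHE: dict = {}


def rama_allowed_mask(config: SimConfig | None = None) -> np.ndarray:
    """Boolean (n, n) grid of sterically allowed (phi, psi) cells.

    Cell (i, j) covers phi in [-180 + i*g, -180 + (i+1)*g) and likewise psi;
    admissibility is evaluated at the cell centre with
    :func:`tripeptide_allowed`. Cached per steric table and grid resolution.
    """
    config = config or SimConfig()
    key = config._steric_key()
    cached = _MASK_CACHE.get(key)
    if cached is not None:
        return cached
    n = int(round(360.0 / config.grid_deg))
    centers = -180.0 + config.grid_deg * (np.arange(n) + 0.5)
    pp, ss = np.meshgrid(centers, centers, indexing="ij")
    ok = np.zeros(n * n, dtype=bool)
    flat_p, flat_s = pp.ravel(), ss.ravel()
    chunk = 4096
    for k in range(0, flat_p.size, chunk):
        ok[k:k + chunk] = tripeptide_allowed(flat_p[k:k + chunk],
                                             flat_s[k:k + chunk], config)
    mask = ok.reshape(n, n)
    _MASK_CACHE[key] = mask
    return mask


def allowed_fraction(config: SimConfig | None = None, n_draws: int = 10_000,
                     seed: int | None = None) -> float:
    """Fraction of fully random alanine tripeptides that are clash-free.

    All three residues' (phi, psi) are drawn uniformly over the full square
    and the whole tripeptide is scored, mirroring the classic exercise of
    counting how many random structures survive the hard-sphere filter.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    seq = "AAA"
    phi = rng.uniform(-180.0, 180.0, (n_draws, 3))
    psi = rng.uniform(-180.0, 180.0, (n_draws, 3))
    n_ok = 0
    chunk = 4096
    for k in range(0, n_draws, chunk):
        coords = _build_batch(phi[k:k + chunk], psi[k:k + chunk],
                              np.full_like(phi[k:k + chunk], 180.0), seq,
                              config.geometry)
        n_ok += int(_clash_free_batch(coords, seq, config).sum())
    return n_ok / n_draws


# ---------------------------------------------------------------------------
# sampling

def _draw_dihedrals(rng: np.random.Generator, b: int, n: int, sequence: str,
                    config: SimConfig):
    """Draw (B, N) phi/psi/omega according to the sampling biases."""
    mask = rama_allowed_mask(config)
    grid = config.grid_deg
    centers = -180.0 + grid * (np.arange(mask.shape[0]) + 0.5)
    pp, ss = np.meshgrid(centers, centers, indexing="ij")
    cell_phi, cell_psi = pp[mask], ss[mask]
    # a window is carved out of the unbiased pool only when its bias is
    # actually applied ("the remaining fraction outside the window"); with no
    # bias the pool is the entire allowed region
    outside = np.ones(cell_phi.shape, dtype=bool)
    if config.s_ppii > 0:
        outside &= ~config.ppii_window.contains(cell_phi, cell_psi)
    if config.s_alpha > 0:
        outside &= ~config.alpha_window.contains(cell_phi, cell_psi)
    pool_phi, pool_psi = cell_phi[outside], cell_psi[outside]
    if pool_phi.size == 0:
        raise RuntimeError("no allowed cells outside the bias windows")

    u = rng.random((b, n))
    cat = np.where(u < config.s_ppii, 0,
                   np.where(u < config.s_ppii + config.s_alpha, 1, 2))
    phi = np.empty((b, n))
    psi = np.empty((b, n))
    for c, window in ((0, config.ppii_window), (1, config.alpha_window)):
        sel = cat == c
        k = int(sel.sum())
        if k:
            phi[sel], psi[sel] = window.sample(rng, k)
    def _in_excluded_window(p, s):
        bad = np.zeros(p.shape, dtype=bool)
        if config.s_ppii > 0:
            bad |= config.ppii_window.contains(p, s)
        if config.s_alpha > 0:
            bad |= config.alpha_window.contains(p, s)
        return bad

    sel = cat == 2
    k = int(sel.sum())
    if k:
        idx = rng.integers(0, pool_phi.size, k)
        jit = grid * (rng.random((k, 2)) - 0.5)
        p = pool_phi[idx] + jit[:, 0]
        s = pool_psi[idx] + jit[:, 1]
        # custom windows may straddle cell boundaries: redraw strays
        stray = _in_excluded_window(p, s)
        while stray.any():
            m = int(stray.sum())
            idx = rng.integers(0, pool_phi.size, m)
            jit = grid * (rng.random((m, 2)) - 0.5)
            p[stray] = pool_phi[idx] + jit[:, 0]
            s[stray] = pool_psi[idx] + jit[:, 1]
            stray = _in_excluded_window(p, s)
        phi[sel], psi[sel] = p, s

    omega = np.full((b, n), 180.0)
    pro = np.array([aa == "P" for aa in sequence])
    if pro.any():
        cis = (rng.random((b, n)) < config.cis_pro_rate) & pro[None, :]
        omega[cis] = 0.0
    return phi, psi, omega


def _ca_rows(sequence: str) -> np.ndarray:
    atoms, _ = _atom_layout(sequence)
    return np.array([k for k, (_, name) in enumerate(atoms) if name == "CA"])


def _kernel_args(sequence: str, config: SimConfig):
    """Packed geometry/layout arrays for the numba chain kernel."""
    atoms, _ = _atom_layout(sequence)
    index = {key: k for k, key in enumerate(atoms)}
    n = len(sequence)

    def rows(name):
        return np.array([index.get((i, name), -1) for i in range(n)],
                        dtype=np.int64)

    g = config.geometry
    bonds = np.array([g.n_ca, g.ca_c, g.c_n, g.c_o, g.ca_cb, g.n_h, g.ca_ha])
    angles = np.deg2rad([g.ang_n_ca_c, g.ang_ca_c_n, g.ang_c_n_ca,
                         g.ang_ca_c_o, g.ang_n_ca_cb, g.ang_c_n_h,
                         g.ang_n_ca_ha])
    torsions = np.deg2rad([g.tor_c_n_ca_cb, g.tor_c_n_ca_ha])
    limits = _limit_matrix(sequence, config)
    return (limits, rows("N"), rows("CA"), rows("C"), rows("O"), rows("CB"),
            rows("HA"), rows("H"), bonds, angles, torsions)


def _max_ca_dist(coords_batch: np.ndarray, ca_rows: np.ndarray) -> np.ndarray:
    ca = coords_batch[:, ca_rows, :]
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    d2 = np.einsum("bijk,bijk->bij", diff, diff)
    return np.sqrt(d2.reshape(d2.shape[0], -1).max(axis=1))


def _generate_states(n_residues: int, sequence: str | None, config: SimConfig,
                     n_states: int, rng: np.random.Generator):
    """Accept ``n_states`` clash-free chains; returns (L, f_ppii, attempts)."""
    from ._fastsim import chain_batch

    seq = sequence or "A" * n_residues
    if len(seq) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    args = _kernel_args(seq, config)
    n_atoms = args[0].shape[0]
    coords_scratch = np.zeros((n_atoms, 3))
    ls, fs = [], []
    n_acc = 0
    attempts = 0
    consecutive_rejects = 0
    batch = max(64, min(4096, 4 * n_states))
    ok = np.zeros(batch, dtype=np.bool_)
    l = np.zeros(batch)
    while n_acc < n_states:
        phi, psi, omega = _draw_dihedrals(rng, batch, n_residues, seq, config)
        chain_batch(phi, psi, omega, *args, coords_scratch, ok, l)
        attempts += batch
        n_ok = int(ok.sum())
        if n_ok == 0:
            consecutive_rejects += batch
            if consecutive_rejects > config.max_rejections:
                raise RuntimeError(
                    f"exceeded {config.max_rejections} consecutive rejections; "
                    "reduce the chain length or the sampling bias")
            continue
        consecutive_rejects = 0
        n_acc += n_ok
        ls.append(l[ok].copy())
        in_ppii = config.ppii_window.contains(phi[ok], psi[ok])
        fs.append(in_ppii.mean(axis=1))
    l = np.concatenate(ls)[:n_states]
    f = np.concatenate(fs)[:n_states]
    return l, f, attempts


def sample_conformer(n_residues: int, sequence: str | None = None,
                     config: SimConfig | None = None,
                     rng: np.random.Generator | None = None) -> Conformer:
    """Draw one clash-free conformer by whole-chain rejection sampling."""
    config = config or SimConfig()
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    seq = sequence or "A" * n_residues
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rejections = 0
    while True:
        phi, psi, omega = _draw_dihedrals(rng, 1, n_residues, seq, config)
        coords = _build_batch(phi, psi, omega, seq, config.geometry)
        if _clash_free_batch(coords, seq, config)[0]:
            atoms, _ = _atom_layout(seq)
            l = float(_max_ca_dist(coords, _ca_rows(seq))[0])
            return Conformer(phi=phi[0], psi=psi[0], omega=omega[0],
                             coords=coords[0], atoms=atoms, l=l)
        rejections += 1
        if rejections > config.max_rejections:
            raise RuntimeError(
                f"exceeded {config.max_rejections} rejections for one state; "
                "reduce the chain length or the sampling bias")


def run_ensemble(n_residues: int, config: SimConfig | None = None,
                 stop: int | str = 2000, sequence: str | None = None,
                 rng: np.random.Generator | None = None) -> EnsembleSummary:
    """Generate a uniform-weight ensemble and summarize its size statistics.

    ``stop`` is either a fixed number of accepted states, or ``"auto"`` for
    the stability rule: keep growing the ensemble tenfold until the running
    mean of L changes by less than 1%. ``realized_f_ppii`` is the fraction of
    residues whose (phi, psi) landed inside the PPII window, averaged over
    accepted states; steric rejection makes it differ from the applied bias.
    """
    config = config or SimConfig()
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if isinstance(stop, (int, np.integer)):
        if stop < 1:
            raise ValueError("stop must be a positive state count or 'auto'")
        l, f, attempts = _generate_states(n_residues, sequence, config,
                                          int(stop), rng)
        return EnsembleSummary(n_states=int(stop), mean_l=float(l.mean()),
                               rh=float(l.mean()) / 2.0,
                               realized_f_ppii=float(f.mean()),
                               sd_l=float(l.std(ddof=1)) if stop > 1 else 0.0,
                               converged=None, n_attempts=attempts)
    if stop != "auto":
        raise ValueError("stop must be an int or 'auto'")

    target = 100
    max_states = 1_000_000
    l, f, attempts = _generate_states(n_residues, sequence, config, target, rng)
    converged = False
    while not converged and target * 10 <= max_states:
        prev_mean = l.mean()
        l2, f2, att = _generate_states(n_residues, sequence, config,
                                       9 * target, rng)
        l = np.concatenate([l, l2])
        f = np.concatenate([f, f2])
        attempts += att
        target *= 10
        converged = bool(abs(l.mean() - prev_mean) < 0.01 * prev_mean)
    return EnsembleSummary(n_states=int(l.size), mean_l=float(l.mean()),
                           rh=float(l.mean()) / 2.0,
                           realized_f_ppii=float(f.mean()),
                           sd_l=float(l.std(ddof=1)),
                           converged=converged, n_attempts=attempts)
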