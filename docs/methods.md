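# Methods

This note records the models implemented in `dsekit`, their assumptions, the
numerical and design choices that were genuinely open, and what the test
suite does and does not establish.

## Hydrodynamic-size model

The central empirical relationship is a power law in chain length,
Rh = Ro·N^v, with Ro = 2.16 Å and an exponent that responds to the chain's
mean PPII propensity,

    v = 0.503 − 0.11·ln(1 − f_PPII),

optionally amended by a net-charge correction +0.26·|Q_net| − 0.29·√N (all
five constants are stored in one `RhCoefficients` record and can be
overridden; the screening module refits the two charge coefficients per
dataset). f_PPII is the mean per-residue PPII propensity under a chosen
scale; Q_net counts (K + R) − (D + E), ignoring histidine and the termini —
a deliberate reproduction of the counting rule used with the underlying
hydrodynamic data, not a pH-dependent charge model.

The model is inverted in closed form: the observed exponent is
ln(Rh_powerlaw/Ro)/ln N and f_PPII follows from the exponent relation.
Inversion refuses inputs below the unbiased-coil floor, with one numerical
concession: implied f_PPII in (−10⁻³, 0), which arises when a rounded,
tabulated Rh sits marginally below the floor, is clamped to 0. Mutational
pairs (wild type vs an n-site substitution variant) yield a per-site bias
change (f_wt − f_mut)·N/n; both charge-corrected and charge-free inversions
are exposed because either convention is defensible for mutational data.

Power-law fitting is nonlinear least squares on the untransformed residuals
(not a log-log regression), with a fixed multi-start grid (Ro ∈ {1, 2, 4},
v ∈ {0.4, 0.6}) and tight tolerances (1e−14) so results are deterministic;
a mode with Ro held fixed supports exponent-vs-bias analyses, and
v = v₀ + a·ln(1 − S_PPII) is fitted linearly in ln(1 − S_PPII).

## Propensity scales and the free-energy conversion

Scales are shipped as packaged CSVs (code, value, optional `approx` flag) and
carry their measurement temperature: proline-host CD scale at 278.15 K
(18 amino acids; W/Y unmeasured), glycine-host scale at 293.15 K (18; G/P
unmeasured), calorimetric host–guest scale at 298.15 K (complete), a
restricted-coil-library scale at 298.15 K (complete), and helix-formation
free energies at 273.15 K (complete; the W and Y entries are approximate in
the original report and flagged as such, stored as 0.6 and 0.4 kcal·mol⁻¹).
Free energies convert to propensities by p = K/(1+K), K = exp(−ΔG/RT) with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹; converting the full free-energy column at
its own 273.15 K anchor reproduces every printed propensity at its printed
precision and their mean of 0.29 (the mean of the *unrounded* conversions is
0.2940; averaging the rounded column would instead give 0.295, i.e. 0.30 —
the package averages unrounded values). Incomplete scales are completed with
their pre-fill average (`fill_missing`), the same convention used when
comparing scales of different coverage; the operation is idempotent and
preserves the average.

## Van't Hoff temperature model

A residue's conformational bias is a two-state equilibrium with deformation
constant K = (1 − p)/p. Assuming a temperature-independent transition
enthalpy ΔH (per residue, amino-acid-independent by default; a per-residue
mapping is accepted),

    ln K(T) = (ΔH/R)(1/T_anchor − 1/T) + ln K(T_anchor),

so each scale is shifted from its own anchor temperature rather than from a
fixed 298 K; 25 °C is represented as 298.15 K throughout (the entropy
checkpoint of 45.1 cal·mol⁻¹·K⁻¹ for ΔH = 13 kcal·mol⁻¹, p = 0.32 at 298 K
is insensitive to the 0.15 K difference at one decimal place). The
transition entropy is ΔS = (ΔH − ΔG)/T with ΔG = −RT·ln K, consistent with
(∂G/∂T)_P = −S by construction and verified against a finite difference.
Propensities of exactly 0 or 1 have no finite equilibrium constant and are
left fixed under temperature shifts. Rh–temperature curves recompute f_PPII
at each temperature and hold Q_net constant; no heat-capacity (ΔCp) term is
modelled, and the systematic low-temperature deviations expected from an
α-helix bias are deliberately outside this curve (see the population model).

## Three-state population model

A generic unfolded polypeptide interconverts between unordered (reference),
α-helix and PPII states. Anchors default to a PPII propensity of 0.35 at
298.15 K (the mean of the calorimetric PPII scale) and a helix propensity of
0.29 at 273.15 K (the mean of the converted helix scale). Each transition is
shifted to the target temperature with its own ΔH by the van't Hoff equation,
propensities convert to free energies ΔG = −RT·ln(p/(1−p)), and populations
follow from Q = 1 + exp(−ΔG_α/RT) + exp(−ΔG_PPII/RT). Signs are chosen so
that heating depletes both ordered states when ΔH > 0. Two enthalpy scenarios
are characteristic: with ΔH_α = 1 kcal·mol⁻¹ (the bare calorimetric helix
enthalpy) helix *depletes* on cooling — contrary to known peptide behaviour —
while ΔH_α = 11 kcal·mol⁻¹ (helix formed at the cost of disrupting PPII)
gives helix populations that rise monotonically as heat is removed, with
PPII dominant in the cold and both ordered states small at 338 K. Propensities
that reach the numerical boundary are clamped at 1e−12 with a warning.

## Hard-sphere ensemble simulator

Chains are poly-alanine by default, built residue by residue with the natural
extension reference frame from standard bond lengths and angles (N–Cα 1.458,
Cα–C 1.525, C–N 1.329, C=O 1.231 Å; N–Cα–C 111.0°, Cα–C–N 116.6°,
C–N–Cα 121.7°). Each residue carries N, Cα, C, O, Cβ (absent in glycine), the
α-hydrogen, and the amide hydrogen (absent in proline and at the N-terminus);
the amide H is rigid in the peptide plane anti to the carbonyl O, and Cβ/Hα
are fixed by improper torsions that encode the L-configuration. ω is trans
except for prolines, which sample cis at a 6% default rate (configurable to
10%; no neighbour dependence).

Steric admissibility is the only score. Three tiers of atom pairs:

* pairs whose separation is fixed by covalent geometry and ω (≤2 bonds, plus
  the ω-rigid 1-4 pairs across each peptide bond) are not scored;
* 1-4 pairs (exactly three bonds apart), whose approach reflects torsional
  strain rather than pure van der Waals contact, use a relaxed table
  (C···C 2.90 Å, …, H···H 1.90 Å);
* all other pairs use the classic "normal" limits (C···C 3.20, C···N 2.90,
  C···O 2.80, N/O···N/O 2.70, X···H 2.40, H···H 2.00 Å), with two
  modifications: amide-H···carbonyl-O pairs are capped at 1.8 Å so backbone
  hydrogen bonds (the O(i)···H(i+4) distance in an ideal α-helix is 2.17 Å)
  are not scored as clashes, and H···N is set to 2.30 Å (between the normal
  2.40 and outer 2.20 values) because at 2.40 the rigid amide H(i+1) collides
  with N(i) for all ψ > −36°, walling off the upper quarter of the α basin.

These choices were calibrated against three structural requirements — the
(0°, 0°) conformation of a central alanine must clash while (−90°, 90°) must
not; ideal PPII and α helices and the full sampling windows must be sterically
admissible; and the whole-tripeptide random acceptance rate must reproduce the
classic hard-sphere observation of roughly 2% — and then frozen. With the
defaults the measured acceptance is 2.0–2.4%.

Sampling biases: per residue, with probability s_ppii the (Φ, Ψ) pair is
uniform in the PPII window (−85°..−65°, 135°..155°), with probability s_alpha
uniform in the α window (−74°..−54°, −51°..−31°), otherwise uniform over the
sterically allowed region (precomputed for a blocked central residue on a 5°
grid and cached), excluding a window from that remainder only when its bias
is nonzero — at zero bias the unbiased coil samples the whole allowed region,
including both basins. Whole chains are rejected on any clash until a
clash-free state accumulates (an accelerated numba kernel detects the first
violation during construction; it is regression-tested to make identical
accept/reject decisions to the plain numpy filter). Accepted states get
uniform weights, L is the maximum Cα–Cα distance, Rh ≈ ⟨L⟩/2, and the
realized f_PPII is the fraction of residues landing in the PPII window,
averaged over states. A convergence mode grows the ensemble tenfold until
⟨L⟩ changes by less than 1%.

**Uniform weights are the simulator's stated approximation.** The reference
analyses weight states with a surface-area-parameterized energy function;
without it the hard-sphere coil is both more expanded and effectively stiffer
at short chain lengths. Two documented consequences, left as failing checks
rather than hidden:

* the unbiased scaling exponent fitted over N ∈ {10, 20, 40, 80} is ≈ 0.66
  (local slopes fall from 0.76 to 0.66 across that range, heading toward the
  excluded-volume ≈ 0.59 only at lengths far beyond what whole-chain
  rejection can reach — acceptance decays as ≈ e^(−0.11·N)), not the
  energy-weighted 0.503 nor the 0.45–0.60 band;
* at a fixed s_ppii = 0.4 the admissible α-bias range is capped at 0.6 by
  s_ppii + s_alpha ≤ 1, where mean helical run lengths (~2.5 residues)
  produce only turn-like compaction, so mean L decreases monotonically in
  s_alpha. The full non-monotone compaction-then-elongation response is
  reproduced when helix sampling can dominate: at s_ppii = 0, N = 40, mean L
  falls from 55.3 Å (s_alpha = 0) to 44.4 Å (0.6) and rises to 60.3 Å at
  s_alpha = 1 (rod-like helices), and that property is asserted in the unit
  suite.

Problem sizes in the test suite (2000 states at N = 20; 100–2000 states for
the exponent fit; 1000 states per α-bias point) were chosen so that 95%
confidence intervals separate the PPII-bias means cleanly.

## Coil-library statistics

Residue records are tabular (CSV columns aa, phi, psi, ss_label, segment_id,
position_in_segment, segment_length); constructing libraries from raw PDB
files is out of scope. Mesostates are 30°×30° bins with the origin at
(−180°, −180°), row-major in Φ. Default basins are axis-aligned boxes around
the conventional centres — PPII Φ∈[−110,−50), Ψ∈[110,180); α Φ∈[−100,−30),
Ψ∈[−67,−7); β Φ∈[−180,−110), Ψ∈[110,180); α_L Φ∈[30,100), Ψ∈[0,80) — checked
for pairwise disjointness; everything else is "other". Culling levels nest:
`full` (segment-terminal residues removed), `no_ss` (helix/sheet removed),
`no_ss_turns` (turns removed), `internal_coil` (contiguous coil stretches of
≥4, internal positions only; requires segment annotations). Basin
propensities are per-amino-acid fractions that sum to 1 across
basins ∪ other; amino acids without records are absent, not zero.
Reproducing the published per-amino-acid coil propensities or the 40%/28%
retention fractions requires the external structure set and is not attempted.

## Scale screening and synthetic data

Candidate scales are scored on two axes: squared Pearson correlation of the
charge-free power-law predictions with experimental Rh, and squared Pearson
correlation of the size-normalized error (pred − exp)/√N with |Q_net|/√N.
The error regression's coefficients, reported in the orientation
rh = powerlaw + slope·|Q_net| + intercept·√N, are each scale's empirical
charge correction — on data generated with (0.26, −0.29) they are recovered
to machine precision and the corrected error vanishes. "Best" scales pass
both thresholds (defaults 0.7 and 0.4) and have corrected mean absolute error
below the mode of the passing subset's error histogram (fixed 0.1 Å bins
anchored at zero; the mode is estimated as the centre of the most populated
bin, ties toward the lower bin). The consensus is the per-amino-acid mean
(with sd) over selected scales, optionally restricted to scales respecting a
user-supplied rank order — no default order is shipped because the measured
nonpolar ranking is not public. The charge regression is unweighted ordinary
least squares.

The synthetic IDP generator draws sequences i.i.d. from a hard-coded
composition profile (enriched D/E/K/R/S/P/Q/G, depleted W/C/F/I; it needs to
produce realistic spread in charge and f_PPII, not mimic any particular
database) and radii from the charge-corrected model plus Gaussian noise
(default σ = 0.5 Å). Because sequences are i.i.d., between-protein
composition variance is only p(1−p)/L — much smaller than in real IDP sets —
so a candidate scale's error is nearly collinear with its fitted charge/√N
correction and the consensus-recovery experiment (30 proteins, 10³ random
scales) is strongly dataset-seed-dependent: the consensus–truth correlation
scatters roughly 0.1–0.7 across seeds even at σ = 0, with rare amino acids
regressing to the 0.5 prior. Proline, both common in the profile and extreme
in the truth, is the reliably recovered signal. This is a faithful property
of the i.i.d. design, documented rather than tuned away; passing tests on
synthetic data accordingly demonstrate the machinery and the noiseless
identities, not field-strength recovery on real, compositionally diverse IDP
sets. The dihedral-record generator draws (Φ, Ψ) uniformly within prescribed
basin boxes (or their complement) with exact ground-truth weights for
recovery tests.

## Known limitations

* No energy weighting of simulated states (uniform weights), no side chains
  beyond Cβ, no rotamer sampling, no proline ring atoms, and no
  neighbour-dependent cis rates.
* No Rg/Rh interconversion or bead-model hydrodynamics; Rh ≈ ⟨L⟩/2 is used
  as in the source analyses.
* The charge model is a count, not a titration; κ-type charge patterning is
  deliberately not implemented.
* The simulator's scaling exponent and the fixed-PPII α-response differ from
  the energy-weighted reference, as detailed above.
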