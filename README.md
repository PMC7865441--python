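# dsekit

Sequence-based modelling of the protein **denatured-state ensemble (DSE)** —
the heterogeneous collection of non-native conformations that unfolded
proteins and intrinsically disordered proteins (IDPs) sample in solution.

Unfolded chains are not featureless random coils: they carry intrinsic,
per-amino-acid biases for the left-handed polyproline II (PPII) backbone
conformation and, in the cold, for the α-helix. Because PPII is extended,
the PPII content of a disordered chain controls its mean hydrodynamic radius,
which makes hydrodynamic measurements a quantitative window onto backbone
conformational bias. `dsekit` is for structural biologists and biophysicists
who work with IDPs, peptide propensity scales, or coil-library statistics and
want those connections as reusable, testable code.

## What it computes

**Hydrodynamic size from sequence.** The mean Rh of a disordered chain of
N residues follows a power law whose exponent grows with the chain's mean
PPII propensity f_PPII = Σ PPII_i / N, amended by a net-charge term
(Q_net = #K + #R − #D − #E):

```
Rh = 2.16 Å · N^(0.503 − 0.11·ln(1 − f_PPII))            (power-law form)
Rh = (power-law form) + 0.26·|Q_net| − 0.29·√N           (charge-corrected)
```

The model is invertible in closed form, so a measured Rh (or a mutational
ΔRh pair) yields the apparent PPII bias of a chain.

**Propensity scales.** Ships the three peptide-measured PPII scales
(proline-host CD, glycine-host NMR/CD, calorimetric SH3–Sos host–guest), a
coil-library PPII scale, and the alanine-host helix-formation free energies,
with the K/(1+K), K = exp(−ΔG/RT) conversion between free energy and
propensity.

**Temperature.** Per-residue van't Hoff modelling of conformational
equilibria (K = (1−p)/p, constant ΔH) propagates any scale to any
temperature, predicts Rh-vs-T curves, extracts transition entropies, and
drives a three-state PPII / α-helix / unordered population model of a generic
unfolded polypeptide.

**Hard-sphere ensembles.** A conformer generator builds chains from standard
covalent geometry and random dihedrals, rejects states with steric overlap
(the only scoring function), and supports PPII and α sampling biases applied
per residue inside the windows (−75±10°, +145±10°) and (−64±10°, −41±10°).
The ensemble statistic is L, the maximum Cα–Cα distance; ⟨L⟩/2 approximates
the mean Rh.

**Coil-library statistics.** Mesostate (30°×30°) indexing, Ramachandran basin
assignment, the increasingly stringent culling levels (full → no
helix/sheet → no turns → internal coil), per-amino-acid basin propensities
and Ramachandran histograms from tabular dihedral records.

**Scale screening.** Scores candidate (e.g. random) PPII scales against a
table of experimental radii, fits each scale its own charge correction,
selects the best performers, and averages them into a consensus scale —
with a synthetic-data generator providing ground-truth datasets for
parameter-recovery experiments.

## Worked example

```bash
$ cat demo.fa
>sic1_like
MTPSTPPRSRGTRYLAQPSGNTSSSALMQGQKTPQKPSQNLVPVTPSTTKSFKNAPLLAPPNSNMGMTSPFNGLTSPQRSPFPKSSVKRT

$ dsekit predict-rh --fasta demo.fa
id        N   f_ppii    q_net  rh_A
sic1_like 90  0.434667  11     27.6538
```

The 90-residue chain has a mean PPII propensity of 0.43 under the
calorimetric peptide scale and a net charge of +11; the charge-corrected
model predicts a mean hydrodynamic radius of 27.7 Å — far larger than an
unbiased statistical coil of the same length (2.16·90^0.503 − 0.29·√90 ≈
18.5 Å), which is the structural signature of high PPII content.

```bash
$ dsekit populations --t-min 273 --t-max 338 --t-step 13
T_K  unordered  alpha      ppii
273  0.252372   0.104236   0.643392
299  0.631285   0.044717   0.323998
338  0.924234   0.007732   0.068034
```

With matched transition enthalpies (ΔH_PPII = 10, ΔH_α = 11 kcal·mol⁻¹) the
generic unfolded chain is PPII-dominated in the cold (64% at 273 K, with
helix populated at 10%), and both ordered states melt away by 338 K.

```bash
$ dsekit simulate --n-res 20 --s-ppii 0.4 --states 2000 --seed 7
n_res  s_ppii  n_states  mean_L_A  rh_A     realized_f_ppii
20     0.4     2000      37.8758   18.9379  0.4302
```

A 40% PPII sampling bias expands the 20-mer hard-sphere ensemble to
⟨L⟩/2 ≈ 18.9 Å (the unbiased ensemble gives ≈ 17.2 Å); the realized PPII
fraction (0.43) exceeds the applied bias slightly because extended,
PPII-containing states survive the steric filter more often.

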