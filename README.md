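# dhxflex

Residue-resolved deuterium-to-hydrogen exchange (DHX) analysis for
transmembrane-domain (TMD) peptides, plus cleavage-product mass assignment
for intramembrane-protease substrates.

## The problem

How conformationally flexible is a substrate helix, residue by residue?
Backbone amides that are H-bonded inside a helix exchange their deuterons
slowly; flexible hinges and frayed termini exchange fast.  Measuring DHX of
an exhaustively deuterated peptide after a 1:20 dilution into protonated
solvent, fragmenting it by electron-transfer dissociation (ETD), and reading
the c/z fragment-ion ladders localizes deuterons to single residues without
scrambling.  This package implements the complete analysis chain:

1. **Intrinsic rates** (`dhxflex.intrinsic`) — sequence-specific chemical
   exchange rates `k_ch = k_A[H+] + k_B[OH-] + k_W` from the classic
   poly-DL-alanine reference rates and side-chain inductive factors
   (Bai et al. 1993), D-to-H direction, with Arrhenius temperature
   correction and pH-time equivalence (`t_eff = t * 10^(pH - pH_ref)`).
2. **Fragment kinetics** (`dhxflex.fragments`) — weighted isotonic
   (pool-adjacent-violators) smoothing of cumulative c/z deuteron ladders,
   consecutive differencing to per-residue contents, inverse-variance
   merging of the two sides.
3. **Kinetic fitting** (`dhxflex.fitting`) — monoexponential
   `D(t) = 0.95 e^{-kt} + 0.05` vs biexponential
   `D(t) = A e^{-k_A t} + B e^{-k_B t} + 0.05` (A + B = 0.95), selected by
   Wilks' likelihood-ratio criterion (`Lambda = n ln(RSS_mono/RSS_bi)`,
   chi-square with 2 df, biphasic if p < 0.01).
4. **Energetics** (`dhxflex.energetics`) — Linderstrom-Lang EX2 opening free
   energies `dG = -RT ln(k_exp / (k_ch - k_exp))` from the slow phase, with
   confidence intervals from the +/-1 SE of log10 k, assembled into
   per-residue "flexibility profiles" with biphasic and n.d. flags.
5. **Cleavage products** (`dhxflex.cleavage`) — average-mass enumeration of
   AICD/Abeta species for C100-His6-style constructs (epsilon/zeta/gamma
   sites) and nearest-mass assignment of MALDI-TOF peak lists.
6. **Synthetic data** (`dhxflex.simulate`) — ground-truth generator using the
   exact two-state Linderstrom-Lang solution (EX1/EX2/mixed regimes,
   conformer mixtures for biphasic amides, frayed termini, seeded noise).

## Worked example

```bash
dhxflex run --preset hinge --seed 7 --out results/run_hinge
```

simulates a C99-TMD-like peptide (Lys-flanked, Abeta numbering) and pushes
it through the full pipeline.  `profile.tsv` then contains, per residue
(excerpt from the run above):

```
domain_position  delta_g_kcal_mol  ci_low  ci_high  biphasic  nd
36               3.5068            3.4638  3.5498   1         0
37               3.4910            3.4560  3.5260   1         0
41               4.5072            4.4985  4.5160   0         0
42               5.0143            5.0027  5.0259   0         0
```

i.e. the G37/G38 hinge region is recovered at ~3.5 kcal/mol with biphasic
flags (diamonds in the heatmap table), while the stable core sits at its
construction values of 4-5.5 kcal/mol.  The numbered scripts under
`analysis/` run the same stages as a narrative (simulation, rate tables,
curve localization, fitting, profiles, cleavage-product assignment) and
write their tables under `results/`.

The equivalent library calls:

```python
from dhxflex import compute_kch, analyze_curve, build_profile
from dhxflex.simulate import get_preset, generate_dataset
from dhxflex.fragments import residue_contents

spec = get_preset("hinge", seed=7)
data = generate_dataset(spec)
curves = residue_contents(data["fragments"], spec.peptide)
fits = {c.position: analyze_curve(c) for c in curves if c.fit_eligible()}
profile = build_profile(spec.peptide, fits, compute_kch(spec.peptide),
                        t_max=float(spec.time_grid[-1]))
```

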