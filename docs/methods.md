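# Methods

## Exchange model

A backbone amide in a helix is treated as a two-state system: the H-bond
opens with rate `k_open`, recloses with `k_close`, and the deuteron
exchanges chemically with rate `k_ch` only while open.  The deuteron
survival decays with the slow eigenvalue of this scheme,

    lambda = ( s - sqrt(s^2 - 4 k_open k_ch) ) / 2,
    s = k_open + k_close + k_ch,

computed in the rationalized form `2 k_open k_ch / (s + sqrt(...))`, which
is stable for extreme rate ratios.  Limits: EX2 (`k_close >> k_ch`) gives
`lambda ~ (k_open/k_close) k_ch` so the observed rate reports the opening
equilibrium; EX1 (`k_close << k_ch`) gives `lambda ~ k_open`.  Under EX2
and a predominantly closed state, the opening free energy follows the
Linderstrom-Lang relation

    dG = -R T ln( k_exp / (k_ch - k_exp) ),   R = 1.987e-3 kcal/(mol K).

`dG` is computed only where `0 < k_exp < k_ch`; anything else is reported
as not determined with a reason code, never as a number.  For biphasic
amides the slow phase is used: the fast phase is interpreted as superposed
correlated (EX1-like) exchange from a second, transiently less protected
conformer, and carries no clean EX2 meaning.  Where the literature labels
the two biexponential populations inconsistently, this package always takes
the numerically smaller rate for dG; population labels are presentation
only.

## Intrinsic rates

`k_ch` per residue is the sum of acid-, base- and water-catalyzed terms
built from the poly-DL-alanine reference rates for the D-to-H direction at
20 degC (log10 kA = 1.40, kB = 10.00 in 1/(M min); kW = -1.60 in 1/min) and
the Bai et al. (1993) side-chain inductive factors, shipped as a versioned
TSV (`dhxflex/data/amide_factors.tsv`).  The factor of the residue carrying
the amide (lambda) multiplies with the factor of its N-terminal neighbor
(rho); the water term shares the base factors.  Choices worth recording:

* **pH is used as read.**  Exchange is D-to-H in protonated solvent, so no
  pD electrode correction applies.
* **Ionizable side chains** (Asp pKa 3.87, Glu 4.33, His 7.00) titrate
  between their protonated and deprotonated factor sets on the linear
  scale, Henderson-Hasselbalch weighted.  Without this, strongly acidic
  side chains would spuriously break the base-dominance property at pH 4.
* **Temperature**: Arrhenius corrections with activation energies 14 / 17 /
  19 kcal/mol (acid/base/water) around the 20 degC reference, and the water
  ion product pKw(T) interpolated on a CRC grid.  All shipped study
  conditions are at 20 degC, where the corrections are the identity.
* **Exclusions**: residue 1 (no amide), residue 2 (quench back-exchange)
  and prolines (no amide H).  Terminal-group charge perturbations are not
  modeled: the C-terminal carboxylate factor would depress base catalysis
  ~60-fold at the last amide, but terminal amides are never interpreted in
  TMD profiles and omitting the perturbation keeps the base-dominance
  property uniform across the peptide.  Solvent-composition effects (80%
  TFE) are likewise not modeled; aqueous values are used throughout.
* **pH-time equivalence** `t_eff = t * 10^(pH - pH_ref)` is valid only
  where base catalysis dominates; the implementation warns below pH 4.0.
  Against the full `k_ch` ratio the shortcut agrees to ~4% per pH unit
  (the small acid/water contribution).

The reference-rate fixture in the test suite (Ala pentapeptide,
`k_ch = 6.83 /min` at pH 5, 20 degC) is a frozen closed-form evaluation of
this pinned parameter set.

## Fragment ladders to residue curves

Cumulative c/z ladder contents are physically non-decreasing in fragment
size, so each ladder is smoothed per time point by weighted isotonic
regression (pool-adjacent-violators, weights 1/sigma^2).  This is the
minimal smoother enforcing the physical constraint; the exact kernel used
by proprietary evaluation software is not published, so the smoother is a
swappable strategy behind `smooth_ladder`.  Consecutive differences
localize contents (`C(i) - C(i-1)` from the c side, mirrored for z), the
two sides merge by inverse variance, and single-sided estimates carry a
1.5x inflated sigma.  Residues with no flanking fragment pair, or covered
at fewer than half the time points, are n.d. — the synthetic-data module
can emulate such coverage gaps.  Sigma of a smoothed value is kept at the
input sigma: PAVA pooling reduces error (verified by simulation) and this
conservative choice feeds the weighted fits.

## Kinetic fitting and model selection

Rates are estimated in log10 space, bounded to [1e-6, 1e3] 1/min, by
weighted least squares (scipy `least_squares`, analytic Jacobians).  The
monoexponential has a single free parameter; the biexponential adds a
second log-rate and an amplitude split with `A + B = 0.95` fixed by the
1:20 dilution.  Eight deterministic multistarts cover the rate window
spanned by the time grid plus starts derived from the monoexponential
solution; the start at equal rates guarantees `RSS_bi <= RSS_mono`, the
nesting safeguard.  Standard errors of log10 k come from the Gauss-Newton
covariance at the optimum.

Model choice follows Wilks' theorem on the Gaussian likelihood ratio,
`Lambda = n ln(RSS_mono/RSS_bi)` against chi-square with 2 degrees of
freedom, biphasic at p < 0.01.  A biexponential optimum whose rates differ
by less than 1.5x or whose smaller amplitude is below 0.02 is unresolvable
at the noise level and collapses onto the monoexponential fit before the
test; this is what keeps the biphasic call rate at its nominal level (the
measured type-I error at sigma = 0.01, 12 time points, is ~0.012 with a
95% CI covering 0.01) despite the finite-sample optimism of the raw
likelihood-ratio statistic.

## Confidence intervals and censoring

The "standard confidence interval" of dG evaluates the EX2 relation at
`k * 10^(+/-se)` — a +/-1 SE interval, not 95%.  In the small-rate limit
its half width is `RT ln(10) se`.  If `k * 10^se` reaches `k_ch` the
interval is one-sided and flagged.  Residues whose fitted rate implies less
than 5% label loss over the longest observed time are censored
(`censored_slow_exchange`): their dG is a lower bound, not a value.
Coverage of the +/-1 SE interval was checked by simulation (~68% nominal,
observed within [0.55, 0.82] at n = 300).

## Synthetic data

The generator is the package's study-condition definition, not a tuning
surface: 12 log-spaced effective time points from 0.1 min to 7 d (the
measured 1 min-3 d window plus pH-simulated extremes), additive Gaussian
noise of 0.01 deuterons on fragment contents, exhaustive c2..c(n-1) /
z1..z(n-2) coverage, all draws from a single integer seed.  Biphasic
residues are two-conformer mixtures — an EX2 conformer carrying the stated
dG plus an EX1-like conformer 100x faster — because a conformer mixture is
the simplest mechanism that produces exactly biexponential decay.  Presets:
`hinge` (C99-TMD-like: core dG cycling 4.0-5.5 kcal/mol, di-glycine hinge
at 3.5 with mixing, frayed termini at 2.5), `rigid` (poly-Leu, uniform
6.0, monophasic), `epsilon` (poly-Leu + VGGV hinge + destabilized
epsilon-site glycines).

What the simulation does *not* emulate: raw spectra (peak picking, isotope
envelopes, charge states), deuterium scrambling, back-exchange gradients,
ladder gaps from fragmentation efficiency (available only via explicit
dropping), or TFE-specific chemistry.  Passing the recovery suites
therefore demonstrates the correctness of the analysis chain under its own
statistical model, not instrument-level robustness.

## Cleavage-product masses

Average (not monoisotopic) masses, consistent with linear-mode MALDI-TOF of
4-12 kDa species; the residue-mass table is summed directly and is
cross-checked in the tests against an independent elemental-composition
calculation.  Products are enumerated per site from the C100-His6 layout
(Met + C99 + GSRS + His6); epsilon-site C-terminal products are the AICDs
(eps49 -> AICD50, eps48 -> AICD51).  Assignment assumes singly protonated
peaks (+1.008 Da applied at match time) and takes the nearest species
within a 1.0 Da default tolerance; unmatched peaks stay unassigned.
Intensity quantification and isotope-envelope handling are out of scope.

## Problem sizes

The shipped studies use 30-residue peptides, 12 time points, 2000
replicates for the null-calibration suite and 200 replicates for the
hinge-recovery suite — sizes at which every statistical claim in the test
suite is recomputed from scratch in minutes on one CPU.

## Known limitations

* The inductive-factor table is transcribed to two decimals; residues with
  strongly acidic neighbors near pH 4 are the most sensitive to it.
* Wilks df = 2 with a Gaussian iid likelihood is a convention; the true
  null distribution of the nested-exponential LRT is non-standard
  (boundary/identifiability issues).  The degeneracy collapse is the
  empirical regularizer and its thresholds (1.5x rate ratio, 0.02
  amplitude) are implementation choices.
* No global (linked-parameter) fitting across residues, no three-phase
  models, no solvent correction of `k_ch`.
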