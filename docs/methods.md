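# Methods

This note records the models implemented in `memlipid`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written
down. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Lipid species model and masses

Species are represented at *sum* level (class + total acyl carbons :
total double bonds, e.g. `PC 34:1`) or *sn-resolved* level
(`PI 18:0/10:0`, chains ordered *sn*-1/*sn*-2). Sphingolipid sum
compositions carry a third index counting hydroxyls (`Cer 44:0:4`).
Deuterated chains (`d31-16:0`) are first-class so spiked standards get
exact masses.

Elemental compositions are assembled from a hard-coded per-class
head-group table: species = head alcohol + Σ fatty acids − one water
per ester bond (glycerophospholipids, glycerolipids, steryl esters), or
long-chain-base + amide-linked fatty acid arithmetic (ceramides, with
inositol-phosphate and mannose additions for IPC/MIPC). The table is
validated two ways in the tests: against published monoisotopic masses
for nine classes, and against an independently hand-typed IUPAC
atomic-mass summation over hundreds of randomly drawn species (agreement
required to 1e-4 Da). Atomic masses at run time come from the NIST
table shipped with pyteomics.

Supported singly charged adducts: [M+H]+, [M+NH4]+, [M+Na]+, [M−H]−,
[M+Cl]−, with electron-mass-corrected charge carriers. Default
ionization per class follows shotgun practice with ammonium additive in
positive mode and deprotonation in negative mode: PC/LPC as [M+H]+,
DG/TG/EE as [M+NH4]+, all negative-mode classes as [M−H]−. The choice
is configurable per class because the acquisition protocol only fixes
the additives, not the adduct per class.

## Annotation and quantification

Peak matching is a closed ±tol window in relative units:
|m/z_obs − m/z_theo|/m/z_theo ≤ tol_ppm·1e-6, default 3 ppm, boundary
inclusive. All candidates within tolerance are reported; isobaric peaks
are flagged and their intensity split equally among candidates unless
MS2 evidence resolves them — the equal split is a declared assumption,
not a measurement.

Quantification assumes unit response factors within a class (one spiked
standard per class): amount = I_species/I_standard × spiked pmol. Mol%
is expressed over polar lipids only (GPL + sphingolipid classes);
storage lipids are quantified but excluded from the denominator.
Type-II isotope-pattern corrections are not applied (limitation:
intensities at M and M+2 of a one-double-bond neighbour overlap at
unit resolution; shotgun data at R ≈ 240,000 largely separates these,
which is why the omission is tolerable).

## sn-regiochemistry from MS2

For a deprotonated diacyl GPL the diagnostic fragments per chain are
the carboxylate anion RCOO⁻, the acid neutral loss [M−H−RCOOH]⁻ and the
ketene loss [M−H−(RCOOH−H₂O)]⁻. Every two-chain decomposition of the
candidate's total C:DB (chain carbons 4–26, double bonds 0–4 by
default) is scored by total matched fragment intensity (±0.01 Da); for
the winning decomposition the chain with the larger *summed* acid +
ketene loss intensity is assigned *sn*-2. Summing the two loss channels
is a package choice — the underlying empirical rule only says losses
from *sn*-2 are more abundant. The confidence threshold is
ratio ≥ min_ratio with min_ratio = 7 by default (the empirical floor of
the ratio in the system that motivated this package), inclusive at the
boundary; below it the call is "ambiguous". Assignments are invariant
to uniform intensity scaling by construction.

In-silico PLA2 digestion removes the *sn*-2 acyl of PC/PE/PI/PS
(classes with an annotated lyso form), yielding the *sn*-1 lyso-lipid
and the free *sn*-2 fatty acid; the "recovered lipid-bound" profile
therefore contains only *sn*-1 chains, which is the logic that places a
never-recovered chain (e.g. C10:0) at *sn*-2. Asymmetry: chain-length
difference ≥ 6 carbons (covering the 6–8 range characteristic of
C10:0-at-*sn*-2 species), symmetric in chain order, configurable.
Sum-level species can be promoted for the asymmetry call via an explicit
`assume_sn2` mapping (e.g. class-wide C10:0 at *sn*-2 established by a
PLA2 experiment); the flag is deliberately loud in the API because it is
an assumption.

## GUV flicker spectroscopy

Contours are recentred on their polygon (area) centroid per frame —
the centroid choice matters at O(u²) only. The radius is linearly
interpolated at 512 uniform angles; contours whose path angle is not
monotonic about the centroid are rejected as non-star-shaped. The
normalized deviation u = (r − r̄)/r̄ is Fourier-transformed with the
two-sided convention u(φ) = Σ_q u_q e^{iqφ}; mode variances ⟨|u_q|²⟩
are frame averages with standard errors, and an optional constant noise
floor can be subtracted (camera noise handling is an open choice in
published flicker pipelines; the default is none).

The model spectrum is the quasi-spherical equatorial sum over
spherical-harmonic degrees (formula in the README), evaluated in
log-space via log-gamma and log-double-factorial identities so l = 100,
q = 20 is numerically safe; P_l^q(0) uses |P_l^q(0)| = (l+q−1)!!/(l−q)!!
for l+q even (odd terms vanish). l_max defaults to 100; the truncation
check (l_max 100 → 200 changes mode-6 variance by < 0.1%) is a unit
test. Translation (q = 0, 1) and the dilation contribution are excluded
(q ≥ 2, l ≥ 2).

The fit is weighted least squares over modes 6–20 (configurable) with
free (log κ, σ̄), weights from per-mode standard errors; κ is
log-parameterized to stay positive, σ̄ may go slightly negative during
optimization (bounded above −6 where the l = 2 term diverges) and a
negative optimum triggers a warning and a refit clamped at σ̄ ≥ 0.
Standard errors come from the weighted Jacobian, scaled by reduced χ²
when > 1; the κ standard error uses the delta method on the log
parameter. Statsmodels-style surface: `FlickerSpectrumModel.fit()`
returns a results object with `summary()`, `predicted()` and χ²/dof.

GP imaging is pixel arithmetic (I₁−I₂)/(I₁+I₂) with zero-denominator
pixels masked. Ld/Lo phase areas use the two-class variance-minimizing
(Otsu) threshold on the closed equatorial intensity profile; the ratio
is bright/dim arc length. A profile is declared single-phase when the
two class means are closer than 4 pooled within-class standard
deviations — Otsu applied to unimodal noise yields a separation near
2.7, so 4 rejects noise splits while accepting any genuine two-level
contrast above four noise SDs.

## Isotope tracing

The correction matrix entry [i, j] is the probability of observing mass
shift i given j tracer-labeled skeleton carbons, i.e. a binomial in the
remaining n_skeleton − j + n_derivatization carbons at p_natural =
0.0107 (¹³C). Derivatization carbons (the FAME methyl, default 1 where
used) contribute natural abundance but can never carry tracer. Columns
sum to ≤ 1 because shifts beyond M+n are truncated by the measurement
window. Inversion is by non-negative least squares with renormalization
(robust to counting noise; direct inversion can go negative), and the
labeled fraction is 100(1 − M+0). Only carbon is corrected; O/H/Si
isotopes from derivatization are a documented limitation relative to
full GC-MS correction.

## TMH comparison

The built-in predictor is a deliberate stand-in so synthetic cohorts
need no external tool: Kyte–Doolittle windowed mean (window 19) ≥ 1.6,
maximal runs of qualifying window centres reported as segments, runs
closer than 3 residues merged. It reports centre spans, so predicted
lengths sit systematically below the planted hydrophobic-stretch length
by up to (window−1)/2 on each side; comparative statistics are
unaffected because the bias is common to all species. Real annotations
(e.g. from a profile HMM) enter through the same 1-based inclusive TSV
interface.

Length filtering pools all predicted segments across species, takes the
median m and discards segments with |length − m| ≥ ceil(0.5·m)
(inclusive boundary, so median 23 gives cutoff 12 and a 35-aa segment
is discarded). Pooling across species is the reading that yields a
single median; the filter is idempotent when the median is stable.
Single-span selection is decided on the reference species' member.

The rank-sum test enumerates the exact null for combined n ≤ 25 by
dynamic programming over (subset size, doubled-midrank sum) — tie-safe,
two-sided by distance of the rank sum from its permutation mean (with
ties the null can be asymmetric, so tail-doubling and distance-from-mean
differ; the package defines and tests the latter). Larger samples use
the tie-corrected normal approximation without continuity correction,
which is well calibrated at the cohort sizes used (the null rejection
rate is checked against the binomial interval in the acceptance suite).
Residue classes default to small non-polar {G,A,S,C,P}, large non-polar
{V,L,I,M,F,W,Y}, polar {T,N,Q,H}, charged {D,E,K,R}; the table is a
convention and therefore a configurable argument.

## Synthetic-data generators

All generators take a seed and are byte-deterministic under it; each
returns its ground truth alongside the data.

* **Lipidome** — deterministic species mol% (class weights 38/22/28/12
  for PC/PE/PI/PS; per-class asymmetric fractions 0.45/0.55/0.90/0.50,
  i.e. highest for PI as in a C10:0-producing yeast), species drawn
  from an asymmetric palette (16:0/10:0, 18:0/10:0, 18:1/10:0) and a
  symmetric one (16:0/16:0, 16:0/18:1, 18:1/18:1). The standard mix
  uses the conventional deuterated standards with spike amounts 71 pmol
  PC, 50 pmol PE, 43 pmol PI, 24 pmol PS. Noise: multiplicative
  log-normal on intensities and Gaussian ppm jitter on m/z —
  conventional defaults, as no instrument noise model is prescribed.
  Not emulated: isotope envelopes, chemical background, in-source
  fragmentation, chromatography. A run whose class standard jitters
  outside the matching window cannot be quantified and is treated as a
  failed run, as it would be at the bench.
* **MS2** — exact fragment m/z with the planted sn-2/sn-1 loss-intensity
  factor; optional log-normal noise. No peak shapes or isotope clusters.
* **GUV contours** — independent complex Gaussian mode amplitudes with
  Helfrich variances per frame (quasi-static approximation: no temporal
  correlation between frames, so the effective frame count is exactly
  the nominal one, unlike real video where correlation inflates errors).
  512 points per frame by default: linear re-interpolation of sparser
  contours measurably attenuates modes near q = 20 and biases κ upward
  by a few percent at 256 points.
* **Isotopologues** — mixture of a tracer-labeled binomial (purity 0.99
  per skeleton carbon) and an unlabeled natural-abundance binomial,
  multinomially sampled at 1e5 counts by default.
* **Proteomes** — hydrophilic backgrounds with planted hydrophobic
  stretches; per-species length medians (default 23 aa), optional
  per-species median shifts, helix dropout and G/A/S enrichment.
  Passing tests on these cohorts shows the statistics recover planted
  effects through the prediction-filter-test chain; it does not
  validate the hydropathy predictor against real TMH annotations.

## Problem sizes

The acceptance computation uses 4,000 frames per (κ, σ̄) grid point —
the frame count at which the flicker pipeline is specified to operate —
a 500-species sample for the mass oracle, 25 replicate lipidome runs to
estimate class-mol% standard errors, 1e5 counts per isotopologue
vector, all two-sample splits with combined n ≤ 10 for the exact
Wilcoxon oracle and 1,000 null simulations (n = 50 per group, integer
lengths) for its calibration. These sizes make the whole recomputation
run in under a minute on one CPU.
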