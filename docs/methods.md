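# Methods

This note records the models implemented in `amyloidsim`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter.

## Structural models and fibril stacking

Structures are flat atom lists (chain, residue number, residue name, atom
name, element, coordinates) read from PDB/mmCIF via gemmi; only ATOM records
of the first model are kept (HETATM and waters dropped). Residue numbering
is taken verbatim from the file; all ranges are 1-based and inclusive.

A fibril stack replicates one layer by helical symmetry: layer k is rotated
k·twist about z and translated k·rise along z, with the fibril axis fixed to
+z by convention. The default rise is 4.7 Å — the canonical inter-strand
spacing of the cross-β motif. Chains are relabeled `A0, A1, …` and the
central layer (index ⌊n/2⌋) is recorded; peak enumeration defaults to a
central-layer-vs-all convention so that edge layers do not distort contact
statistics. Stacking is a rigid transform, so intra-layer geometry is
preserved exactly and, for an untwisted stack, the same-atom inter-layer
distance equals the rise exactly.

Composite ("chimera") models are lists of (structure, residue ranges, label)
parts with disjoint residue claims; their spectrum is defined as the *sum*
of the per-part rendered spectra, never a joint re-enumeration — the parts
represent distinct structural states of different sequence segments, not a
single folded molecule.

### Secondary structure

A deliberately simple (φ, ψ)-window classifier covers the synthetic
structures: helix for φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; strand for
φ ∈ [−180°, −80°], ψ ∈ [80°, 180°] ∪ [−180°, −170°]; coil otherwise; runs
shorter than 3 residues are demoted to coil. It is *not* a DSSP/STRIDE
replacement — no hydrogen-bond analysis — and experimental folds should use
curated span maps instead. Three such maps ship as data files: the native
human lysozyme fold (4 α-helices, 4 3₁₀ helices, 3 strands), the human
fibril fold (11 named β-strands plus one 7-residue strand of unknown
sequence: 12 total) and the HEWL fibril fold (9 named strands plus 6- and
4-residue unknowns: 11 total). Unknown-sequence strands carry placeholder
numbering ≥ 901 and the label `unassigned`; only their residue counts are
meaningful, and they are excluded from shift-dependent simulation because no
sequence is available for them.

## Chemical shifts

Shift tables are usually produced by an external structure-based predictor
and read in (dialect auto-detected from the header). The embedded fallback
is a random-coil + secondary-structure-offset model: standard published
random-coil ¹³C/¹⁵N values per residue type, plus offsets by secondary
structure class (helix: ΔCA +2.6, ΔCB −0.5, ΔC′ +1.8, ΔN −1.5 ppm; strand:
ΔCA −1.6, ΔCB +2.1, ΔC′ −1.5, ΔN +1.5 ppm; coil zero), plus optional
Gaussian heterogeneity of standard deviation `heterogeneity_sd` (default 0,
i.e. deterministic). The fallback's only job is to place helix vs sheet
resonances in the correct spectral regions — for alanine it separates the
helical and β CA/CB cross peaks by 4.2 and 2.6 ppm respectively — not to
rival a trained predictor; no ring-current or hydrogen-bond terms are
included. All values are overridable.

## Peak enumeration

¹³C-¹³C peaks: every ordered carbon pair within the distance cutoff
(default 5 Å) produces a peak at (δᵢ, δⱼ); both orders are emitted so the
list is symmetric about the diagonal. Filters restrict to intra-residue
(same chain *and* residue) or inter-residue contributions. Diagonal peaks
are added for every shifted carbon. N-CA/N-CB peaks are bond-mediated, one
per residue, with no distance criterion (glycine skipped for N-CB).
Through-space ¹⁵N-¹³C peaks are gated by a per-chain isotope labeling
scheme; under a 1:1 mixed scheme (alternating ¹⁵N-only / ¹³C-only chains)
every surviving peak is inter-molecular, which is what makes the
sheet-residue count well-defined: residues contributing an inter-chain
N(i)-CA(i) peak are exactly the strands of an in-register sheet.

Amplitudes are uniform (1.0): the simulation is positional, and modeling
polarization-transfer efficiencies or mixing-time physics is out of scope.
Peaks coinciding within 0.01 ppm on both axes are merged with amplitudes
summed and capped at 1.0; merged peaks keep the full list of contributing
atom pairs so that residue counting survives coincident shifts (a
homopolymer stretch would otherwise collapse to one peak and lose its
provenance).

## Spectrum rendering and comparison

Linewidths convert between Hz and ppm through the nucleus Larmor frequency
(proton field default 850 MHz; ¹³C and ¹⁵N frequency ratios fixed to the
IUPAC Ξ values, giving 213.73 and 86.16 MHz). Human-facing output rounds
ppm to one decimal; full precision is kept internally.

Rendering places a unit-apex 2D Gaussian at each peak with per-axis
σ = FWHM/(2√(2 ln 2)). The default grid is 512×512 (the model-selection
demo uses coarser grids for speed); at ≥ 8 points per FWHM the rendered
integral matches the analytic 2πσ₁σ₂ within 1%, and a warning fires below 3
points per FWHM. Comparison is the Pearson correlation of the two grids
over a window (default 0–80 ppm × 0–80 ppm, the aliphatic CC region), which
is invariant to affine intensity rescaling; ranking sorts candidates by
descending correlation with lexicographic tie-break.

## Relaxometry

T2′ is fitted by nonlinear least squares of I(τ) = I₀·e^(−τ/T2′),
initialized from a log-linear regression; non-decaying data is an error. No
baseline offset is fitted by default — the decays are treated as single
exponentials — but an exponential-plus-offset variant is available behind a
flag for decays that do not relax to zero. The homogeneous linewidth is the
Lorentzian FWHM 1/(πT2′).
Decomposition is *additive*: heterogeneous = total − homogeneous, matching
the arithmetic of the 750 = 250 + 500 Hz budget; a Voigt-style
Gaussian⊗Lorentzian deconvolution would change the split by tens of Hz and
is deliberately not implemented. Temperatures are carried as metadata only.

## Worm-like chains

The 2D (surface-equilibrated) convention is used throughout — tangent
correlation e^(−s/2Lp) — because contours come from fibrils adsorbed on a
surface. The generator takes fixed-length steps with Gaussian turning
angles of variance step/Lp, which reproduces the closed-form ⟨R²(l)⟩ within
sampling error.

The MSED estimator fits ⟨R²(l)⟩ = 4Lp[l − 2Lp(1 − e^(−l/2Lp))] over
l ∈ [0.2·Lp₀, 4·Lp₀] (Lp₀ from a pilot fit). The secant-MSD statistic is the
perpendicular deviation of the contour midpoint from the secant joining
points separated by arc length l; its stiff-regime law ⟨u²⟩ = l³/(48Lp) was
derived for the weakly bending continuous chain and is validated by
simulation rather than taken from any particular tracing tool. Two
systematic effects bracket its validity: discrete sampling *inflates* u² at
small lags (at l = 2 steps the exact discrete expectation is 1.5× the
continuum law), and chain bending *deflates* it as l approaches Lp. The
end-to-end estimator therefore iterates a fit window l ∈ [0.4·Lp₀, 0.8·Lp₀]
(≥ 4 arc steps, within the stiff range l ≤ 2·Lp₀) with relative-error
weighting; under the validation conditions (500 chains, contour length
20·Lp, arc step Lp/10) this recovers Lp within ~10%, versus ~1% for MSED,
and the two estimators agree within 20%. Reported estimates require ≥ 10
segments; rod-like data that pushes Lp far beyond the observed lag range is
flagged `lower_bound_only`. Standard errors come from a 200-resample
bootstrap over contours (seeded). Ratios of Lp estimates propagate relative
errors in quadrature.

## Synthetic data: what it does and does not emulate

Toy structures use a reduced backbone atom set (N, CA, CB, C, O) built from
ideal internal coordinates — enough for every enumeration mode, but with no
side chains beyond CB, no hydrogens, and no disulfides. The chimera demo
uses a 60-residue synthetic sequence with an Ala-rich central strand region
(residues 21–40) flanked by helical segments, so the helix-Ala vs sheet-Ala
spectral signature appears without any real protein sequence. The
pseudo-experimental spectrum is the chimera sum plus i.i.d. Gaussian grid
noise; real spectra additionally carry correlated t1 noise, baseline
artifacts and apodization effects that are not modeled, so passing the
model-selection test demonstrates the ranking machinery, not robustness to
every experimental artifact. Decays are ideal exponentials with
multiplicative noise; contour ensembles are ideal 2D WLCs with no tracing
error or pixelation. All generators are pure functions of (parameters,
seed).

Problem sizes used in the validation suite — 5-layer stacks, 192–256 point
grids, 200 decays, 500-chain ensembles — were chosen as the smallest sizes
at which the estimators' sampling error is comfortably below the tolerances
being checked.

## Known limitations

* No spin dynamics: DARR/PAIN transfer efficiencies, MAS sidebands and
  mixing-time dependence are not modeled; peak lists are positional.
* The dihedral secondary-structure classifier mislabels anything requiring
  hydrogen-bond context (3₁₀ vs α boundaries, bulges).
* The additive linewidth decomposition is a convention, not a deconvolution.
* Persistence-length estimation assumes equilibrated 2D adsorption; kinetic
  trapping of real fibrils on mica violates this and biases Lp.
* The sequence identity of unknown-density strands is unresolved; they are
  carried as counts only.
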