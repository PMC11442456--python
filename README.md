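# amyloidsim

Tools for discriminating reversible from irreversible amyloid fibril
structure from low-resolution data, built around three computational pillars:

1. **Structure-based simulation of 2D solid-state NMR spectra.** Given an
   atomic model (PDB/mmCIF, or an idealized synthetic helix/cross-β stack)
   and per-atom chemical shifts, the package enumerates 2D correlation peaks
   — ¹³C-¹³C within a 5 Å distance cutoff (DARR-like), bond-mediated N-CAα /
   N-Cβ, and labeling-gated through-space ¹⁵N-¹³C (PAIN-like, where a 1:1 mix
   of ¹⁵N-only and ¹³C-only chains makes every peak inter-molecular) — and
   renders them as 2D Gaussian intensity grids at a chosen linewidth.
   Candidate structural hypotheses (e.g. a *chimera*: native helical
   sub-domain + fibrillar β-core) are ranked against a reference spectrum by
   windowed Pearson correlation.
2. **Linewidth decomposition.** A single-exponential fit of a variable-delay
   spin-echo decay gives the coherence lifetime T2′; its Lorentzian width
   1/(πT2′) is the *dynamic* (homogeneous) share of the observed linewidth
   and the remainder is *structural heterogeneity*:
   `total = 1/(πT2′) + heterogeneous` (e.g. 750 Hz = 250 Hz + 500 Hz, and
   500 Hz ≈ 2.3 ppm for ¹³C at an 850 MHz ¹H field).
3. **Worm-like-chain persistence length.** Fibril contours traced from AFM
   images are treated as 2D worm-like chains (tangent correlation
   e^(−s/2Lp)). Lp is estimated from the mean-square end-to-end distance,
   ⟨R²(l)⟩ = 4Lp·[l − 2Lp(1 − e^(−l/2Lp))], and cross-checked with the
   mean-square midpoint deviation from the secant, ⟨u²(l)⟩ = l³/(48Lp) in
   the stiff regime. The Lp ratio between fibril classes quantifies the
   flexible-vs-rigid contrast.

A `synthetic` module generates every input with known ground truth
(idealized helices, in-register cross-β stacks with 4.7 Å rise, shift tables
with secondary-structure offsets, exponential decays, WLC ensembles), so the
full pipeline runs and is tested without any downloads.

## Worked example

Count the residues in an inter-molecular β-sheet from a mixed-labeling
¹⁵N-¹³C experiment, simulated on a synthetic 20-residue in-register stack:

```python
from amyloidsim import chemshift, model_io, peaksim, synthetic

stack = synthetic.generate_beta_stack("A" * 20, n_layers=5)   # 4.7 Å rise
shifts = chemshift.predict_shifts(
    "A" * 20, model_io.SecondaryStructureMap([model_io.Span(1, 20, "strand", "core")])
)
scheme = peaksim.LabelingScheme.mixed(stack.chain_ids)  # alternate 15N / 13C chains
pain = peaksim.enumerate_pain_peaks(stack, shifts, scheme, cutoff=5.0)
print(peaksim.count_sheet_residues(pain))
```

prints `20` — each strand residue places its amide N within 5 Å of the same
residue's CA on the neighbouring (differently labeled) molecule, so the
count recovers the known sheet size.

Decompose a 750 Hz linewidth with the T2′ that gives a 250 Hz dynamic width:

```bash
$ amyloidsim lw-decompose --total-hz 750 --t2-ms 1.2732
total_hz        750     3.5 ppm
homogeneous_hz  250     1.2 ppm
heterogeneous_hz        500     2.3 ppm
```

Run the chimera model-selection demo (pseudo-experimental spectrum =
chimera sum + 10% grid noise):

```bash
$ amyloidsim rank --reference demo --noise-sd 0.1 --seed 2
1       chimera-sum     0.9996
2       native-only     0.9785
3       fibril-only     0.3460
```

The chimera (helical flanks + β-core) explains the reference better than
either single-state model.

All stages are also available as CLI subcommands (`simulate-cc`,
`simulate-nc`, `simulate-pain`, `render`, `compare`, `rank`, `t2fit`,
`lw-decompose`, `lp-estimate`, `make-synthetic`); each writes a JSON
manifest of its inputs, seeds and parameters next to its output.

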