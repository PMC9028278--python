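# Methods

## Mass conventions

All masses are monoisotopic, in daltons; retention times are minutes.
Element masses come from the NIST table shipped with pyteomics; residue
masses are evaluated at import time from the standard amino-acid elemental
compositions through the package's own element table, so every printed
value traces to one source of truth. Cys is unmodified (no
carbamidomethylation): the workflow derivatizes with 2PCA only.

m/z is computed as (M + z·m_H)/z with the **hydrogen-atom** charge carrier
(1.007825 Da), i.e. without electron-mass correction. This is the
convention under which the standard printed diagnostic values of the 2PCA
chemistry are simultaneously self-consistent: the marker ion C₆H₇N₂ at m/z
107.0609 is the plain atomic-mass sum of the ion formula, and the
"calculated" serine b1-type mass 178.0742 equals residue + C₆H₃N + 2·m_H.
With the true proton (electron-corrected) these values would differ by one
electron mass (~0.0005 Da), which is visible at four decimals. The
PCA residual C₆H₃N (89.0265 Da) is a *neutral* addition to peptide mass;
the marker formula C₆H₇N₂ is the *ion* itself.

## Ring-opening enumeration

A head-to-tail n-mer has n openable backbone amides; candidate k is the
rotation starting at residue k (1-based on the written sequence). All
candidates share the neutral mass ring + H₂O — they are isomers, which is
precisely why precursor mass cannot localize the soft spot.

For disulfide-cyclized peptides only amides strictly inside the bridged
loop open the ring; for a bridge between Cys_i and Cys_j this gives j − i
candidates (new N-termini at residues i+1 … j). The opened species is
branched — two chains joined by S–S — but its MS/MS is interpreted
pseudo-linearly: the candidate sequence runs from the new N-terminus to the
C-terminus, and the other chain's mass (minus 2 H for the oxidized bridge)
rides as a fixed appendage on the bridged Cys of that chain. Fragments
whose span covers the anchor carry the appendage mass; this reproduces the
y-ladder interpretation used in practice without inventing branched
fragment chemistry. `pseudo_linear=False` drops the anchor from fragment
generation (bare sub-chain ions) while keeping the precursor mass exact.
The parent ring mass for the disulfide topology is chain + H₂O − 2·m_H;
whether the bridge survives collisional activation is an assumption of the
pseudo-linear reading, not a verified mechanism.

Topology is always an explicit user input. A peptide with two terminal Cys
residues *suggests* disulfide cyclization but is never inferred.

## Fragment generation

For a derivatized candidate of length n:

* b_i = Σ(first i residues) + C₆H₃N + H⁺, i = 1…n−1 (the 2PCA residual
  rides on every N-terminal fragment); a_i = b_i − CO.
* y_i = Σ(last i residues) + H₂O + H⁺ — never 2PCA-modified.
* internal b ions over every contiguous span touching neither terminus,
  Σ(span) + H⁺.
* the diagnostic doublet is (b1, a1); the marker ion is fixed at 107.0609.

Hydrogen-transfer variants (integer multiples of m_H, default offsets
{0, −1}, +1 optional) are applied to the imidazolidinone-bearing ion types
(doublet, b, a) only — the observed ±1 H discrepancies arise from the
incompletely understood gas-phase chemistry of the 2PCA conjugate, and
there is no evidence channel for such shifts on y or internal ions.
Multiply charged variants are generated up to `max_charge`. Neutral losses
and c/z ions are out of scope. Internal fragments are b-type (acylium)
only.

Internal fragments whose residue multisets coincide (e.g. PLK and LKP in
JB1's sequence) are isobaric and can masquerade as terminal sequence tags;
`isobaric_internal_groups` finds all groups within a ppm tolerance by a
sorted sweep (adjacent chaining), and scoring flags any matched member as
ambiguous evidence rather than crediting it.

## Background subtraction

For each analyte scan at time t, control scans of the same scan function in
[t − w, t + w] are pooled (defaults: w = 0.2 min). Each analyte peak is
matched against every pooled control peak within ±10 ppm (symmetric window
on the analyte m/z); the **maximum** matched control intensity, scaled by
the factor (default 2), is subtracted. Non-positive residuals drop the peak
by default (`drop_nonpositive=False` clamps to zero instead — the
alternative behavior is a config switch because either is defensible).
Consequences, verified as property tests: output intensities never exceed
inputs, no new m/z appears, and the output is monotonically non-increasing
in both the scaling factor and the window width (a wider window can only
raise the control maximum). No retention-time warping is applied; analyte
and control runs are assumed to share the LC method. When no matrix-only
control exists, `cross_peptide_controls` merges the runs of the *other*
cyclic peptides as the control.

## Scoring and ranking

The evidence channels of manual interpretation are encoded as an explicit,
overridable linear score: w₁·doublet + w₂·y_coverage + w₃·b_coverage +
w₄·marker + w₅·matched_intensity_fraction, defaults (0.4, 0.4, 0.1, 0.05,
0.05). The doublet dominates jointly with y coverage because those are the
two decisive channels: the doublet names the first residue; the y ladder
separates duplicate candidates sharing that residue. The doublet is
credited only when **both** members match at one consistent H-offset — the
CO spacing is the diagnostic, a lone member is not. Coverage counts
distinct ladder ordinals over n − 1. Matching uses ±10 ppm by default.

Ranking is total and deterministic (score, then doublet, then y coverage,
then opening site ascending). A verdict is issued when the top candidate
leads the runner-up by more than the ambiguity margin (default 0.1 score
units — an interpretive threshold with no physical meaning, configurable);
otherwise the result is "ambiguous" with the tied set. MS/MS spectra are
selected by precursor match (±10 ppm) to the derivatized target at any
charge; optional RT gating restricts them to marker-peak windows (off by
default, since targeted scans may fire outside AIF marker peaks). Marker
peaks with no matching MS/MS are reported as "unassigned 2PCA species"
(e.g. secondary metabolites that lost further residues) with the most
intense co-eluting MS1 peak as the observed precursor; they are flagged,
never auto-sequenced.

## Synthetic data generator

The generator emulates the incubation-assay data shape: a matrix-only
control and an analyte run sharing identical matrix ions (m/z, RT,
intensity and jitter), plus analyte-only planted species. Defaults are the
validation conditions used throughout: 6-min RT span with a 0.05-min
MS1+AIF duty cycle (121 cycles), 50 matrix ions with log-uniform
intensities in 10⁴–10⁶ of which 20% carry 2PCA (and hence emit the marker
ion in AIF), Gaussian elution profiles with σ = 0.05 min, 3 ppm m/z jitter,
20 uniform noise peaks per spectrum, analyte apex intensity 10⁶ with the
marker at 8% of it (matching its low relative abundance), y/b ladder
completeness 0.9/0.5, planted doublet at H-offset −1 (the commonly observed
one-hydrogen deficit), and three targeted MS/MS scans at each planted apex.
These sizes make a full analyte/control pair plus pipeline run take well
under a second, so multi-seed validation is cheap.

Design choices worth noting:

* **Jitter is magnitude-bounded**: Gaussian with σ = jitter/3, truncated at
  ±jitter, so "jitter ≤ 3 ppm" guarantees containment in a ±5 ppm XIC
  window; an unbounded 3-ppm-σ Gaussian would scatter ~10% of marker points
  outside that window and artificially split chromatographic peaks.
* **2PCA-bearing matrix conjugates are placed chromatographically resolved
  from the planted analyte species** (outside the subtraction window plus
  peak width). A matrix marker co-eluting within ±0.2 min at comparable
  intensity would — correctly — cancel the analyte's marker during
  subtraction; the emulated assay presumes resolvable conjugates, as the
  real workflow does.
* The split-peak artifact of the two 2PCA conjugation isomers is modelled
  as two Gaussians 0.5 min apart sharing fragment spectra (resolved peaks,
  indistinguishable MS/MS), off by default.
* Matrix species are random masses with random fragment m/z, not real
  sequences: only their m/z / RT / intensity behavior matters to
  subtraction.
* y-ion intensities are boosted when the candidate contains an internal
  Lys (charge sequestration at the ε-amine) — a plausibility choice.

What passing on synthetic data shows — and what it does not: recovery
across seeds demonstrates that enumeration, fragment prediction,
subtraction, screening and scoring compose correctly under matrix
background, realistic mass error and noise. It does not validate
instrument-level effects absent from the emulation (isotope envelopes,
profile peak shape, RT drift between runs, co-eluting isobaric matrix
interference, detector saturation), nor the wet-lab derivatization
efficiency itself.

## Numerical choices and degenerate inputs

* ppm windows are symmetric, computed on the target (or analyte) m/z.
* Chromatographic peaks are maximal contiguous XIC runs ≥ an intensity
  floor with ≥ 3 points; apex ties break to the earliest scan.
* A 1-mer candidate has no ladder: only doublet/marker/parent ions.
* An empty MS/MS spectrum scores 0 (not an error); an empty control run
  returns the analyte unchanged with a warning; identical analyte and
  control runs subtract to empty spectra and yield "no evidence".
* AIF classification: ms level 2 with no selected precursor, or an
  isolation window ≥ 100 m/z.
* mzML is written as uncompressed 64-bit-float centroid mzML 1.1
  (deterministic byte-for-byte for a fixed generator seed) and read back
  with a namespace-agnostic parser that also accepts zlib-compressed and
  32-bit-float arrays; profile spectra trigger a warning and naive
  local-maxima centroiding.

## Known limitations

Single disulfide bridges only; no lactam/thioether cyclizations or
unnatural residues; no de novo sequencing of secondary metabolites; no
intensity prediction; no RT alignment between runs; quantitative
time-course kinetics (parent depletion) are out of scope.
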