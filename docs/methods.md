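# Methods

This note documents the models implemented in `g4probe`, the choices
made where the underlying procedures are conventionally underspecified,
what the synthetic-data generators do and do not emulate, and the known
limits of the analyses.

## Sequence design and provenance

Oligos are immutable records of an uppercase A/C/G/T string with an
optional parent and an edit list. Edits use 1-based coordinates (the
way positions are spoken about at the bench: "G14") and are applied in
class order — substitutions, then deletions, then terminal additions —
with deletion positions interpreted against the sequence as it stands
when the deletion is applied. A substitution or deletion may declare
the base it expects to find; a mismatch is an error rather than a
warning, because silent coordinate drift between a design table and a
sequence file is exactly the failure this guards against. Replaying a
child's edit list against its parent must reproduce the child exactly
(`verify_provenance`).

The built-in family derives from AS1411,
d(GGTGGTGGTGGTTGTGGTGGTGGTGG): the G14→T substitution produces AT14
with a central TTTT linker at positions 12–15; AT14-T1 and AT14-T2
delete one and two linker thymines; the AT14T series adds a terminal
thymine at both ends of each core variant.

## G4Hunter scoring

Per-base scores follow the standard rule set: every position inside a
maximal run of k guanines scores +min(k, 4), cytosine runs score
−min(k, 4), A/T positions 0; the sequence score is the arithmetic mean.
Because the package targets 24–28-mer synthetic oligos, scoring is over
the full length by default; a sliding window (returning per-window
means) is available for longer inputs but a window ≥ the sequence
length silently degrades to full-length scoring. Two symmetries are
useful as checks and are enforced by property tests: the score of a
reverse complement is the negation of the score, and A↔T swaps leave it
unchanged.

## Global alignment and the CF factor

The aligner is a three-state (match / gap-in-a / gap-in-b) affine-gap
Gotoh dynamic program under the NUC4.4 nucleotide matrix (+5 match, −4
mismatch; loaded from Biopython's bundled copy rather than re-typed).
Gap costs follow the EMBOSS/NCBI convention: a gap of length L costs
open + (L − 1)·extend, with defaults open = 10.0 and extend = 0.5, and
end gaps are penalized. Because several alignments can share the
optimal score while differing in aligned-identity counts, traceback
ties are broken deterministically — diagonal, then vertical, then
horizontal — so matched-pair counts are reproducible run to run.

The CF factor aligns a competitor against the reverse complement of the
probe and divides the number of identically aligned positions
("expected duplex base pairs") by the probe length, clipped to [0, 1].
Only exact Watson–Crick matches count; wobble or ambiguous pairings are
deliberately excluded, which makes CF a slightly conservative
hybridization-risk estimate. Correctness is checked two independent
ways: exhaustive enumeration of all global alignments for short pairs,
and score agreement with Biopython's `PairwiseAligner` on longer random
pairs.

## Melting curves

The folded fraction is the min–max map
θ = (y − y_min)/(y_max − y_min), which by construction has extremes 0
and 1. The default leaves the curve's direction alone (a rising FAM
trace maps low→high); `orientation="folded_high"` flips the curve when
needed so the folded, low-temperature side reads θ = 1, which is the
natural convention for denaturation data regardless of the raw signal
direction.

Transitions are fit with the four-parameter Boltzmann sigmoid

    y(T) = A2 + (A1 − A2) / (1 + exp((T − Tm)/dT)),

whose inflection is Tm and whose width dT > 0 (bounded in (10⁻³, 50) °C).
Both asymptotes are free so raw fluorescence and normalized curves fit
identically — normalization and fitting commute, and the S factor is
invariant to any affine rescaling of the signal (tested). Initial
values are data-driven: Tm₀ at the steepest central-difference slope,
dT₀ = 2 °C, asymptotes from the first and last signal deciles. No
smoothing is applied to melting data before fitting; least squares
already averages pointwise noise and pre-smoothing biases the fitted
slope. A fit is reported unconverged when the optimizer fails or the
fitted amplitude collapses (|A1 − A2| below 10⁻³ of the initial span),
and a Tm outside the temperature range is flagged rather than silently
returned.

For FRET-MC plates, replicate fits (one curve per plate, three plates
by default) are averaged per condition before differences are formed:
ΔTm values are condition means, and S = ΔTm(competitor)/ΔTm(reference).
A reference stabilization below 0.5 °C is an error — the assay has no
dynamic range and S would be a ratio of noise.

## Iso-FRET

F = (FI_competitor − FI_duplex)/(FI_F22 − FI_duplex) is computed per
replicate and then averaged, because plate gain drifts between wells;
a pooled mode (F of replicate-mean intensities) is also provided, and
the two coincide exactly when replicates share control wells (tested).
F is not clipped: values slightly outside [0, 1] are evidence about
noise and gain, not errors. Competitors whose CF factor exceeds a
configurable threshold (default 0.5 — an artifact default, not an assay
constant) are flagged as potentially confounded by direct
hybridization. File-level controls are plate means: each competitor
well is normalized against the mean `f22_alone` and `duplex` wells of
its plate.

## Difference spectra and the G4 signature

The difference is folded − unfolded after dilution correction
(a measurement diluted by factor d is multiplied by d to restore the
shared concentration scale); the classical TDS sign convention
(unfolded − folded) is available as a flag. Grids may differ by at most
1 nm in spacing, in which case the unfolded spectrum is linearly
interpolated onto the folded grid.

Band calling: the difference is pre-smoothed with a 3 nm-sigma Gaussian
— about a third of a typical ~9 nm UV band width, so band centers of
near-symmetric bands are preserved while pointwise noise is strongly
attenuated — and extrema are found by prominence (threshold 5% of the
smoothed amplitude) with a minimum width of 4 nm at half prominence.
Both guards exist because plate-noise at realistic levels otherwise
fragments genuine bands into narrow sub-peaks and promotes isolated
noise spikes into "bands"; width and smoothing encode the physical fact
that absorbance bands span several nm and noise does not. The G4 call
requires extrema within ±5 nm of all of 245, 273 and 295 nm with the
295 nm band opposite in sign to the 273 nm band. Because only the
*relative* sign is tested and thresholds are relative to the amplitude,
the call is invariant to the sign convention and to positive scaling of
the spectrum. Measured on the synthetic generator: 48/50 detection with
centers within ±2 nm at SNR 10, and 0/100 false calls on duplex-like
single-band spectra across two noise levels.

Topology classification (e.g. the parallel-G4 260/240 nm CD pattern) is
out of scope; the band report lists extrema positions and signs and
leaves interpretation to the user.

## Binding fits

α = (I − I_free)/(I_bound − I_free) with I_free the zero-titrant point.
When I_bound is not supplied it defaults to the mean of the final two
intensities, accepted as a plateau only if the last two increments do
not *both* exceed 5% of the total span in the direction of the
transition — a single noisy step is not evidence of an unsaturated
series, but a consistent trend is. Values of α outside [0, 1] are kept.

The Hill model α = c^n/(K_D + c^n) is fit by least squares. As written
the constant has units M^n; internally the optimizer works on the
molar half-saturation constant k = K_D^(1/n) (an equivalent
parameterization that keeps the parameter on one well-conditioned
scale for any n) and both forms are reported. n is free in (0.1, 10)
by default, initialized at 1 with k₀ the concentration nearest
α = 0.5; it can be fixed (`n_fixed` / `--n-fixed`). The abscissa is
the titrant (protein-domain) concentration. When the fitted k falls
below a tenth of the probe concentration the titration is
depletion-limited — the free and total titrant concentrations diverge —
and the fit carries a `depletion_flag`: the Hill constant is then an
apparent upper bound, not a true affinity. An exact-binding (Morrison
quadratic) model would be the right tool there and is noted as an
extension, not implemented.

Normalizing with a plateau-estimated I_bound on a series that has not
fully saturated biases K_D slightly low (the unreached asymptote is
mistaken for saturation); on the default grid the noiseless bias is
within a few percent for low-nanomolar K_D and is part of what the
recovery tests measure.

## Synthetic data

Generators produce exactly what the readers consume (same CSV/FASTA
dialects) plus a truth record stating every parameter and the noise
model. All noise is independent Gaussian, either absolute or relative
(multiplicative), and each generator is a pure function of its
parameters and seed — same seed, same bytes.

Default conditions:

* **Melting plates** — 20–95 °C in 0.5 °C steps (151 points),
  transition width dT = 3 °C, three replicate plates, noise sd 0.005 of
  the amplitude; FAM-style rising transitions.
* **Titrations** — 100 nM probe; 16 titrant points: 0 plus 15 geometric
  steps from 0.5 to 150 nM (≈1.5× per step). The geometric ladder is
  how a titration against a 100 nM probe resolves a low-nanomolar K_D:
  a 10 nM linear step leaves at most one point below half-saturation
  for K_D of a few nM and the constant is then poorly identified.
  Sub-picomolar half-saturation (tens of pM) is not identifiable from
  any 0.5–150 nM ladder — the first nonzero point is already saturated —
  and the generator marks such combinations with a grid warning in the
  truth record; recovery at 30 pM requires extending the ladder to
  ~10 pM, which the tests do explicitly.
* **Spectrum pairs** — a smooth 258 nm-centered absorbance envelope
  (~0.8 OD) shared by both states; the folded state adds signed 9 nm
  Gaussian bands, by default −0.04/−0.10/+0.05 at 245/273/295 nm in the
  folded − unfolded convention; noise sd 0.002 per point (SNR 50
  against the largest band; recovery tests also run at SNR 10).
* **Iso-FRET plates** — control intensities 100 (F22) and 10 (duplex),
  three replicates, 2% relative noise.
* **Sequence sets** — the seven-member family plus per-sequence shuffles
  of family members as decoys. Shuffles preserve length and base
  composition but not run structure, so decoy G4Hunter scores are
  usually *higher* than the originals (shuffling a (GGT)ₙ repeat tends
  to create longer G runs); decoys are composition controls, not
  score-matched negatives.

What the generators do **not** emulate: correlated (drift-like) noise,
plate edge effects, FRET photophysics (quencher distance, incomplete
labeling), probe depletion in titrations (series are drawn from the
Hill model itself), aggregation or higher-order G4 stacking, and
baseline slopes in melting curves. Passing recovery tests therefore
demonstrates that the analysis chain is correct and unbiased under its
own stated noise model — not that real plate data will reach the same
precision.

## Problem sizes and tolerances

The recovery suites use 100 seeded titrations per K_D (median molar
K_D within ±5% of truth at 1% noise) and 50 seeded melting-curve pairs
per shift (median ΔTm within ±0.5 °C at 0.005 amplitude noise); oracle
equivalence uses 1,000 random sequences for G4Hunter and 200 random
short pairs for the aligner, with all-alignment enumeration feasible at
length ≤ 5 (≤ 1,683 alignments per pair). These sizes make the full
suite run in seconds while leaving the medians' sampling error an order
of magnitude below the tolerance they are checked against.

## End-to-end runs

`g4probe all` executes generate → write → re-read → analyze → report
from one YAML config with a single seed; per-stage seeds are derived
deterministically from it. Outputs carry no timestamps, floats are
written at fixed precision, and a manifest of SHA-256 hashes is
emitted, so identical configs yield byte-identical output trees — the
property the determinism tests assert. The example config's F22 probe
sequence is a synthetic stand-in (a telomere-derived 22-mer); real
analyses should supply the actual probe sequence.
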