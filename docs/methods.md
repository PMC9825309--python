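# Methods

## Scope and model overview

`diasim` synthesises DIA bottom-up proteomics runs from a declared precursor
library. The simulation is fully deterministic given a master seed and is
built from five models, each with explicitly stated assumptions:

1. **Retention.** Library retention coordinates (Prosit iRT scores, MaxQuant
   observed retention times, or uniform synthetic iRTs) are mapped onto the
   gradient by an affine transform onto `[padding, run_length − padding]`.
   The map is order-preserving by construction; gradient nonlinearity is not
   modelled. Coordinates outside the library's observed window are clamped
   with a logged warning. The default padding is 5% of the run length at
   each end, so no elution profile is truncated by the run boundaries.

2. **Elution.** Each species elutes as an exponentially modified Gaussian
   (EMG) with location μ (the mapped apex), Gaussian width σ, exponential
   tail τ, and area equal to the species' per-sample abundance. Numerically
   the density is evaluated through `erfcx` whenever the `erfc` argument is
   positive (the regime where the textbook formula overflows for σ ≫ τ) and
   through the direct formula otherwise; τ = 0 falls back to the exact
   Gaussian. The profile "support" used to bound which scans a species
   contributes to is the interval where intensity exceeds a configurable
   fraction of apex (default 10⁻³); signal outside it is dropped, a
   truncation of well under 0.5% of peak area that is identical across
   samples and therefore cancels in fold-change ratios.

3. **Isotopes.** MS1 envelopes are aggregated (unit-mass binned) isotope
   distributions computed by exponentiation-by-squaring convolution of
   per-element patterns from a bundled IUPAC/CIAAW table
   (`src/diasim/data/isotopes.tsv`). Peak *k* sits at monoisotopic
   + k × 1.00286864 Da (divided by charge), the aggregate neutron-mass
   excess of organic compositions — fine structure is deliberately not
   resolved, matching how unit-resolution envelopes appear on instruments.
   Envelopes keep the first 5 peaks by default, drop peaks below mole
   fraction 10⁻⁴, and are *not* renormalised, so truncation loss stays
   measurable. Fragment ions are emitted monoisotopic-only, as spectral
   libraries carry single fragment m/z values. Decoy species from `.msp`
   files have no elemental composition, so their MS1 representation is a
   single centroid at the declared precursor m/z.

4. **Acquisition.** A duty cycle is an ordered list of scan events (≥1 MS1
   survey plus MS2 windows with per-event durations); the cycle repeats
   from t = 0 and an event is scheduled iff it finishes within the run
   (10⁻⁹ s float tolerance). Isolation windows are half-open
   `[lower, upper)`, which makes precursor-to-window assignment unambiguous
   in the default contiguous layout and well-defined (multi-assignment) in
   overlapping layouts. Scan speed is modelled entirely by event durations;
   no instrument-physics timing model is attempted.

5. **Spectra.** A peak's intensity is
   `elution_intensity(t) × species_fraction × abundance_to_counts ×
   spray_factor(scan)`, where `species_fraction` is the isotope mole
   fraction (MS1) or library relative fragment intensity (MS2). Co-eluting
   species superpose additively; peaks closer than 10⁻⁶ Th are summed
   (ion suppression and dynamic-range saturation are intentionally outside
   the model, so simulated runs are most realistic for longer gradients or
   simpler mixtures). Mass error is a fixed systematic ppm shift plus
   per-peak Gaussian ppm jitter; ionization instability is a per-scan
   multiplicative lognormal factor applied coherently to all peaks of the
   scan; an optional noise process adds Poisson-count uniform random
   centroids. Profile mode replaces each centroid with an area-preserving
   Gaussian, Lorentzian or m/z-domain EMG shape (FWHM = m/z / resolution)
   on a grid anchored at integer multiples of the grid step, so overlapping
   peaks sum on shared grid points; all-zero regions are omitted.

## Randomness discipline

All draws derive from one master seed through independent named
`SeedSequence` substreams: per-sample abundances and missingness, peak-width
jitter, decoy placement, per-scan spray factors, per-species mass-error
jitter, and noise centroids each own a stream. Mass-error jitter is keyed by
species id, so adding or removing any species (decoys included) leaves every
other species' draws — and hence the rest of the file — bit-for-bit
unchanged. Two runs with the same seed produce byte-identical mzML and
ground-truth files, which is what the replay file relies on.

## Study designs

For precursor *i* with base abundance $A_i$, the abundance in replicate *r*
of group *g* is $A_i \cdot 2^{\mathrm{fc}_{ig} + \varepsilon_{igr}}$ with
$\mathrm{fc}_{ig} \sim N(0, \text{between-sd})$ (zero for the reference
group 1 — the recorded true log2 fold change) and
$\varepsilon \sim N(0, \text{within-sd})$. Normal-on-log2 was chosen as the
variance model because label-free intensity variation is approximately
lognormal; the family and parameters are recorded in the parameter yaml.
Fragment intensities inherit the precursor's multiplier (fully correlated),
the conservative default for precursor-level quantification. Abundances are
sampled first and missingness masks applied afterwards: group-wise masking
(probability per precursor × group, removing every replicate of that group)
and sample-wise masking (independent per cell) are independent mechanisms,
so the expected absent-cell fraction is
$1-(1-p_\text{group})(1-p_\text{sample})$. Missingness is
missing-completely-at-random; intensity-dependent (MNAR) censoring, batch
effects and run-order drift are not modelled.

## The synthetic library generator

The generator emulates a tryptic HCD spectral library without external
data: peptides of 7–20 residues drawn uniformly from the 19 non-K/R
standard residues plus a terminal K or R (no missed cleavages), charges 2–3,
uniform iRT on [0, 100], base abundances $10^{N(6,\,0.6)}$ (≈3 orders of
magnitude of dynamic range, typical of label-free proteome data), and full
b/y ladders at charge 1 with uniform random relative intensities, keeping
the 12 most intense. Precursor and fragment m/z are exact consequences of
the elemental compositions, which is what makes the library usable as
ground truth. What it does **not** emulate: realistic fragmentation
propensities (intensities are random, not learned), charge-state
correlation with length, retention behaviour correlated with
hydrophobicity, shared peptides between proteins, or real mass-defect
clustering beyond what peptide-like compositions impose. Tests passing on
synthetic libraries therefore validate the simulator's bookkeeping and
signal model, not biological realism of any particular library.

## The XIC validator

`diasim.validation` is a deliberately naive stand-in for a DIA search
engine's quantification module: it integrates the monoisotopic MS1 trace
within a ppm tolerance (default 10 ppm) around each ground-truth precursor
m/z, restricted to a retention window around the true apex — without the RT
restriction, any species sharing the m/z tolerance anywhere in the gradient
would contaminate the area, which is not a failure mode any practical
quantifier has. The area is a Riemann sum (trace × MS1 scan spacing);
points per peak (PPP) is the number of trace points above half the trace
maximum. Fold-change recovery follows the "no missing values" convention:
precursors with any absent cell are excluded, estimated
log2 fc = log2(mean area group 2 / mean area group 1), and r² is the
squared Pearson correlation of estimated vs true, restricted to true fold
changes in [−5, 5] for comparability across scenarios. Envelope-summed
quantification and peptide identification/FDR are out of scope.

## The scan-speed benchmark

`diasim.benchmark.points_per_peak_sweep` fixes one scenario (chosen once as
the package's desk-scale echo of the classic cycle-time experiment): 1000
synthetic precursors, 600 s gradient, σ = 2.55 s / τ = 0.3 s (FWHM ≈ 6 s),
20 × 30 Th windows over 400–1000 Th, two groups × three replicates with
between-group log2 sd 1.0 and within-group 0.2, and per-scan spray
instability ln-sd 0.25. The spray noise is part of the scenario definition,
not an afterthought: a smooth peak's Riemann sum is exponentially accurate
in the sampling rate (Poisson summation), so without per-scan intensity
noise the integrated area — and hence r² — would be flat in PPP and there
would be no scan-speed effect to measure. With it, the per-sample area
error scales like $\text{sd}/\sqrt{\mathrm{PPP}}$ and quantitative accuracy
degrades as the duty cycle lengthens, which is the behaviour the benchmark
asserts (r² ≥ 0.95 at ~10 PPP, strictly decreasing to ~2 PPP, visibly
worse below ~6). The same seed — the same library, abundances and fold
changes — is used at every scan speed, making the sweep a paired
comparison. These problem sizes keep the full sweep under a minute on one
CPU while leaving the r² differences between adjacent sweep points an
order of magnitude above their sampling noise.

## Numerical and format choices

- mzML output is indexed mzML 1.1.0 with 64-bit m/z, 32-bit intensity,
  zlib compression, scan start times in minutes, and isolation windows
  encoded as target + lower/upper offsets — the encoding profile most
  widely accepted by DIA tools. The writer emits XML text directly with a
  byte-offset index and SHA-1 checksum; outputs are validated against the
  package's own CV-param-driven reader and, independently, Bioconductor
  mzR.
- Ground-truth rows are ordered by apex time then m/z; absent cells are
  written as empty fields (never zero). A single `apex_rt_s` column is
  written because the gradient map is sample-independent here; per-sample
  apex columns would be identical copies.
- The configuration registry is the single source of defaults; resolution
  order is defaults < config file < explicit overrides, unknown keys are
  rejected at every layer, and the parameter yaml always contains the full
  resolved mapping.
- Samples are simulated sequentially. The engine is vectorised per species
  (bulk EMG evaluation over all of a species' active scans, then one
  lexsort/split into spectra), which keeps a 6-sample, 1000-precursor,
  10 000-spectra-per-sample simulation in seconds without multiprocessing.

## Known limitations

No ion suppression, detector saturation or shot noise; no fragment isotope
envelopes; no MNAR missingness; no retention-time drift between replicates;
constant resolving power across m/z (an m/z-dependent law would be a
straightforward extension of the FWHM computation); decoys lack isotope
structure. The validator quantifies at MS1 only and performs no
identification, so search-engine-dependent effects (scoring, FDR, peak
picking) are outside what this package can benchmark directly.
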