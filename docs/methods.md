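# Methods

## Two-strain biofilm competition model

The simulator integrates, on a masked regular grid Ω (default: a disc),

    ∂B_i/∂t = d_i ∇·( φ(B) ∇B_i ) + r_i B_i (1 − B),   B = B1 + B2,

with φ(B) = max(0, 1 − B). Growth is logistic in the *total* density, so the
two strains compete for the same local carrying capacity (scaled to 1), and
spatial spread is negative density-dependent: the effective diffusivity
falls linearly with total biomass and vanishes at capacity (degenerate
diffusion). This is the mechanism behind the model's central behaviour —
once the interior of the colony saturates, the arrangement of strain sectors
freezes, so whichever strain reached more territory first keeps it, and a
modest growth-rate advantage compounds into near-exclusion. φ is a plain
callable on the config (`SimulationConfig.diffusivity`), so other
diffusivity laws can be substituted without touching the solver.

Nondimensionalisation fixes r₁ = 1 (time in units of strain 1's growth time
scale) and the domain radius sets the length scale. The swept parameter is
the relative growth rate ρ = r₂/r₁, applied to strain 2.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `r` (per strain) | 1.0 | nondimensional logistic growth rate; ρ = r₂/r₁ |
| `d` (per strain) | 1.0 | motility (diffusion) scale |
| domain radius | 30 | nondimensional; chosen so the expansion front crosses the domain within t_end = 50 at d = 1 (colonies in this regime span tens of length units) |
| grid | 256² (desk default; tests use 40²–128²) | spatial resolution |
| `dt` | 0.5 × h²/(4 max dᵢ) | half the explicit stability bound |
| `t_end` | 50 | stop time |
| stop rule | occupied fraction (B > 0.05) ≥ 0.90 of Ω, or t_end | whichever first |
| founder layout | n spots per strain, uniform in a central disc, b0 = 0.5 | 1:1 mixed inoculum |

### Discretisation and guarantees

Explicit forward Euler in time; second-order central flux form in space with
face diffusivity the arithmetic mean of φ at the two adjacent cells; fluxes
across ∂Ω are zeroed (zero-flux boundary). Under dt ≤ h²/(4 max dᵢ) the
update writes each new value as a nonnegative combination of old values, so

* nonnegativity holds by construction (a guard raises if the scheme ever
  produces a value below −1e−12; clipping is limited to that tolerance);
* with zero growth, mass is conserved to ~1e−12 relative per step (only
  rounding error, no scheme error);
* for **equal motilities** d₁ = d₂ the same argument applied to 1 − B shows
  B1 + B2 ≤ 1 is preserved. With unequal motilities the bound can be
  violated transiently; the study conditions (strains differing only in
  growth rate) always use equal d, and the property tests randomise within
  that regime.

Flux divergences are accumulated pairwise — (east + west) + (north + south)
— and the founder coordinate axis is exactly antisymmetric about 0 in
floating point. IEEE commutativity then makes a mirrored layout evolve
bitwise mirror-symmetrically; outcome sums use exact (`math.fsum`)
summation, so the mirrored equal-rate competition ends at exactly
f1 = f2 = 0.5, not approximately. This is used as a self-test of the scheme.

Outcome statistics: fᵢ = ∑Bᵢ / ∑(B1+B2) over Ω at the final state
("relative strain density"; ×100 gives % challenger remaining), plus the
fraction of Ω each strain occupies above the 0.05 density threshold. The
sweep reports f2_final as the outcome statistic as a function of ρ.

Numerical notes: overlapping founder spots are capped by proportional
scaling so B1 + B2 ≤ 1 at t = 0; a dt explicitly above the stability bound
is rejected with the bound in the message; non-finite values abort with a
diagnostic; an empty layout yields NaN fractions rather than an error.

## Image quantification

`quantify_relative_density` implements the fluorescence-macro contract at
the contract level (the original macro's parameters are not published):
per-channel background subtraction, automatic threshold, then the
challenger's share of integrated above-threshold intensity. Intensity
weighting is the default because relative strain *density* should weight
brighter (denser) regions; `mode="pixels"` switches to pixel counting.

* Background: rolling-ball-style morphological background — a grey opening
  with a flat (2r+1)² structuring element applied separably (two 1-D
  erosions then two 1-D dilations), subtracted and clipped at zero. The
  radius must exceed the colony scale or real signal is removed; pass
  `background_radius=None` for images without additive background (e.g.
  rendered synthetic images).
* Threshold: Otsu per channel; a channel with no variation contributes zero
  signal, and "both channels empty" is a defined error, not a number.
* The statistic is invariant under multiplying both channels by a positive
  constant (threshold, background and sums all scale linearly).

Footprints threshold the image (Otsu), label connected components and
return the largest component's area — satellite colonies are ignored by
construction. A uniformly saturated frame is the whole frame; a blank frame
is 0 with a warning.

Doubling times come from a least-squares fit of log2(OD600) against time.
The automatic window is chosen in two stages: among all contiguous runs of
≥ 3 points with positive slope and R² > 0.99, take the best R² observed,
then the longest window within 1e−6 of it. Maximising fit quality before
length keeps lag/plateau boundary points out of the window — a hockey-stick
window can hold R² above 0.99 while biasing the slope, but cannot tie the
pure exponential run's R² ≈ 1. On noiseless exponentials the fit is exact
for any sampling grid. For noisy curves an explicit window is usually the
better choice and is supported.

## Synthetic genomes and what they do (and do not) emulate

The generator builds annotated genomes around packaged synthetic template
CDSs (comQXPA operon, rapP-phrP, a Rap-family paralog at ~45% identity, an
IS-like cassette) embedded in random intergenic filler at ~43% GC with no
T-runs longer than 4 nt. Templates are deterministic (fixed internal seed)
so the generator and the screens' reference set agree; they are *stand-ins*,
not real *B. subtilis* sequence — real genomes remain the intended screen
input, with user-supplied references.

* The 3610-like comP template (769 codons, matching the ComP length class)
  carries exactly one maximal 8×T run at a recorded offset in the 5′ region
  (engineered as codons TTT TTT TTC after a codon ending in A). Other
  pherotype templates have the entire 5′ third recoded, so no equivalent
  tract exists and the hotspot locus does not align — emulating the 5′
  polymorphism that restricts the hotspot to one pherotype.
* Mutation classes: nonsense (codon → TAA), frameshift indels (size ≢ 0 mod
  3, insertion or deletion), in-frame deletions (whole codons),
  insertion-element insertion (1,196-nt cassette with 25-nt terminal
  inverted repeats + 4-nt target-site duplication = 1,200 nt inserted,
  divisible by 3 so the element call is not confounded with a frameshift
  call), and poly-T slippage (±n T within the run). Edits shift downstream
  feature coordinates; ground truth is recorded on the genome.
* rapP modules: residue 236 is AAC (N, signal-responsive) or ACC (T,
  3610-type unresponsive); 5′ truncation removes the first 150 codons and
  the start; plasmid context is a small separately named contig (< 20% of
  the chromosome contig, annotated "plasmid") carrying the module.
* Not emulated: phylogenetic divergence among genomes (templates differ only
  where the screens need them to), operon regulatory context, realistic
  intergenic structure, sequencing error. Passing the round-trip panels
  therefore shows the *classification logic* is correct, not that threshold
  choices are optimal for real annotation noise.

Rendered images map two density fields through a common affine gain (80% of
the uint16 range at the field peak) plus optional cross-channel bleed and
additive Gaussian noise (SD as a fraction of the dynamic range), clipped and
quantised; ground truth is the challenger's share of field mass. DE tables
draw logFC ~ N(0, 1.2) and FDR ~ U(0, 1) with optional pinned effects, and
record the rows passing the strict panel filter.

## Screen operating points

All thresholds live on `ReferenceSet` and are deliberate, documented
choices, not published values:

* **Conserved 3′ boundary: codon 300.** The 5′ region is polymorphic across
  pherotypes; no boundary is published. `boundary_from_alignment` derives
  one from a user-supplied multi-pherotype alignment (first codon from
  which every 10-codon window exceeds 80% identity).
* **Nonsense cutoff: stop before 95% of the reference length**, tolerating
  natural C-terminal variation while catching premature truncation. A stop
  is counted only when the whole stop codon lies strictly upstream of the
  first frameshifting or element-scale indel — stops *created by* an indel
  are that indel's consequence, not an independent nonsense mutation.
* **Insertion element: intra-CDS insertion ≥ 100 nt.** Length is the only
  annotation-free signal; shorter in-frame insertions are reported but not
  disruptive. Insertions ≥ 100 nt are excluded from the net-frameshift
  computation (the net of the remaining indels, mod 3, decides frameshift).
* **Codon-aware comparison** is a global nucleotide alignment with affine
  gaps (match 1, mismatch −2, open −5, extend −0.2), post-processed into
  indel blocks with every gap left-shifted to its leftmost score-equivalent
  placement (standard homopolymer normalisation).
* **Variant protein length**: translate the allele from its annotated start
  in its own (shifting) frame to the first stop, reading into downstream
  genomic context (3 kb kept) because frameshifted alleles often terminate
  past the annotated CDS end; a missing stop is flagged "runs off".
* **Hotspot detection** anchors the reference tract ±25 nt by local
  alignment (score ≥ 60% of the window length), reports the maximal T-run
  overlapping the mapped locus and whether any alignment gap falls inside
  the run. Substitutions that split the run are thus not mislabelled as
  indels.
* **Pherotype**: global protein identity (matches / alignment length,
  BLOSUM62) to each reference ComQ; assign at ≥ 90% with ≥ 5-point margin.
* **rapP**: candidate at ≥ 80% identity over ≥ 60% of the reference
  (paralogs sit near 45%); complete at ≥ 95% coverage with intact start;
  5′-truncated when ≥ 5% of the reference's N-terminus is unaligned.
  Residue 236 is read at the *aligned* reference column, so indels elsewhere
  cannot shift the call. phrP is sought ≤ 500 nt downstream on the same
  strand at ≥ 60% identity.
* **Replicon**: plasmid annotation > plasmid-reference match > size rule
  (< 20% of the largest contig in a ≤ 5-contig assembly); the largest
  contig is chromosomal; anything else unknown.
* **Point substitutions are never called disruptive** (e.g. an E510K-style
  missense allele screens as intact); the screen is a deliberate
  underestimate of functional comP loss.

The LXG repertoire matrix consumes an externally produced domain-hit table
(e.g. a PF04740 profile search) and computes, per reference toxin × isolate,
the maximum global-alignment identity (matches / alignment length, gap
columns included — identity conventions vary, so this one is stated). The
DE panel filter applies FDR < 0.01 and |logFC| > 1 with strict inequalities
(log base 2: "over 2-fold" ⇔ |logFC| > 1); operon summaries require every
member measured and past the fold cut.

## Problem sizes in the test and acceptance runs

Test-suite simulations use 40²–128² grids with small domains; the
qualitative desk-scale check runs at 256² (radius 30, t_end 50, ~9 s).
Screen recovery panels use 50 genomes per disruption class plus 50 intact
controls in the test suite and 25 per class in the acceptance script, with
positions and sizes randomised per seed. Image recovery uses 20 rendered
128² sector images at 2% noise. These sizes were chosen so the full suite
re-runs comfortably on one CPU.

## Known limitations

* The diffusivity law φ and the domain/inoculum geometry are package
  defaults for the qualitative regime, not fitted to experimental colonies;
  no nutrient field, mechanics, or 3D structure.
* Screening a genome from a *different* pherotype against the 3610-like
  reference can report spurious 5′ indels (the 5′ region is genuinely
  unalignable); real multi-pherotype screens should supply per-pherotype
  references via `ReferenceSet`.
* Threshold choices (boundary codon, 95%/100-nt/80%/60% cutoffs) are
  operating points validated on synthetic panels; on real annotation noise
  they are starting points, all exposed as configuration.
* `run_screen` holds each genome in memory one at a time; assemblies are
  expected at the bacterial scale.
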