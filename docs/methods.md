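# Methods

## Data model and conventions

All statistics consume an `Alignment`: n haploid sequences of equal
length L over {A,C,G,T,N,-}. Coordinates are 1-based inclusive
everywhere. Annotations are a minimal TSV dialect
(`id replicon start end strand kind`, kind ∈ {CDS, IGR}) validated on
read: CDS lengths divisible by 3, same-kind features non-overlapping,
intervals inside the replicon. A GFF3 importer would be a thin extension
of `read_annotation`; only intervals, strand and kind are used
downstream.

**Missing data.** Complete deletion: any column containing N or `-` is
removed before anything is counted, and the reported L is the number of
surviving sites. π is a raw per-site proportion with no multiple-hit
correction — at the diversities this package targets (π ~ 10⁻⁴) the
Jukes–Cantor correction is below the fourth significant digit.

**Singletons and η.** A singleton is an allele carried by exactly one
sequence (unpolarized; no outgroup). A column with a alleles contributes
a−1 to η and 1 to S; on infinite-sites simulated data η = S.

## Neutrality battery

Tajima's D uses the standard variance constants derived from n. Fu &
Li's D* and F* use the corrected (post-erratum) variance constants; the
test suite carries a second, independently coded transcription of the
same constants plus a simulation check that their neutral means sit
within ±0.1 of zero (the residual ≈ −0.07 negative bias at n = 14 is a
known finite-sample property of these studentized statistics, visible
identically in an independent coalescent implementation).

Fu's Fs computes S′ = P(K ≥ K_obs) under the Ewens sampling distribution
with θ = k̄, via unsigned Stirling numbers of the first kind evaluated in
log space (the triangular recurrence overflows double precision near
n ≈ 20 in linear space). K_obs = 1 makes S′ = 1 and Fs undefined; this
and every other degeneracy (S = 0, k̄ = 0, numerically saturated tails)
raises `UndefinedStatisticError` with a reason — statistics are never
silently NaN.

**Significance.** The null is the constant-size coalescent conditioned
on the observed S: random genealogies with exactly S mutations placed
multinomially on branches proportional to length. Two-sided p-values use
the (count+1)/(reps+1) estimator and are reported in the buckets ns,
<0.05, <0.02, <0.01. Fixed-S conditioning was chosen over the
fixed-θ/beta-approximation alternatives because it requires no nuisance
parameter and is exact for the quantity actually observed; it is seeded
and reproducible. 2000 replicates resolve the <0.01 bucket comfortably.

**UPGMA.** Average linkage on per-site p-distances; candidate merges are
ordered by (distance, label pair), a cluster being labelled by its
lexicographically smallest leaf, so output is independent of input order.
Heights are d/2, making the tree exactly ultrametric.

## Sudden-expansion mismatch model

Time is measured in mutational units (τ = 2υt). For a sequence pair,
differences given coalescence time t are Poisson(t) (unit total rate),
and in a population of scaled size θ a pair coalesces at rate 1/θ. The
equilibrium spectrum is geometric, F̂ᵢ(θ) = θⁱ/(θ+1)ⁱ⁺¹. For a sudden
jump from θ₀ to θ₁ at τ before present, conditioning on whether the pair
coalesces in the recent epoch gives

    Fᵢ(τ; θ₀, θ₁) = F̂ᵢ(θ₁)·P[Γᵢ₊₁ ≤ τ(1 + 1/θ₁)]
                    + e^(−τ/θ₁) Σ_{j≤i} Pois(j; τ) F̂ᵢ₋ⱼ(θ₀),

an exact rearrangement of the classical sudden-expansion solution,
derived here from first principles rather than transcribed, because
transcription errors in this formula are common in the literature. The
implementation is validated in the tests against the coalescent
simulator run under the same (θ₀, θ₁, τ): the mean simulated spectrum
matches the formula to Monte-Carlo error, and the curve sums to 1 to
1e−9 across the parameter ranges exercised.

**Fitting.** Nonlinear least squares on classes 0..max(3·d_max, 50)
against the observed spectrum, with bounds θ₀ ∈ [0, k̄], τ ∈ [0, 2·d_max]
and θ₁ = θ₀ + Δ, Δ ∈ [0, 10⁴] (the reparameterization enforces
θ₁ ≥ θ₀ by construction). 16 multi-start points on a grid of
(θ₀, τ) scaled by the observed mean guard against the fit surface's
local minima. A spectrum with all mass at class 0 is flagged degenerate
with τ = 0 rather than fit. τ is additionally reported from the
method-of-moments estimator (θ̂₀ = √(v−m), τ̂ = m − θ̂₀, clamped at 0),
which assumes θ₁ = ∞; both values are labelled.

**Raggedness.** r = Σᵢ₌₁..dmax (xᵢ − xᵢ₋₁)² across the supplied
frequency vector, with no wrap-around term. Literature conventions
differ on the boundary term; under this one, appending zero-frequency
classes beyond the vector's end never changes r, and a single-class
spectrum has r = 0.

**Dating.** t = τ/(2υL) years before sampling, with υ the per-site
per-year rate. Default clock: 0.0033 mutations per genome per
generation, 44 generations per year (≈200 h/generation for soil
bacteria), genome 7,139,558 bp — i.e. υ ≈ 2.03×10⁻⁸/site/year. No
calibration beyond this strict clock is attempted, and outputs are
labelled "years before sampling".

## SNP classification

Variants are classified by strand-aware codon translation of the
reference and alternate base under the standard genetic code: same amino
acid → sSNP, different → nsSNP, outside every CDS → iSNP. Start/stop
codon positions are classified by the same translation rule.
Multi-allelic sites are represented as one record per alternate allele.

Degeneracy: the fold class of a codon position is the number of bases
preserving the amino acid (1→0-fold, 2→2-fold, 3→3-fold, 4→4-fold).
3-fold sites (Ile third positions) are tracked as their own class
because binning them into 2- or 4-fold is convention-dependent; the
0/2/4 summary reports them separately. Stop codons are excluded from
degeneracy counts and from the expected ns/s enumeration (their three
sites are not mutation opportunities in the null), so fold-class counts
total the sense-codon sites rather than the raw CDS length; mutations
*creating* a stop count as non-synonymous. The expected ns/s null ratio
enumerates all 3 changes at every sense-codon site and is checked in the
tests against a brute-force oracle for exact equality.

Variant-site filters (defaults): coverage ≥ 6 reads; variant P ≤ 6×10⁻⁶;
a strand-bias P ≥ 5×10⁻⁵ applied only when the majority-strand fraction
of variant reads exceeds 65 % (otherwise that sub-filter passes); variant
present in ≥ 95 % of unique reads. Rejections carry the list of failed
conditions. The site summary includes an explicit majority-strand
fraction field, without which the two-part strand rule cannot be
evaluated.

## Coalescent simulator

Genealogies are drawn by the standard n-coalescent with model-dependent
pair rates: constant size (rate 1, coalescent units, mutation rate θ/2
per branch), sudden expansion (mutational units, rate 1/θ(s) with θ(s) =
θ₁ for s < τ and θ₀ earlier, mutation rate 1/2 — so simulated panels are
directly comparable with the mismatch formula's parameters), and
exponential growth (rate e^{gs}, sampled by inverting the cumulative
hazard). Mutations are Poisson on total branch length and land at
uniformly drawn *distinct* sites; the ancestral base is A and each
mutation flips its carriers to a uniformly random other base (all
statistics here are allele-label invariant).

**Capacity precondition.** Because mutation placement samples sites
without replacement, infinite sites holds exactly; the guard instead
checks model fidelity: with E[m] = μ·E[total branch length] (closed form
θ·a₁ for constant size; exact lineage-count death-process ODE otherwise,
cached per model), simulation refuses loci where a with-replacement
placement would collide with probability ≥ 1 %.

**Seeding.** A panel expands one master seed through
`numpy.random.SeedSequence` into per-replicate 31-bit seeds, so any
replicate is regenerable from (master seed, index). Fixed seeds give
bit-identical alignments.

**Toy genomes.** Alternating CDS (ATG + random sense codons + stop, on a
random strand) and uniform-random intergenic segments. `plant_snps`
chooses sites whose class is known by construction (synonymous alternates
at degenerate positions, amino-acid-changing alternates, intergenic
sites), at most one variant per position.

**What the generator does not emulate:** recombination, gene conversion,
selection, population structure/migration, finite-sites mutation,
sequencing error and missing data. Passing tests therefore demonstrate
correctness of the estimators under the stated neutral clonal models,
not robustness to those real-data complications — in particular, real
bacterial data require recombinant-region masking before these
statistics are interpretable, which this package deliberately does not
automate (the field practice is inspection-based).

## Problem sizes in the shipped checks

The test and acceptance runs use n = 14 samples throughout (matching the
isolate-panel setting the package targets): 2000 constant-size
replicates at θ = 10, L = 65 kb for the neutral calibration; 200–300
sudden-expansion panels (θ₀ = 0.5, θ₁ = 50, τ = 5, L = 120–130 kb) for
τ recovery (observed bias ≲ 6 %, well inside the ±15 % band) and the
expansion-regime signatures; 2000 fixed-S replicates for significance
buckets. Exact-curve fit recovery is required to sse ≤ 1e−12 with τ
within 1 % and θ's within 10 %.

## Known limitations

- Fu's Fs saturates (tail probability 0 or 1 in double precision) for
  extreme K_obs at large θ; such cases are flagged, not clamped.
- The by-class Tajima's D assumes the alignment is in reference
  coordinates (no indels relative to the reference) and classifies each
  polymorphic column by its most frequent non-reference allele.
- The expansion fit's θ₁ is weakly identified when τ is small or the
  spectrum is near-geometric; τ itself is the robustly recovered
  parameter, as the recovery tests show.
- UPGMA assumes a clock; on recombinant or rate-variable data the tree
  is a summary of distances, not a phylogeny.
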