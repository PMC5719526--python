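# Methods

## Signal model

A sequenced single-end read marks one end of a nucleosome-protected DNA
fragment.  Reads are extended to a fixed fragment length (default 147 bp,
the canonical length of nucleosomal DNA) and summarized by the **dyad**,
the fragment's central base pair: `start + 73` on the + strand,
`(end − 1) − 73` on the − strand, the interval midpoint for unstranded
reads.  Identical `(chrom, start, end, strand)` tuples are clonally cut
to at most one copy beforehand (configurable), removing PCR amplification
bias; the synthetic reads used in the validation studies carry no clonal
artefacts, so those studies skip the cut.

Dyads are accumulated into a per-chromosome 1 bp density track by
Gaussian kernel smoothing.  Each dyad contributes total mass exactly 1:
the kernel is truncated at ±4σ and renormalized over its discrete
support, and kernel mass falling outside the chromosome is reflected back
onto the boundary bins, so the track's total mass equals the dyad count
to machine precision.  **Default bandwidth: 10 bp.**  At the ~165 bp
nucleosome repeat of budding yeast, 20 bp smoothing merges adjacent dyad
clouds into single maxima at low coverage (~20 dyads/nucleosome); 10 bp
preserves the inter-nucleosome valleys while still suppressing
single-base noise.  Depth normalization scales two tracks
multiplicatively to the geometric mean of their total masses (symmetric
between samples); per-million scaling is available.

## Naked-DNA bias correction

MNase cuts DNA with a sequence preference that partial digests leave
intact, so a chromatin track carries peaks that reflect the enzyme, not
nucleosomes.  A naked-DNA digest of the same genome measures the
preference directly.  The correction is pointwise subtraction of the
depth-normalized naked track from the chromatin track, floored at zero
(peak calling needs non-negative density; the unfloored signed difference
feeds the signed log-p curves).  Subtraction happens after smoothing;
subtracting raw counts before smoothing is mathematically equivalent for
the unfloored difference (smoothing is linear) and differs only in where
the floor acts.  For qPCR-style amplicon vectors the correction is
division (chromatin / naked, with a pseudocount), kept as a separate
operation.

A GC diagnostic correlates per-fragment GC content (genome-average
subtracted) with log10 mean naked signal (pseudocount 0.5); a positive
Pearson r reproduces the expected overrepresentation of GC-rich,
MNase-resistant fragments in naked digests.

## Nucleosome calling

Candidate summits are local maxima of the track with height ≥
`min_height` (default: 2× the genome-wide mean track value); maxima
closer than `merge_distance` (default 100 bp) merge, keeping the higher,
leftmost on ties, so called summits are always ≥ 100 bp apart.  When the
raw dyads are available, each summit is refined by **mean-shift** to the
centroid of its dyad cloud (iterated mean over an 80 bp half-window,
≤ 5 iterations) and refined summits are re-merged.  The density mode has
positional noise of order σ_jitter/2 at 20 dyads/nucleosome; the centroid
estimator's noise is σ_jitter/√n, several-fold smaller, which is what
makes ±20 bp positioning possible at low coverage.

Per call:

* **occupancy** — track height at the summit;
* **fuzziness** — population standard deviation (bp) of the dyads within
  ±`merge_distance` (100 bp) of the summit.  The window is the call's
  exclusive territory (summits cannot be closer than that); a ±73 bp
  window would truncate the dyad distribution of genuinely fuzzy
  nucleosomes — the SD of a N(0, 50 bp) cloud truncated at ±73 bp is
  36 bp, a 27% underestimate, while the 100 bp window keeps the estimate
  within ~10% over the 10–50 bp range that matters;
* **p-value** — Poisson upper tail `P(X ≥ round(signal mass))` of the
  147 bp summit-window mass against the background-track mass over the
  same window, with the background rate floored at 0.1 to avoid
  degenerate zero-background tests.  No multiple-testing correction is
  applied (a Benjamini–Hochberg view would be a one-liner on the saved
  table); the conventional filter is p < 0.01.

## Differential comparison

Two maps are matched one-to-one by greedy nearest-summit pairing within
74 bp (half a nucleosome); each pair carries Δoccupancy and Δfuzziness
(second condition minus first).  The named fuzziness thresholds 40
(highly fuzzy) and 30 (well positioned) are module constants.  The 2D
kernel density of (Δfuzziness, Δoccupancy) scatter uses a 100 × 100 grid
spanning the data range padded 5%, with a Gaussian kernel truncated at a
radius of 30 grid cells and σ = radius/3 — the truncation-radius reading
of the "radius" parameter of the originating desktop statistics tool.
Signed log-p curves compare two binned signals per bin with the Poisson
upper tail of the larger value against the smaller (floored at 0.1):
−log₁₀ p is plotted where the first signal is higher, +log₁₀ p (negative)
where it is lower, 0 at equality; the curve is antisymmetric by
construction.  Logs are base 10 (configurable).

The category-level tests — two-sample KS, Student's t (pooled variance),
Wilcoxon–Mann–Whitney (exact on small tie-free samples), upper-tail
hypergeometric enrichment, and two-sided Fisher's exact — are thin,
shape-checked wrappers over scipy.stats; the test suite verifies each
against independent enumeration oracles (label-permutation enumeration
for KS and Mann–Whitney, margin-constrained table enumeration for
Fisher, combinatorial sums for the hypergeometric, numerical integration
of the t density for the t test) to 1e−9.

## Metagene analysis

Genes are scaled to a common pseudo-length: 500 unscaled upstream bp,
the body linearly interpolated onto 1000 bins, 500 unscaled downstream
bp, all in transcription orientation (− strand genes reversed); the axis
anchors at the TSS (0) or the pAS.  Genes with bodies < 200 bp are
excluded (interpolation stability); bins beyond chromosome ends are
NaN-masked and excluded from the per-bin mean.  Stratification supports
promoter class (TATA / TATA-like), tags (e.g. RP), and transcription-rate
quartiles computed by ranking the rated genes and splitting into four
groups whose sizes differ by at most one (Q1 = most transcribed).  An
isolation filter keeps genes whose pAS is ≥ 500 bp from every other TSS,
for clean pAS-anchored profiles.

Nucleosomes are assigned to the nearest gene by interval distance
(0 inside the gene, within 1 kb otherwise) and classified
promoter / body / other under either of the two conventions in use:
*scaled* (promoter −500..0 bp upstream, body scaled position 0–1000) or
*genomic* (promoter TSS−500..TSS, body TSS..gene end).  Both exist in
the literature and must be chosen explicitly.  Positional mean-fuzziness
curves bin the TSS-relative summit positions at 50 bp.

Nucleotide profiles report coding-strand A/C/G/T frequencies per
position in a ±500 bp window around the TSS (− strand genes
reverse-complemented), with per-gene region means over the promoter
(−500..−100) and body (+50..+500) and two-sample t-tests between strata
per nucleotide.

## Periodicity and map comparison

The nucleosome repeat length is detected by a Fourier periodogram of
the 1 bp-binned, mean-subtracted centre-occurrence series over a region
(promoter −500..0 or body 0..1000), evaluated on a 1 bp period grid from
50 to 400 bp.  Power is `|2/N · Σ xₙ e^(−2πin/T)|²`, so an injected
sinusoid of amplitude A peaks at A² and duplicating every event scales
all powers by exactly 4.  A caveat: maps built from *called* summits are
nearly delta combs, whose harmonics carry power comparable to the
fundamental; the repeat-recovery studies therefore use centre jitter
(σ = 10 bp), which suppresses harmonics through the Gaussian spectral
envelope.

Map-to-map agreement: for each centre in map A, the distance to the
nearest centre of map B on the same chromosome; the 1 bp histogram is
smoothed with a centered moving average of window 10 (edges truncated),
and the cumulative frequency curve, resampled onto a fixed 0..500 bp
grid, is compared between profiles by Euclidean norm.  The comparison is
directional (A→B); trees symmetrize the two directions.  UPGMA
(average linkage on the distance matrix, via scipy's linkage) produces an
ultrametric with merge heights d/2 and a Newick string whose branch
lengths are height differences; the suite checks it exactly against a
naive O(n³) re-implementation.

## The synthetic-data generator

The generator emulates the experimental design end to end and is the
substrate for every validation claim.

* **Genome** — i.i.d. sequence at a target GC fraction (default 0.38,
  yeast-like), deterministic under seed.
* **Landscape** — genes packed left to right (bodies 900–2100 bp,
  intergenic gaps 560–760 bp, random strands), each with a
  nucleosome-depleted region (NDR, default 140 bp) immediately upstream
  of the TSS, a −1 nucleosome beyond it, a +1 nucleosome with its dyad
  73 bp downstream of the TSS, and a phased array at the repeat length
  (default 165 bp = 147 + 18 bp linker) through the body.  Each
  nucleosome carries an occupancy weight (lognormal, σ = 0.3) and a
  positional jitter σ (its true fuzziness).  A configurable fraction of
  −1 nucleosomes (RP genes first) is flagged MNase-fragile; fragile
  sampling weight is scaled by `fragile_retention` (1.0 = partial
  digestion preserves them).  TATA (20%) vs TATA-like classes get
  class-specific GC offsets in promoter and body sequence, giving the
  composition analyses a real effect.  Transcription rates are lognormal,
  RP genes ×8.
* **Bias model** — per-base cut weights (preference of cutting 5′ of
  each base) times a log-linear GC protection factor
  `exp(−gc_effect · (GC₁₀₁ − GC_genome))`: a deliberately minimal
  two-knob model that reproduces the two empirical phenomena (non-flat
  naked digestion; GC-rich fragments overrepresented), not a claim about
  MNase chemistry.
* **Chromatin arm** — per nucleosome, a Poisson number of fragments at
  mean `coverage × weight/mean(weight)`; dyad = summit + round N(0, σ);
  fragment = dyad ± 73; the candidate fragments are then resampled with
  probability proportional to the cut weight at their two ends
  (count-preserving — a library is sequenced to target depth, bias
  shifts its composition).  A `background_fraction` (default 0.2) of
  fragments comes from the naked-DNA process restricted to accessible
  DNA (cut weight ×0.05 under nucleosome footprints): the free DNA any
  gentle partial digest contains, and the carrier of false
  sequence-bias peaks.  Reads are 36 bp single-end from a uniformly
  random fragment end.
* **Naked arm** — cut sites drawn per base with probability proportional
  to the local cut weight (rate ≈ 1/150 bp); fragments between
  successive cuts are kept only at mononucleosome size (120–180 bp, the
  gel size selection) and emitted as reads the same way.
* The cassette used by the bias-correction studies (`free_cassette`) is
  gene- and nucleosome-free, and its sequence is re-drawn as
  mononucleosome-sized (125–165 bp) GC-rich resistant elements
  (±0.3 GC amplitude) between AT-rich spacers — protein-free DNA that
  yields nucleosome-sized fragments under digestion, the concrete
  mechanism behind false peaks at resistant promoter sequences.

What the generator does **not** model: sequencing errors, mappability,
paired-end reads, digestion kinetics/titration series, nucleosome
eviction dynamics, or realistic genome composition (isochores,
repeats).  Passing the validation studies therefore demonstrates that
the estimators recover the truth of *this* generative model at realistic
signal-to-noise, not that the method is robust to every artefact of real
libraries.

## Validation study conditions

All studies (in `mnasemap.validation`, reused by `scripts/acceptance.py`)
run on a 120 kb genome with 40 genes at bandwidth 10 bp, all randomness
derived from one seed:

* **Bias correction** — strong preference (A/T weight 4, G/C 0.25,
  gc_effect 5), 20 kb resistant cassette, coverage 50, naked 30 k
  fragments, 5 runs: cassette calls must strictly decrease after
  correction in every run with ≥ 90% of true summits elsewhere recovered
  within 20 bp on the corrected map.
* **Caller recovery** — coverage 20, jitter 30 bp, bias and background
  off, constant occupancy (the pure positional-recovery condition):
  ≥ 95% recovery within 20 bp, ≤ 5% spurious calls.
* **Fuzziness recovery** — jitter σ ∈ {10, 30, 50} bp at coverage 100,
  bias off: estimates strictly increasing and within 20% of σ.
* **Periodicity** — phased-array maps at repeats 150/165/200 bp with
  10 bp centre jitter: periodogram argmax within 3 bp; power scaling
  exact to 1e−6.
* **Oracle agreements** — Poisson tail vs pmf summation (1e−12, 1000
  pairs); the five statistical tests vs enumeration (1e−9, 20 instances
  each); UPGMA vs the naive implementation (4-leaf matrices, 20 seeds).
* **Metagene** — constant-track and mirror invariance; the profile
  minimum against the simulated NDR position.
* **Map comparison** — self-comparison gives all-zero distances;
  replicate maps join first in the UPGMA tree in 5/5 runs.
* **Determinism** — two full pipeline runs under one seed are
  byte-identical across all primary outputs.

## Numerical choices and degenerate inputs

Ties at equal peak height break leftmost.  Fuzziness of a call with no
dyads in its window is NaN and the call is flagged by `n_dyads = 0`.
Pearson correlation on zero-variance input returns NaN rather than
raising.  `ratio_normalize` masks zero denominators when the pseudocount
is 0 and reports the mask count.  z-scores use the sample (ddof = 1)
standard deviation and reject constant input.  bedGraph output merges
runs of equal value, omits zeros, and round-trips to 1e−6.  The Poisson
λ floor (0.1), the pairing threshold (74 bp), the moving-average window
(10), the cumulative-curve grid (0..500 bp) and the kernel radius
interpretation (σ = radius/3) are all explicit constants or parameters.

## Known limitations

Single-end reads only (no paired-end fragment-midpoint mode); no
model-based bias correction (the method is direct empirical
subtraction, which is its point); no sub-nucleosomal particle calling or
joint positioning; spectral peaks carry no significance test; absolute
call counts depend on the `min_height` convention (2× mean) and are not
comparable across tracks with very different signal fractions.
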