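# mnasemap

Nucleosome mapping from **partially digested MNase-seq data**, with the
sequence bias of micrococcal nuclease removed by subtracting a
**naked-DNA digestion control**.

## The problem

MNase preferentially cuts linker DNA between nucleosomes, so sequencing
mononucleosome-sized fragments maps nucleosome positions genome-wide.
Exhaustive digestion destroys the fragile (MNase-sensitive) nucleosomes
found at many promoters; gentle, partial digestion preserves them but
lets the enzyme's DNA-sequence preference through — protein-free,
MNase-resistant (typically GC-rich) sequences yield nucleosome-sized
fragments that masquerade as nucleosomes.  Digesting naked DNA with the
same enzyme measures that preference directly.  This package implements
the resulting mapping method for people analysing chromatin structure in
yeast-scale genomes:

1. reads (BED) → clonal deduplication → dyad (fragment-centre) positions
   → smoothed 1 bp dyad-density tracks;
2. depth normalization of chromatin and naked tracks to a common mass
   and pointwise subtraction, `corrected(x) = chromatin(x) − naked(x)`,
   floored at zero;
3. nucleosome calling on the corrected track: summits (density maxima,
   mean-shift refined to the dyad-cloud centroid), **occupancy** (peak
   height), **fuzziness** (population SD, in bp, of the dyads around the
   summit — the cell-to-cell positional spread), and a Poisson
   enrichment p-value of the 147 bp summit window against a background
   track;
4. downstream analyses: matched Δoccupancy / Δfuzziness between two
   conditions with Gaussian kernel-density heat maps (100 × 100 grid,
   truncation radius 30 cells), signed log-p difference curves, metagene
   profiles (genes scaled to 1000 bins, 500 bp unscaled flanks, aligned
   to TSS or pAS, stratified by promoter class / tags / transcription
   quartile), nucleosome repeat-length periodograms (power in
   amplitude-squared units over 50–400 bp periods), nearest-centre
   distance histograms with cumulative curves, and UPGMA trees over the
   Euclidean distances of those curves;
5. a synthetic-data generator producing complete experiments — genome,
   annotation, ground-truth nucleosome landscape (phased arrays, NDRs,
   per-nucleosome jitter and occupancy, fragile −1 nucleosomes), an
   MNase cut-preference model, and chromatin/naked read sampling with
   mononucleosome size selection — so every stage can be tested against
   known truth.

## Worked example

```python
import numpy as np
import mnasemap as m

genome, sizes = m.make_genome(length=120_000, gc_fraction=0.38, seed=1)
bias = m.BiasModel(weights={"A": 4.0, "T": 4.0, "C": 0.25, "G": 0.25},
                   gc_effect=5.0)
truth = m.make_landscape(genome, n_genes=40, bias=bias,
                         free_cassette=("chrI", 90_000, 110_000), seed=1)
chromatin = m.sample_chromatin_reads(truth, mean_dyads_per_nucleosome=50, seed=2)
naked = m.sample_naked_reads(truth.genome, bias, n_fragments=30_000, seed=3)

dy = m.dyads(chromatin, fragment_length=147)
chrom_track = m.smooth(dy, bandwidth=10.0, genome_lengths=truth.genome_lengths)
naked_track = m.smooth(m.dyads(naked), 10.0, truth.genome_lengths)
chrom_track, naked_track = m.normalize_depth(chrom_track, naked_track)
corrected = m.subtract_background(chrom_track, naked_track)

raw_map = m.call_nucleosomes(chrom_track, dyad_positions=dy)
cor_map = m.call_nucleosomes(corrected, dyad_positions=dy)
cor_map = m.significance(cor_map, corrected, naked_track)

cassette = lambda mp: int(np.sum((mp.summits("chrI") >= 90_000)
                                 & (mp.summits("chrI") < 110_000)))
print(f"true nucleosomes: {len(truth.nucleosomes)}")
print(f"raw map: {len(raw_map)} calls, {cassette(raw_map)} in the naked-only cassette")
print(f"corrected map: {len(cor_map)} calls, {cassette(cor_map)} in the cassette")
print(f"significant at p<0.01: {len(cor_map.significant(0.01))}")
true = truth.summits("chrI")
rec = np.mean([np.abs(cor_map.summits('chrI') - s).min() <= 20 for s in true])
print(f"true summits recovered within 20 bp: {100*rec:.1f}%")
fz = np.nanmean([n.fuzziness for n in cor_map.nucleosomes])
print(f"mean fuzziness score: {fz:.1f} bp (simulated jitter 20 bp)")
```

which prints, with the counts as on this run:

```
true nucleosomes: 404
raw map: 412 calls, 13 in the naked-only cassette
corrected map: 395 calls, 0 in the cassette
significant at p<0.01: 126
true summits recovered within 20 bp: 97.8%
mean fuzziness score: 19.4 bp (simulated jitter 20 bp)
```

The 20 kb cassette contains no nucleosomes, only MNase-resistant naked
DNA; the 13 peaks called there from the raw chromatin track are pure
sequence-bias artefacts, and all of them disappear after the naked-DNA
subtraction while 97.8% of the real nucleosomes stay correctly placed —
the method's core behaviour in miniature.

The same pipeline is available from a shell:

```bash
mnasemap simulate --outdir sim --seed 1
mnasemap tracks  --bed sim/chromatin.bed --chrom-sizes sim/genome.chrom.sizes --out chromatin.bedgraph
mnasemap tracks  --bed sim/naked.bed     --chrom-sizes sim/genome.chrom.sizes --out naked.bedgraph
mnasemap correct --chromatin chromatin.bedgraph --naked naked.bedgraph \
                 --chrom-sizes sim/genome.chrom.sizes --out corrected.bedgraph
mnasemap call    --track corrected.bedgraph --bed sim/chromatin.bed \
                 --background naked.bedgraph --chrom-sizes sim/genome.chrom.sizes --out map.tsv
```

plus `diff`, `metagene`, `spectra` and `compare-maps` subcommands for the
downstream analyses.  Every subcommand accepts `--config` (flat YAML,
unknown keys rejected), `--seed` and `--verbose`, and writes the fully
resolved configuration next to its output.

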