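# clipsplice

Tools for finding the direct targets of an RNA-binding splicing regulator by
integrating iCLIP binding data with cassette-exon splicing quantification.
The package is aimed at computational biologists analysing
protein–RNA crosslinking (iCLIP/CLIP-seq) experiments together with RNA-seq
splicing and expression data, in settings like the switch from a splicing
repressor (e.g. PTBP1) to its neuronal paralog during neuronal
differentiation.

## What it computes

**Crosslink sites.** iCLIP cDNAs truncate at the protein–RNA crosslink, so a
read aligned on the plus strand starting at genomic position *s* marks the
crosslink at *s − 1* (for a minus-strand alignment `[a, b)`, at *b*). PCR
duplicates are removed by comparing the random barcodes of reads sharing a
start position; the *height* of a site is its unique-read count.

**Positional FDR.** Within each gene, the gene's total crosslink events *T*
are re-placed uniformly over the gene span in each of *P* permutations, and
for an observed height *h*

&nbsp;&nbsp;&nbsp;&nbsp;FDR(*h*) = E<sub>perm</sub>[#positions with height ≥ *h*] / #observed positions with height ≥ *h*,

capped at 1. Sites with FDR < 0.01 are *significant*; each is extended
20 nt on both sides and overlapping extensions are merged into clusters,
which are kept when they contain ≥ 4 significant reads.

**Motif enrichment.** Sense-strand sequence ±30 nt around each significant
intronic site is scanned for all 1024 pentamers; the null redraws one
same-width interval per window uniformly from the same intron, and
*Z* = (observed − null mean)/null sd ranks the pentamers.

**Differential splicing.** A cassette exon's percent spliced in is estimated
from its junction evidence — upstream/downstream inclusion reads I1, I2 and
skipping reads E — as PSI = 100·m/(m+E) with m = (I1+I2)/2, after pooling
replicates. ΔPSI between conditions is filtered at a two-sided Fisher exact
p < 0.05 and |ΔPSI| ≥ 15 percent points; the quadrant of (knockdown ΔPSI,
differentiation ΔPSI) classifies exons as regulator-repressed or -activated.

**Direct targets and enrichment.** An exon is a *direct target* when it is
knockdown-responsive, changes concordantly during differentiation, and has a
filtered cluster within the exon or the 500-nt intron flanks. Set overlaps
(binding vs response, ChIP occupancy within 1 kb of a gene vs induced genes,
with induction defined by fold-change cutoffs of 2.0/1.5 on mean FPKM plus
Welch's t-test p < 0.05) are scored with the upper-tail hypergeometric test.

A synthetic-data module (`clipsplice.simulate`) generates genome, annotation,
truncation-model iCLIP reads with PCR duplication and random barcodes,
binomial junction counts, log-normal FPKM tables and ChIP clusters — all with
a ground-truth manifest — so the full pipeline runs end to end with no
external data.

## Worked example

```python
from clipsplice import SimulationConfig, run_pipeline

result = run_pipeline(sim_config=SimulationConfig(seed=1), seed=1)
s = result.summary
print(s["n_unique_reads"], s["n_significant_sites"], s["top_pentamer"])
print(s["n_direct_targets"], s["n_direct_repressed"], s["n_direct_activated"])
print(round(s["direct_target_sensitivity"], 3), round(s["direct_target_precision"], 3))
```

prints

```
6024 65 TCTCT
55 40 15
1.0 1.0
```

i.e. 12,021 simulated reads collapse to 6,024 unique molecules; 65 crosslink
positions are significant at FDR < 0.01 and the planted CU-rich pentamer
TCTCT ranks first of 1024 by Z-score; intersecting knockdown response,
differentiation change and binding yields 55 direct targets (40 repressed,
15 activated), recovering the planted target set with sensitivity and
precision 1.0. The same run is available from the shell:

```bash
clipsplice run-all --out-dir scratch/demo --seed 1
```

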