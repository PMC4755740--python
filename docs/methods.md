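# Methods

## Coordinate model

All intervals are 0-based half-open internally; GTF I/O converts to and from
the 1-based inclusive dialect and BED is native. "Upstream" and "downstream"
are defined in transcript orientation throughout, because intron positions
relative to a cassette exon are properties of the pre-mRNA, not of the
reference strand. One transcript model is kept per gene — the transcript
with the greatest total exonic length — and every internal exon of that
model is enumerated as a candidate cassette trio. Interval merging requires
a genuine shared nucleotide; abutting intervals are kept separate, so two
significant sites exactly 41 nt apart produce two clusters, not one.

## Crosslink-site calling

The truncation model places the crosslink one nucleotide 5' (transcript
orientation) of the read start: position `start − 1` for plus-strand reads
and, by the mirror-image argument, position `end` for a minus-strand
alignment `[a, b)`. PCR deduplication collapses reads sharing (chromosome,
transcript-orientation start, strand, barcode); it deliberately ignores the
3' end, since fragment-length variation among copies of one molecule is a
library artifact.

The positional FDR is a per-gene permutation test. Let T be the gene's total
unique-read crosslink events and L its span (exons plus introns). Each of
`n_perm = 100` permutations places T events uniformly over the L positions;
for every observed height h the FDR is the ratio of the mean permuted to the
observed number of positions with height ≥ h, capped at 1. Counting tails
(≥ h) makes the estimate non-increasing in h by construction, so no separate
monotonicity correction is needed. The uniform-placement null treats the
whole gene span as eligible sequence; a null restricted to exonic/transcript
sequence would be stricter for intron-poor genes, and this choice is the
package's own (the randomization region is a free parameter of this class of
methods). Sites that fall in no gene model are reported separately and not
tested. Significance is FDR < 0.01; significant sites extended ±20 nt merge
into clusters, and clusters need ≥ 4 significant *reads* (summed member
heights, not a site count) to survive filtering.

## Pentamer enrichment

Windows are the sense-strand sequence ±30 nt around each significant site,
clipped to the host intron; exonic and unassignable sites are excluded so
the observed and null sequence pools are drawn from the same composition
stratum. The null re-draws, `n_rand = 100` times, one uniform same-width
interval per window from the same intron. Z-scores are
(observed − null mean)/null sd with overlapping 5-mer counting at step 1.
When the null sd is zero the score is 0 if the observed count equals the
constant null, otherwise a signed infinity flagged `degenerate` — this only
arises for tiny `n_rand` or pathological sequence and is excluded from
summary statistics by the flag. Pentamers are reported in the DNA alphabet;
a motif printed as UCUCU elsewhere corresponds to TCTCT here.

## PSI and differential splicing

The PSI estimator is the standard trio-evidence ratio
`100·m/(m+E)`, `m = (I1+I2)/2`, on replicate-pooled counts; pooling (rather
than a replicate-level model) matches the low-replicate design the junction
tables come from. Under the generator's binomial model (I1 = I2 = x,
E = n − x with x ~ Bin(n, ψ)) the estimator is exactly unbiased. The
significance test is a two-sided Fisher exact test on the 2×2 table of
rounded inclusion evidence m versus E across the two conditions — an
intentionally simple stand-in where no test is canonically defined for this
evidence type — and events pass at p < 0.05 and |ΔPSI| ≥ 15 percent points.
No multiple-testing correction is applied to splicing p-values; the filter
is a raw per-event threshold, which the calibration benchmark quantifies
(null false-pass rate ≤ 8 % at depth 200, in practice ≪ 1 % because the
|ΔPSI| cutoff dominates). Quadrant classification uses the sign conventions
kd ΔPSI = knockdown − control and diff ΔPSI = differentiated − progenitor,
so "repressed" means inclusion rises when the regulator is removed *and*
during differentiation.

## Integration

Binding association requires ≥ 1 nt overlap between a filtered cluster on
the host gene's strand and the cassette exon or its 500-nt intron flanks
(clipped at the neighbouring exons); antisense clusters are tabulated but
never confer binding. Direct targets are the conjunction of knockdown
response, differentiation change and binding, with discordant directions
excluded and counted. Expression changes use fold = mean(test)/mean(reference)
with both means floored at 0.1 FPKM (avoids division by zero while leaving
well-expressed genes' ratios exact), Welch's unequal-variance t-test
(two groups with zero variance: p = 1 when means are equal, else p = 0),
and cutoffs 2.0 and 1.5. "Expressed" genes are those with mean FPKM ≥ 1 in
either group. ChIP binding is strand-agnostic overlap with the gene span
± 1 kb. All overlap enrichments are raw upper-tail hypergeometric p-values.

## Synthetic data: what it emulates and what it does not

The generator writes, from one seed, a single-chromosome genome with
`n_genes = 300` five-exon genes (exons 90–180 nt, introns 1100–2500 nt —
long enough that both 500-nt flanks and motif windows always fit), one
measured cassette event per gene, and a planted event-class structure:
40 direct repressed and 15 direct activated targets (bound, knockdown and
differentiation ΔPSI of ±30 pp), 10 bound-but-unresponsive and 20
responsive-but-unbound decoys, the rest unchanged. 65 binding sites are
planted in the 500-nt flanks of bound events with two copies of the CU-rich
pentamer TCTCT written into the sense strand inside the ±30-nt window.
iCLIP molecules per site are Poisson(20), background reads are uniform over
gene spans at 2 reads/kb, PCR adds Poisson(1) extra copies per molecule, and
9-nt barcodes are drawn uniformly with collisions at a shared position
redrawn, so deduplication recovers the molecule count exactly and the
manifest records it. Junction depth is Poisson(200) per replicate (2
replicates, 4 conditions); FPKM tables are log-normal (log-sd 1.0 across
genes, 0.15 across replicates; 3 reference vs 5 test replicates) with
planted folds 4.0/1.7/0.25; ChIP clusters bind 15 % of genes, boosted 3×
among induced genes, with 10 decoy clusters placed ≥ 2 kb from any gene.

Deliberately not modelled: sequence composition bias and mappability,
crosslinking sequence preference beyond the planted motif, overdispersion
in junction and expression counts, multi-isoform genes, overlapping genes,
and read-level RNA-seq. Passing the recovery benchmarks therefore shows the
pipeline's logic and calibration are correct under its stated assumptions,
not that real libraries — with their correlated noise and annotation
imperfections — would yield these sensitivities.

## Problem sizes and numerical choices

The default benchmark scale (300 genes, ~12k reads, 100 permutations, 100
null replicates, 1000-event estimator checks, 20-seed FDR calibration) was
chosen as the smallest scale at which the planted effects are comfortably
identifiable by the statistics involved; the whole suite runs in well under
a minute. Fisher tables round m to an integer; PSI is kept in percent
throughout; hypergeometric tails use the survival function at k − 1;
cluster member assignment is by site position within the merged interval.
Degenerate inputs (zero support, constant PSI vectors, empty read files,
zero-variance expression) return explicit `None`/NaN/convention values
rather than raising, and every skip is counted and reported in the summary.

## Known limitations

* The permutation FDR ignores local sequence/structure biases within a gene;
  heights at neighbouring positions are treated as exchangeable.
* The Fisher test on pooled counts understates replicate variability; with
  only two replicates per condition this is a pragmatic, documented choice.
* Cluster-to-event association attributes any same-strand cluster in the
  window to the event, without apportioning clusters shared between
  neighbouring events (impossible by construction in the synthetic data,
  possible in dense real annotations).
* The expressed-gene threshold (mean FPKM ≥ 1) and the 0.1-FPKM floor are
  conventions; enrichment p-values shift with the population definition.
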