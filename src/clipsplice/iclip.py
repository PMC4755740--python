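"""From barcode-bearing iCLIP reads to significant crosslink sites, clusters
and pentamer motif enrichment.

The iCLIP truncation model places the protein-RNA crosslink one nucleotide
upstream (in transcript orientation) of the read start, so a plus-strand read
starting at genomic ``s`` marks position ``s - 1`` and a minus-strand
alignment ``[a, b)`` marks position ``b``.  Sites are scored by the number of
unique (deduplicated) reads supporting them and tested with a per-gene
positional permutation FDR; sites at FDR < 0.01 are extended 20 nt on either
side and merged into clusters.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from clipsplice.core import PLUS, MINUS, GeneModel, GenomicInterval, merge_intervals

SIGNIFICANCE_FDR = 0.01
ALPHABET = "ACGT"
N_PENTAMERS = 4 ** 5

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IclipRead:
    """A mapped iCLIP read with its experimental random barcode."""

    alignment: GenomicInterval
    random_barcode: str
    read_id: str = ""


@dataclass
class DedupStats:
    n_input: int = 0
    n_duplicates_removed: int = 0
    n_missing_barcode: int = 0


@dataclass
class CrosslinkSite:
    """A single-nucleotide crosslink position with unique-read height."""

    chrom: str
    position: int
    strand: str
    height: int
    fdr: float | None = None

    @property
    def significant(self) -> bool:
        return self.fdr is not None and self.fdr < SIGNIFICANCE_FDR


@dataclass
class SiteCluster:
    """Merged union of significant sites extended 20 nt on both sides."""

    interval: GenomicInterval
    member_sites: list[CrosslinkSite] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def significant_read_total(self) -> int:
        return sum(s.height for s in self.member_sites)


@dataclass
class PentamerStat:
    pentamer: str
    observed_count: int
    null_mean: float
    null_sd: float
    z: float
    degenerate: bool = False  # null_sd == 0 with observed != null_mean


def _tx_start(read: IclipRead) -> int:
    """5' end of the alignment in transcript orientation."""
    iv = read.alignment
    return iv.start if iv.strand == PLUS else iv.end


def deduplicate(reads: Iterable[IclipRead]) -> tuple[list[IclipRead], DedupStats]:
    """Collapse PCR duplicates by comparing the random barcodes.

    Reads sharing (chrom, transcript-orientation start, strand, barcode)
    collapse to one; all other reads are retained.  Reads without a barcode
    are rejected and counted.  Output order is deterministic (sorted).
    """
    stats = DedupStats()
    seen: dict[tuple, IclipRead] = {}
    for read in reads:
        stats.n_input += 1
        if not read.random_barcode:
            stats.n_missing_barcode += 1
            continue
        key = (read.alignment.chrom, _tx_start(read), read.alignment.strand, read.random_barcode)
        if key in seen:
            stats.n_duplicates_removed += 1
        else:
            seen[key] = read
    unique = sorted(
        seen.values(),
        key=lambda r: (
            r.alignment.chrom,
            r.alignment.start,
            r.alignment.end,
            r.alignment.strand,
            r.random_barcode,
        ),
    )
    return unique, stats


def call_crosslink_sites(
    unique_reads: Iterable[IclipRead],
) -> tuple[list[CrosslinkSite], int]:
    """Aggregate unique reads into crosslink sites with heights.

    Returns the sites (FDR unset) and the count of reads skipped because the
    crosslink position would fall before the start of the contig.
    """
    heights: dict[tuple[str, int, str], int] = {}
    n_skipped = 0
    for read in unique_reads:
        iv = read.alignment
        pos = iv.start - 1 if iv.strand == PLUS else iv.end
        if pos < 0:
            n_skipped += 1
            continue
        key = (iv.chrom, pos, iv.strand)
        heights[key] = heights.get(key, 0) + 1
    sites = [
        CrosslinkSite(chrom=c, position=p, strand=s, height=h)
        for (c, p, s), h in sorted(heights.items())
    ]
    return sites, n_skipped


class _GeneIndex:
    """Locate the host gene of a position by (chrom, strand) bisection."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[tuple[int, GeneModel]]]] = {}
        for gene in genes:
            span = gene.span
            key = (gene.chrom, gene.strand)
            self._by_key.setdefault(key, ([], []))
        for gene in sorted(genes, key=lambda g: g.span.start):
            span = gene.span
            starts, entries = self._by_key[(gene.chrom, gene.strand)]
            starts.append(span.start)
            entries.append((span.end, gene))

    def find(self, chrom: str, position: int, strand: str) -> GeneModel | None:
        got = self._by_key.get((chrom, strand))
        if not got:
            return None
        starts, entries = got
        i = bisect.bisect_right(starts, position) - 1
        if i >= 0 and position < entries[i][0]:
            return entries[i][1]
        return None


def assign_site_fdr(
    sites: Sequence[CrosslinkSite],
    gene_models: Sequence[GeneModel],
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[list[CrosslinkSite], list[CrosslinkSite]]:
    """Assign a positional permutation FDR to every crosslink site.

    Within each gene, the gene's total crosslink events T (sum of site
    heights) are re-placed uniformly at random over the gene span in each of
    ``n_perm`` permutations.  For an observed height h,

        FDR(h) = mean permuted #positions with height >= h
                 / observed #positions with height >= h,   capped at 1.

    Tail counting at >= h makes FDR(h) non-increasing in h by construction.
    Sites not assignable to any gene model (matching chrom and strand) are
    returned separately with FDR unset and are excluded from the test.

    Returns (annotated sites, unannotated sites).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    index = _GeneIndex(gene_models)

    per_gene: dict[str, list[CrosslinkSite]] = {}
    gene_by_id = {g.gene_id: g for g in gene_models}
    unannotated: list[CrosslinkSite] = []
    for site in sites:
        gene = index.find(site.chrom, site.position, site.strand)
        if gene is None:
            unannotated.append(site)
        else:
            per_gene.setdefault(gene.gene_id, []).append(site)

    annotated: list[CrosslinkSite] = []
    for gene_id, gsites in per_gene.items():
        gene = gene_by_id[gene_id]
        length = gene.span.width
        heights = np.array([s.height for s in gsites], dtype=np.int64)
        total_events = int(heights.sum())
        uniq = np.unique(heights)
        observed_ge = np.array([(heights >= h).sum() for h in uniq], dtype=np.float64)
        max_h = int(uniq.max())
        permuted_ge = np.zeros(len(uniq), dtype=np.float64)
        for _ in range(n_perm):
            placed = rng.integers(0, length, size=total_events)
            counts = np.bincount(placed, minlength=length)
            hist = np.bincount(counts, minlength=max_h + 1)
            hist[0] = 0  # unoccupied positions are not sites
            tail = np.cumsum(hist[::-1])[::-1]  # tail[h] = #positions with count >= h
            for j, h in enumerate(uniq):
                permuted_ge[j] += tail[h] if h <= max_h else 0
        fdr_by_height = {
            int(h): min(1.0, (permuted_ge[j] / n_perm) / observed_ge[j])
            for j, h in enumerate(uniq)
        }
        for s in gsites:
            s.fdr = fdr_by_height[s.height]
            annotated.append(s)
    annotated.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return annotated, unannotated


def build_clusters(
    significant_sites: Sequence[CrosslinkSite], extension: int = 20
) -> list[SiteCluster]:
    """Extend significant sites ``extension`` nt on both sides and merge
    overlapping extensions into clusters, separately per chromosome/strand."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    groups: dict[tuple[str, str], list[CrosslinkSite]] = {}
    for site in significant_sites:
        if not site.significant:
            raise ValueError(
                f"non-significant site at {site.chrom}:{site.position} passed to build_clusters"
            )
        groups.setdefault((site.chrom, site.strand), []).append(site)

    clusters: list[SiteCluster] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda s: s.position)
        extended = [
            GenomicInterval(chrom, max(0, s.position - extension), s.position + extension + 1, strand)
            for s in members
        ]
        merged = merge_intervals(extended)
        i = 0
        for iv in merged:
            cluster = SiteCluster(interval=iv)
            while i < len(members) and members[i].position < iv.end:
                cluster.member_sites.append(members[i])
                i += 1
            clusters.append(cluster)
    return clusters


def filter_clusters(clusters: Iterable[SiteCluster], min_reads: int = 4) -> list[SiteCluster]:
    """Keep clusters supported by at least ``min_reads`` significant reads
    (summed unique-read heights of the member sites)."""
    return [c for c in clusters if c.significant_read_total >= min_reads]


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    piece = seq[start:end]
    return str(piece).upper()


def _count_pentamers(seq: str, out: np.ndarray) -> None:
    """Add overlapping 5-mer occurrences of ``seq`` into ``out`` (len 1024)."""
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    vals = [codes.get(b, -1) for b in seq]
    for i in range(len(vals) - 4):
        window = vals[i : i + 5]
        if -1 in window:
            continue
        code = 0
        for v in window:
            code = code * 4 + v
        out[code] += 1


def pentamer_from_code(code: int) -> str:
    out = []
    for _ in range(5):
        out.append(ALPHABET[code % 4])
        code //= 4
    return "".join(reversed(out))


def pentamer_zscores(
    sites: Sequence[CrosslinkSite],
    genome: Mapping[str, object],
    gene_models: Sequence[GeneModel],
    window: int = 30,
    n_rand: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[list[PentamerStat], int]:
    """Pentamer enrichment in crosslink-site windows vs intron-matched nulls.

    For each site inside an intron, the sense-strand sequence ``window`` nt
    either side of the site (clipped to the host intron) is scanned for all
    overlapping 5-mers.  The null re-draws, ``n_rand`` times, one random
    same-width interval per observed window uniformly from the same intron.
    Z = (observed - null mean) / null sd per pentamer; a pentamer whose null
    sd is zero gets z = 0 when observed equals the mean and a signed infinity
    with ``degenerate=True`` otherwise.

    Returns the 1024 stats sorted by descending z, plus the number of sites
    skipped (outside any intron of their host gene, or unassignable).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    index = _GeneIndex(gene_models)

    # (intron, clipped window) per usable site
    placements: list[tuple[GenomicInterval, int, int, str]] = []
    n_skipped = 0
    for site in sites:
        gene = index.find(site.chrom, site.position, site.strand)
        intron = None
        if gene is not None:
            for cand in gene.introns:
                if cand.contains(site.position):
                    intron = cand
                    break
        if intron is None:
            n_skipped += 1
            continue
        lo = max(intron.start, site.position - window)
        hi = min(intron.end, site.position + window + 1)
        if hi - lo < 5:
            n_skipped += 1
            continue
        placements.append((intron, lo, hi, site.strand))

    observed = np.zeros(N_PENTAMERS, dtype=np.int64)
    for intron, lo, hi, strand in placements:
        seq = _fetch(genome, intron.chrom, lo, hi)
        if strand == MINUS:
            seq = revcomp(seq)
        _count_pentamers(seq, observed)

    null_counts = np.zeros((n_rand, N_PENTAMERS), dtype=np.int64)
    for r in range(n_rand):
        row = null_counts[r]
        for intron, lo, hi, strand in placements:
            w = hi - lo
            start = int(rng.integers(intron.start, intron.end - w + 1))
            seq = _fetch(genome, intron.chrom, start, start + w)
            if strand == MINUS:
                seq = revcomp(seq)
            _count_pentamers(seq, row)

    null_mean = null_counts.mean(axis=0)
    null_sd = null_counts.std(axis=0, ddof=0)

    stats: list[PentamerStat] = []
    for code in range(N_PENTAMERS):
        obs = int(observed[code])
        mu, sd = float(null_mean[code]), float(null_sd[code])
        degenerate = False
        if sd == 0.0:
            if obs == mu:
                z = 0.0
            else:
                z = math.inf if obs > mu else -math.inf
                degenerate = True
        else:
            z = (obs - mu) / sd
        stats.append(
            PentamerStat(
                pentamer=pentamer_from_code(code),
                observed_count=obs,
                null_mean=mu,
                null_sd=sd,
                z=z,
                degenerate=degenerate,
            )
        )
    stats.sort(key=lambda s: (-s.z, s.pentamer))
    return stats, n_skipped
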