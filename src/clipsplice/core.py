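"""Genomic coordinate arithmetic and the gene / cassette-exon data model.

Coordinates are 0-based half-open internally.  GTF I/O converts from and to
the 1-based inclusive GTF dialect; BED I/O is native 0-based half-open.
"Upstream" and "downstream" are always meant in transcript orientation
(strand-aware), matching how intron positions relative to an exon are
described on the pre-mRNA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand.

    ``start == end`` represents an explicitly empty interval (used e.g. for
    zero-length flanks); empty intervals are never written to output files.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.chrom}:{self.start}-{self.end}")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start <= end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.start == self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one nucleotide.

        Strand is ignored here; callers that need same-strand overlap check
        strand themselves (ChIP windows, for instance, are strand-agnostic).
        """
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class GeneModel:
    """One transcript model per gene: ordered exons plus derived introns.

    ``exons`` are stored in transcript orientation (5' to 3'), so on the
    minus strand genomic starts are descending.
    """

    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        strands = {e.strand for e in self.exons}
        chroms = {e.chrom for e in self.exons}
        if len(strands) != 1 or len(chroms) != 1:
            raise ValueError(f"gene {self.gene_id}: exons on mixed chrom/strand")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        # normalize to transcript orientation
        self.exons = genomic if self.strand == PLUS else genomic[::-1]

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in transcript orientation."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if self.strand == PLUS else (b.end, a.start)
            out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out


@dataclass(frozen=True)
class CassetteEventAnnotation:
    """Upstream / cassette / downstream exon trio, in transcript orientation."""

    event_id: str
    gene_id: str
    upstream_exon: GenomicInterval
    cassette_exon: GenomicInterval
    downstream_exon: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        trio = (self.upstream_exon, self.cassette_exon, self.downstream_exon)
        if self.strand == PLUS:
            ordered = all(a.end < b.start for a, b in zip(trio, trio[1:]))
        else:
            ordered = all(b.end < a.start for a, b in zip(trio, trio[1:]))
        if not ordered:
            raise ValueError(
                f"event {self.event_id}: exon trio not ordered with nonempty introns"
            )

    @property
    def chrom(self) -> str:
        return self.cassette_exon.chrom

    @property
    def upstream_intron(self) -> GenomicInterval:
        """Intron between the upstream and the cassette exon."""
        if self.strand == PLUS:
            lo, hi = self.upstream_exon.end, self.cassette_exon.start
        else:
            lo, hi = self.cassette_exon.end, self.upstream_exon.start
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def downstream_intron(self) -> GenomicInterval:
        """Intron between the cassette and the downstream exon."""
        if self.strand == PLUS:
            lo, hi = self.cassette_exon.end, self.downstream_exon.start
        else:
            lo, hi = self.downstream_exon.end, self.cassette_exon.start
        return GenomicInterval(self.chrom, lo, hi, self.strand)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge genuinely overlapping intervals into disjoint ones.

    Overlap means sharing >= 1 nt; abutting intervals (zero gap) stay
    separate.  All intervals must lie on one chromosome and strand.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"merge_intervals: mixed chromosomes {sorted(chroms)}")
    if len(strands) > 1:
        raise ValueError(f"merge_intervals: mixed strands {sorted(strands)}")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start < last.end:  # strict overlap only
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


FLANK_SIDES = ("upstream_intron", "downstream_intron", "exon_body")


def flank(event: CassetteEventAnnotation, side: str, length: int) -> GenomicInterval:
    """Strand-aware flank of a cassette exon, clipped to the host intron.

    ``upstream_intron`` / ``downstream_intron`` give up to ``length`` nt of
    intron sequence adjacent to the cassette exon on its transcript-5' /
    transcript-3' side; ``exon_body`` returns the cassette exon itself.
    ``length == 0`` yields an explicitly empty interval at the exon edge.
    """
    if side not in FLANK_SIDES:
        raise ValueError(f"unrecognized flank side {side!r}; expected one of {FLANK_SIDES}")
    if length < 0:
        raise ValueError("flank length must be >= 0")
    ce = event.cassette_exon
    if side == "exon_body":
        return ce
    intron = event.upstream_intron if side == "upstream_intron" else event.downstream_intron
    take = min(length, intron.width)
    # the flank hugs the cassette-exon end of the intron
    exon_side_is_intron_end = (event.strand == PLUS) == (side == "upstream_intron")
    if exon_side_is_intron_end:
        return GenomicInterval(event.chrom, intron.end - take, intron.end, event.strand)
    return GenomicInterval(event.chrom, intron.start, intron.start + take, event.strand)


# ---------------------------------------------------------------------------
# annotation I/O


def _enumerate_cassette_events(gene: GeneModel) -> list[CassetteEventAnnotation]:
    events = []
    for i in range(1, len(gene.exons) - 1):
        events.append(
            CassetteEventAnnotation(
                event_id=f"{gene.gene_id}.ce{i}",
                gene_id=gene.gene_id,
                upstream_exon=gene.exons[i - 1],
                cassette_exon=gene.exons[i],
                downstream_exon=gene.exons[i + 1],
                strand=gene.strand,
            )
        )
    return events


def read_gene_models(
    annotation: str | io.TextIOBase,
) -> tuple[list[GeneModel], list[CassetteEventAnnotation]]:
    """Read GTF exon annotation into gene models and cassette-event trios.

    ``annotation`` is a path, GTF text, or an open text handle.  One model is
    kept per gene: the transcript with the largest total exonic length.
    Every internal exon of a model becomes a candidate cassette event named
    ``<gene_id>.ce<i>`` (``i`` = exon index in transcript orientation).

    Raises ``ValueError`` with the offending record identifier for malformed
    coordinates (start >= end after dialect conversion) or unknown strands.
    """
    if hasattr(annotation, "read"):
        text = annotation.read()
    elif "\n" in annotation or annotation.strip() == "":
        text = annotation
    else:
        with open(annotation) as fh:
            text = fh.read()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return [], []

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    # exons grouped per transcript, transcripts grouped per gene
    by_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    for ex in db.features_of_type("exon"):
        gene_id = ex.attributes.get("gene_id", [None])[0]
        tx_id = ex.attributes.get("transcript_id", [gene_id])[0]
        if gene_id is None:
            raise ValueError(f"exon at {ex.seqid}:{ex.start}-{ex.end} lacks gene_id")
        if ex.strand not in STRANDS:
            raise ValueError(f"unknown strand {ex.strand!r} in record {tx_id}")
        start0, end0 = ex.start - 1, ex.end  # GTF 1-based inclusive -> half-open
        if start0 >= end0 or start0 < 0:
            raise ValueError(f"malformed coordinates in record {tx_id}: {ex.start}-{ex.end}")
        by_gene.setdefault(gene_id, {}).setdefault(tx_id, []).append(
            GenomicInterval(ex.seqid, start0, end0, ex.strand)
        )

    genes: list[GeneModel] = []
    events: list[CassetteEventAnnotation] = []
    for gene_id in sorted(by_gene):
        transcripts = by_gene[gene_id]
        # longest transcript = largest total exonic length; ties broken by id
        best_tx = max(
            sorted(transcripts),
            key=lambda t: sum(iv.width for iv in transcripts[t]),
        )
        model = GeneModel(gene_id=gene_id, exons=transcripts[best_tx])
        genes.append(model)
        events.extend(_enumerate_cassette_events(model))
    return genes, events


def write_gtf(genes: Iterable[GeneModel], path_or_handle) -> None:
    """Write gene models as GTF exon features (1-based inclusive)."""
    own = isinstance(path_or_handle, (str, bytes))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for gene in genes:
            tx = f"{gene.gene_id}.t1"
            for iv in sorted(gene.exons, key=lambda e: e.start):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx}";'
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "clipsplice",
                            "exon",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    finally:
        if own:
            fh.close()
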