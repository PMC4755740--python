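"""Readers and writers for the pipeline's file formats.

BED is native 0-based half-open; iCLIP reads travel as BED6 with the random
barcode appended to the name field (``readID#BARCODE``).  Junction counts and
FPKM tables are tab-delimited with headers.  FASTA goes through Biopython.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from clipsplice.core import GenomicInterval
from clipsplice.iclip import CrosslinkSite, IclipRead, PentamerStat, SiteCluster
from clipsplice.splicing import JunctionCounts

JUNCTION_COLUMNS = ["event_id", "condition", "replicate", "I1", "I2", "E"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_bed6(path) -> list[GenomicInterval]:
    intervals = []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
        comment="#",
    )
    for row in df.itertuples(index=False):
        intervals.append(GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand))
    return intervals


def write_bed6(
    intervals: Sequence[GenomicInterval],
    path,
    names: Sequence[str] | None = None,
    scores: Sequence[object] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_iclip_bed(path) -> list[IclipRead]:
    """BED6 reads whose name field carries ``readID#BARCODE``."""
    reads = []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    for row in df.itertuples(index=False):
        name = row.name
        read_id, _, barcode = name.partition("#")
        reads.append(
            IclipRead(
                alignment=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                random_barcode=barcode,
                read_id=read_id,
            )
        )
    return reads


def write_iclip_bed(reads: Iterable[IclipRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.alignment
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}#{r.random_barcode}\t0\t{iv.strand}\n"
            )


def write_sites_bed(sites: Sequence[CrosslinkSite], path) -> None:
    """Sites as single-nt BED6: score = height, name carries the FDR."""
    with open(path, "w") as fh:
        for s in sites:
            fdr = "NA" if s.fdr is None else f"{s.fdr:.6g}"
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\tfdr={fdr}\t{s.height}\t{s.strand}\n"
            )


def read_sites_bed(path) -> list[CrosslinkSite]:
    """Inverse of :func:`write_sites_bed`."""
    sites = []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    for row in df.itertuples(index=False):
        fdr_text = row.name.removeprefix("fdr=")
        fdr = None if fdr_text == "NA" else float(fdr_text)
        sites.append(
            CrosslinkSite(
                chrom=row.chrom,
                position=int(row.start),
                strand=row.strand,
                height=int(row.score),
                fdr=fdr,
            )
        )
    return sites


def write_clusters_bed(clusters: Sequence[SiteCluster], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster{i}\t{c.significant_read_total}\t{iv.strand}\n"
            )


def write_pentamer_table(stats: Sequence[PentamerStat], path) -> None:
    """Tab-delimited pentamer stats, sorted by z descending."""
    rows = sorted(stats, key=lambda s: (-s.z, s.pentamer))
    with open(path, "w") as fh:
        fh.write("pentamer\tobserved\tnull_mean\tnull_sd\tz\n")
        for s in rows:
            fh.write(f"{s.pentamer}\t{s.observed_count}\t{s.null_mean:.4f}\t{s.null_sd:.4f}\t{s.z:.4f}\n")


def read_junction_table(path) -> list[JunctionCounts]:
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    return [
        JunctionCounts(
            event_id=str(r.event_id),
            condition=str(r.condition),
            replicate=int(r.replicate),
            inclusion_upstream=int(r.I1),
            inclusion_downstream=int(r.I2),
            exclusion=int(r.E),
        )
        for r in df.itertuples(index=False)
    ]


def write_junction_table(counts: Iterable[JunctionCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(JUNCTION_COLUMNS) + "\n")
        for c in counts:
            fh.write(
                f"{c.event_id}\t{c.condition}\t{c.replicate}\t"
                f"{c.inclusion_upstream}\t{c.inclusion_downstream}\t{c.exclusion}\n"
            )


def read_fpkm_table(path) -> pd.DataFrame:
    """Gene-by-replicate FPKM table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_fpkm_table(fpkm: pd.DataFrame, path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")
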