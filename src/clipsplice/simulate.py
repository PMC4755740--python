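"""Synthetic genome, annotation, iCLIP reads, junction counts, expression
tables and ChIP clusters with a known ground truth.

The generator emulates the data-generating assumptions of the analysis:

* truncation-model iCLIP reads that start one nucleotide downstream (in
  transcript orientation) of a planted crosslink site, PCR-amplified with
  random barcodes, over a uniform background of non-specific reads;
* a CU-rich pentamer written into the genome around each planted site, so
  motif enrichment has a planted positive;
* binomial inclusion/exclusion junction counts at specified true PSI per
  condition, so the PSI estimator is unbiased by construction;
* log-normal FPKM replicate tables with planted fold-changes;
* ChIP clusters within 1 kb of a chosen gene subset, enriched among the
  expression-induced genes.

All randomness flows from a single seed; equal seeds give byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from clipsplice.core import (
    MINUS,
    PLUS,
    CassetteEventAnnotation,
    GeneModel,
    GenomicInterval,
    flank,
    write_gtf,
)
from clipsplice.iclip import IclipRead, revcomp
from clipsplice.splicing import JunctionCounts
from clipsplice import io as csio

CONTROL, KNOCKDOWN = "control", "knockdown"
PROGENITOR, NEURONAL = "progenitor", "neuronal"
CONDITIONS = (CONTROL, KNOCKDOWN, PROGENITOR, NEURONAL)

# ground-truth event classes
DIRECT_REPRESSED = "direct_repressed"
DIRECT_ACTIVATED = "direct_activated"
BOUND_UNRESPONSIVE = "bound_unresponsive"
RESPONSIVE_UNBOUND = "responsive_unbound"
UNCHANGED = "unchanged"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (desk scale by default)."""

    n_genes: int = 300
    n_exons_per_gene: int = 5
    exon_length_range: tuple[int, int] = (90, 180)
    intron_length_range: tuple[int, int] = (1100, 2500)
    intergenic_gap: int = 6000
    n_cassette_events: int = 300  # one (middle-exon) event per gene, at most n_genes

    # planted event classes (counts drawn from the cassette events)
    n_direct_repressed: int = 40
    n_direct_activated: int = 15
    n_bound_unresponsive: int = 10
    n_responsive_unbound: int = 20
    planted_dpsi: float = 30.0  # percent points, knockdown and differentiation

    # junction-count model
    junction_depth: int = 200  # expected junction reads per event/condition/replicate
    n_junction_replicates: int = 2

    # iCLIP model
    n_binding_sites: int = 65  # >= number of bound events; extras spread round-robin
    binding_site_motif: str = "TCTCT"
    iclip_site_read_mean: float = 20.0
    background_read_rate: float = 2.0  # reads per kb of gene span
    read_length: int = 30
    pcr_duplication_rate: float = 1.0  # expected extra copies per unique molecule
    barcode_random_length: int = 9

    # expression model (log-normal FPKM)
    n_induced_strong: int = 30  # planted fold 4.0
    n_induced_weak: int = 20  # planted fold 1.7
    n_repressed_expression: int = 10  # planted fold 0.25
    fpkm_log_mean: float = 3.0
    fpkm_log_sd: float = 1.0
    replicate_log_sd: float = 0.15
    n_reference_replicates: int = 3
    n_test_replicates: int = 5

    # ChIP model
    chip_bound_fraction: float = 0.15
    chip_induced_boost: float = 3.0
    n_chip_decoys: int = 10  # clusters >= 2 kb from any gene, never assigned

    seed: int = 0

    def validate(self) -> None:
        if self.n_cassette_events > self.n_genes:
            raise ValueError("n_cassette_events cannot exceed n_genes (one event per gene)")
        if self.n_exons_per_gene < 3:
            raise ValueError("genes need >= 3 exons to host a cassette event")
        if self.exon_length_range[0] < 10 or self.exon_length_range[0] > self.exon_length_range[1]:
            raise ValueError(f"infeasible exon length range {self.exon_length_range}")
        n_bound = self.n_direct_repressed + self.n_direct_activated + self.n_bound_unresponsive
        if self.intron_length_range[0] < 2 * 500 + 100 and n_bound > 0:
            raise ValueError(
                "intron_length_range too short: flank-bound events need introns >= 1100 nt "
                "so both 500-nt flanks and motif windows are well-defined"
            )
        if self.intron_length_range[0] > self.intron_length_range[1]:
            raise ValueError(f"infeasible intron length range {self.intron_length_range}")
        n_classed = n_bound + self.n_responsive_unbound
        if n_classed > self.n_cassette_events:
            raise ValueError("planted event classes exceed n_cassette_events")
        if n_bound > 0 and self.n_binding_sites < n_bound:
            raise ValueError("n_binding_sites must cover every bound event at least once")
        if self.barcode_random_length < 1:
            raise ValueError("barcode_random_length must be >= 1")
        for name in ("junction_depth", "iclip_site_read_mean", "background_read_rate",
                     "pcr_duplication_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.chip_bound_fraction <= 1:
            raise ValueError("chip_bound_fraction must be in [0, 1]")


@dataclass
class GroundTruthManifest:
    """Everything the generator planted, re-derivable from the emitted files."""

    true_psi: dict[str, dict[str, float]] = field(default_factory=dict)
    event_class: dict[str, str] = field(default_factory=dict)
    planted_sites: list[dict] = field(default_factory=list)  # chrom/position/strand/event_id
    motif: str = ""
    n_unique_molecules: int = 0
    expression_class: dict[str, str] = field(default_factory=dict)
    true_fold_change: dict[str, float] = field(default_factory=dict)
    chip_bound_genes: list[str] = field(default_factory=list)

    @property
    def direct_target_events(self) -> set[str]:
        return {
            e for e, c in self.event_class.items() if c in (DIRECT_REPRESSED, DIRECT_ACTIVATED)
        }

    @property
    def bound_events(self) -> set[str]:
        return {
            e
            for e, c in self.event_class.items()
            if c in (DIRECT_REPRESSED, DIRECT_ACTIVATED, BOUND_UNRESPONSIVE)
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], list[CassetteEventAnnotation], GroundTruthManifest]:
    """Generate the genome, gene models, cassette events and planted truth.

    Binding sites (and their motif copies, written into the genome on the
    sense strand) are planted here because they are genome features; the
    read generator later samples reads at those positions.
    """
    config.validate()
    truth = GroundTruthManifest(motif=config.binding_site_motif.upper())

    chrom = "chr1"
    genes: list[GeneModel] = []
    events: list[CassetteEventAnnotation] = []
    cursor = config.intergenic_gap
    exon_lo, exon_hi = config.exon_length_range
    intron_lo, intron_hi = config.intron_length_range
    for i in range(config.n_genes):
        strand = PLUS if i % 2 == 0 else MINUS
        exon_lens = rng.integers(exon_lo, exon_hi + 1, size=config.n_exons_per_gene)
        intron_lens = rng.integers(intron_lo, intron_hi + 1, size=config.n_exons_per_gene - 1)
        exons = []
        pos = cursor
        for j in range(config.n_exons_per_gene):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
            pos += int(exon_lens[j])
            if j < config.n_exons_per_gene - 1:
                pos += int(intron_lens[j])
        gene = GeneModel(gene_id=f"g{i:04d}", exons=exons)
        genes.append(gene)
        cursor = pos + config.intergenic_gap

    genome_codes = _random_seq(rng, cursor + config.intergenic_gap)

    # one measured cassette event per gene: the middle exon trio, with the
    # id read_gene_models() assigns to it
    middle = config.n_exons_per_gene // 2
    for gene in genes[: config.n_cassette_events]:
        events.append(
            CassetteEventAnnotation(
                event_id=f"{gene.gene_id}.ce{middle}",
                gene_id=gene.gene_id,
                upstream_exon=gene.exons[middle - 1],
                cassette_exon=gene.exons[middle],
                downstream_exon=gene.exons[middle + 1],
                strand=gene.strand,
            )
        )

    # assign planted classes to a random subset of events
    order = rng.permutation(len(events))
    classes = (
        [DIRECT_REPRESSED] * config.n_direct_repressed
        + [DIRECT_ACTIVATED] * config.n_direct_activated
        + [BOUND_UNRESPONSIVE] * config.n_bound_unresponsive
        + [RESPONSIVE_UNBOUND] * config.n_responsive_unbound
    )
    classes += [UNCHANGED] * (len(events) - len(classes))
    for idx, cls in zip(order, classes):
        truth.event_class[events[idx].event_id] = cls

    # true PSI per condition
    d = config.planted_dpsi
    for event in events:
        cls = truth.event_class[event.event_id]
        if cls in (DIRECT_REPRESSED, RESPONSIVE_UNBOUND):
            base = float(rng.uniform(15, 35))
            psi = {CONTROL: base, KNOCKDOWN: base + d, PROGENITOR: base, NEURONAL: base + d}
        elif cls == DIRECT_ACTIVATED:
            base = float(rng.uniform(65, 85))
            psi = {CONTROL: base, KNOCKDOWN: base - d, PROGENITOR: base, NEURONAL: base - d}
        else:
            base = float(rng.uniform(20, 80))
            psi = {c: base for c in CONDITIONS}
        truth.true_psi[event.event_id] = {c: round(v, 3) for c, v in psi.items()}

    # plant binding sites in the intron flanks of bound events
    bound_events = [e for e in events if truth.event_class[e.event_id] in
                    (DIRECT_REPRESSED, DIRECT_ACTIVATED, BOUND_UNRESPONSIVE)]
    motif = truth.motif
    motif_codes = np.frombuffer(motif.encode(), dtype=np.uint8)
    motif_idx = np.array([{65: 0, 67: 1, 71: 2, 84: 3}[b] for b in motif_codes], dtype=np.int8)
    rc_idx = motif_idx[::-1] ^ 3  # complement in 2-bit coding: A<->T, C<->G

    def plant(site: int, strand: str) -> None:
        # write the motif at sense offsets -12 and +6 from the site, inside
        # the +-30 window used by the enrichment scan
        for offset in (-12, 6):
            if strand == PLUS:
                start = site + offset
                genome_codes[start : start + 5] = motif_idx
            else:
                start = site - offset - 4
                genome_codes[start : start + 5] = rc_idx

    n_sites = config.n_binding_sites if bound_events else 0
    for s in range(n_sites):
        event = bound_events[s % len(bound_events)]
        side = "upstream_intron" if rng.random() < 0.5 else "downstream_intron"
        region = flank(event, side, 500)
        # keep the +-30 motif window clear of the intron boundaries
        lo, hi = region.start + 35, region.end - 35
        site = int(rng.integers(lo, hi))
        plant(site, event.strand)
        truth.planted_sites.append(
            {"chrom": chrom, "position": site, "strand": event.strand, "event_id": event.event_id}
        )

    genome = {chrom: _to_str(genome_codes)}
    return genome, genes, events, truth


def _draw_barcode(rng: np.random.Generator, length: int) -> str:
    return _to_str(rng.integers(0, 4, size=length, dtype=np.int8))


def simulate_iclip_reads(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruthManifest,
    rng: np.random.Generator,
) -> list[IclipRead]:
    """Truncation-model reads at planted sites plus uniform background.

    Every unique molecule gets a random barcode, unique among the molecules
    sharing its crosslink position (collisions are redrawn), so barcode
    deduplication recovers the pre-amplification molecule count exactly;
    ``truth.n_unique_molecules`` records that count.  PCR copies inherit the
    molecule's position and barcode.
    """
    reads: list[IclipRead] = []
    used: dict[tuple, set[str]] = {}
    n_molecules = 0
    counter = 0
    rl = config.read_length

    def emit(chrom: str, site: int, strand: str) -> None:
        nonlocal n_molecules, counter
        if strand == PLUS:
            iv = GenomicInterval(chrom, site + 1, site + 1 + rl, strand)
        else:
            iv = GenomicInterval(chrom, max(0, site - rl), site, strand)
        key = (chrom, site, strand)
        taken = used.setdefault(key, set())
        barcode = _draw_barcode(rng, config.barcode_random_length)
        while barcode in taken:
            barcode = _draw_barcode(rng, config.barcode_random_length)
        taken.add(barcode)
        n_molecules += 1
        n_copies = 1 + int(rng.poisson(config.pcr_duplication_rate))
        for _ in range(n_copies):
            reads.append(IclipRead(alignment=iv, random_barcode=barcode, read_id=f"r{counter}"))
            counter += 1

    for site in truth.planted_sites:
        n_mol = int(rng.poisson(config.iclip_site_read_mean))
        for _ in range(n_mol):
            emit(site["chrom"], site["position"], site["strand"])

    for gene in genes:
        span = gene.span
        n_bg = int(rng.poisson(config.background_read_rate * span.width / 1000.0))
        for _ in range(n_bg):
            pos = int(rng.integers(span.start, span.end))
            emit(span.chrom, pos, gene.strand)

    truth.n_unique_molecules = n_molecules
    return reads


def simulate_junction_counts(
    config: SimulationConfig, truth: GroundTruthManifest, rng: np.random.Generator
) -> list[JunctionCounts]:
    """Binomial junction evidence at the true PSI of each event/condition.

    Per replicate, total junction depth is Poisson(junction_depth); the
    inclusion draw x ~ Binomial(n, PSI/100) sets I1 = I2 = x and E = n - x,
    so the PSI estimator 100*m/(m+E) with m=(I1+I2)/2 has expectation equal
    to the true PSI.
    """
    counts: list[JunctionCounts] = []
    for event_id in sorted(truth.true_psi):
        for condition in CONDITIONS:
            p = truth.true_psi[event_id][condition] / 100.0
            for rep in range(1, config.n_junction_replicates + 1):
                n = int(rng.poisson(config.junction_depth))
                x = int(rng.binomial(n, p)) if n > 0 else 0
                counts.append(
                    JunctionCounts(
                        event_id=event_id,
                        condition=condition,
                        replicate=rep,
                        inclusion_upstream=x,
                        inclusion_downstream=x,
                        exclusion=n - x,
                    )
                )
    return counts


def simulate_expression_table(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruthManifest,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Log-normal FPKM replicates with planted fold-changes.

    Reference (wild-type) replicates are drawn around each gene's base mean;
    test (mutant) replicates around base mean times the planted fold change.
    """
    n_planted = config.n_induced_strong + config.n_induced_weak + config.n_repressed_expression
    if n_planted > len(genes):
        raise ValueError("planted expression classes exceed n_genes")
    order = rng.permutation(len(genes))
    folds = (
        [("induced_strong", 4.0)] * config.n_induced_strong
        + [("induced_weak", 1.7)] * config.n_induced_weak
        + [("repressed", 0.25)] * config.n_repressed_expression
    )
    fold_by_gene = {g.gene_id: ("unchanged", 1.0) for g in genes}
    for idx, planted in zip(order, folds):
        fold_by_gene[genes[idx].gene_id] = planted

    ref_cols = [f"wt_{i}" for i in range(1, config.n_reference_replicates + 1)]
    test_cols = [f"mut_{i}" for i in range(1, config.n_test_replicates + 1)]
    rows = {}
    for gene in genes:
        cls, fold = fold_by_gene[gene.gene_id]
        truth.expression_class[gene.gene_id] = cls
        truth.true_fold_change[gene.gene_id] = fold
        base = float(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd))
        ref = base * rng.lognormal(0.0, config.replicate_log_sd, size=len(ref_cols))
        tst = base * fold * rng.lognormal(0.0, config.replicate_log_sd, size=len(test_cols))
        rows[gene.gene_id] = list(np.round(ref, 4)) + list(np.round(tst, 4))
    return pd.DataFrame.from_dict(rows, orient="index", columns=ref_cols + test_cols)


def simulate_chip_clusters(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruthManifest,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """ChIP clusters near bound genes, enriched among the induced genes.

    Bound genes get one cluster just upstream of the gene span (inside the
    1-kb assignment window); induced genes are bound at
    ``chip_bound_fraction * chip_induced_boost``.  Decoy clusters are placed
    >= 2 kb from every gene span so they are never assigned.  With
    ``chip_bound_fraction == 0`` the track is empty.
    """
    clusters: list[GenomicInterval] = []
    if config.chip_bound_fraction == 0:
        return clusters
    bound: list[str] = []
    unbound_genes: list[GeneModel] = []
    for gene in genes:
        cls = truth.expression_class.get(gene.gene_id, "unchanged")
        p = config.chip_bound_fraction
        if cls in ("induced_strong", "induced_weak"):
            p = min(1.0, p * config.chip_induced_boost)
        if rng.random() < p:
            span = gene.span
            clusters.append(
                GenomicInterval(span.chrom, span.start - 800, span.start - 500, PLUS)
            )
            bound.append(gene.gene_id)
        else:
            unbound_genes.append(gene)
    for gene in unbound_genes[: config.n_chip_decoys]:
        span = gene.span
        clusters.append(GenomicInterval(span.chrom, span.end + 2200, span.end + 2500, PLUS))
    truth.chip_bound_genes = sorted(bound)
    return clusters


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    events: list[CassetteEventAnnotation]
    reads: list[IclipRead]
    junction_counts: list[JunctionCounts]
    fpkm: pd.DataFrame
    chip_clusters: list[GenomicInterval]
    truth: GroundTruthManifest

    @property
    def reference_replicates(self) -> list[str]:
        return [c for c in self.fpkm.columns if c.startswith("wt_")]

    @property
    def test_replicates(self) -> list[str]:
        return [c for c in self.fpkm.columns if c.startswith("mut_")]

    def write(self, outdir) -> dict[str, Path]:
        """Write every component as plain-text files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "iclip_reads": outdir / "iclip_reads.bed",
            "junctions": outdir / "junction_counts.tsv",
            "fpkm": outdir / "fpkm.tsv",
            "chip": outdir / "chip_clusters.bed",
            "truth": outdir / "truth.json",
        }
        csio.write_fasta(self.genome, paths["genome"])
        write_gtf(self.genes, str(paths["annotation"]))
        csio.write_iclip_bed(self.reads, paths["iclip_reads"])
        csio.write_junction_table(self.junction_counts, paths["junctions"])
        csio.write_fpkm_table(self.fpkm, paths["fpkm"])
        csio.write_bed6(self.chip_clusters, paths["chip"])
        paths["truth"].write_text(self.truth.to_json())
        return paths


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run every generator stage from one seed and bundle the results."""
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    genome, genes, events, truth = simulate_annotation(config, rng)
    reads = simulate_iclip_reads(config, genes, truth, rng)
    junctions = simulate_junction_counts(config, truth, rng)
    fpkm = simulate_expression_table(config, genes, truth, rng)
    chip = simulate_chip_clusters(config, genes, truth, rng)
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        events=events,
        reads=reads,
        junction_counts=junctions,
        fpkm=fpkm,
        chip_clusters=chip,
        truth=truth,
    )
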