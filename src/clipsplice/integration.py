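"""Combining binding, splicing response, differentiation and expression into
direct-target calls and overlap enrichment statistics.

An exon is a *direct target* when it (1) responds to regulator knockdown,
(2) changes concordantly during differentiation, and (3) carries a binding
cluster (>= 4 significant reads) within the cassette exon or the 500-nt
intron flanks.  Set overlaps are tested with the upper-tail hypergeometric
distribution; gene-level expression changes use fold-change cutoffs on group
mean FPKM together with Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from clipsplice.core import CassetteEventAnnotation, GeneModel, GenomicInterval, flank
from clipsplice.iclip import SiteCluster
from clipsplice.splicing import DiffSpliceResult, classify_quadrant

FLANK_LENGTH = 500
CHIP_WINDOW = 1000
EXPRESSED_FPKM = 1.0
FOLD_PSEUDOCOUNT = 0.1


@dataclass
class TargetCall:
    event_id: str
    responsive: bool
    bound: bool
    differentiation_changed: bool
    direction: str | None  # "repressed" | "activated" | None
    direct_target: bool

    def __post_init__(self) -> None:
        if self.direct_target and not (
            self.responsive and self.bound and self.differentiation_changed
        ):
            raise ValueError(f"{self.event_id}: direct_target without all three flags")


@dataclass(frozen=True)
class OverlapEnrichment:
    """Hypergeometric upper-tail enrichment of an overlap k out of a sample
    n, against K marked items in a population of N."""

    population_size: int
    marked: int
    sample_size: int
    overlap: int
    p_value: float

    @property
    def fraction_sample(self) -> float:
        return self.overlap / self.sample_size if self.sample_size else math.nan

    @property
    def fraction_population(self) -> float:
        return self.marked / self.population_size if self.population_size else math.nan


@dataclass(frozen=True)
class ExpressionResult:
    gene_id: str
    mean_reference: float
    mean_test: float
    fold_change: float  # ratio of group means, each floored at 0.1 FPKM
    welch_t: float
    welch_p: float
    classes: Mapping[float, str]  # cutoff -> induced | repressed | unchanged


@dataclass(frozen=True)
class ChipAssignment:
    gene_id: str
    bound: bool


def associate_clusters(
    events: Sequence[CassetteEventAnnotation],
    clusters: Sequence[SiteCluster],
    flank_length: int = FLANK_LENGTH,
) -> tuple[dict[str, bool], dict[str, int]]:
    """Flag events with a same-strand cluster in the exon body or intron flanks.

    An event is *bound* when at least one cluster on the host gene's strand
    overlaps (>= 1 nt) the cassette exon or the ``flank_length``-nt intron
    flanks (clipped to the introns).  Antisense clusters never confer bound
    status; their overlap counts are tabulated separately.

    Returns (bound flag per event_id, antisense overlap count per event_id).
    """
    by_key: dict[tuple[str, str], list[SiteCluster]] = {}
    for cl in clusters:
        by_key.setdefault((cl.interval.chrom, cl.strand), []).append(cl)

    bound: dict[str, bool] = {}
    antisense: dict[str, int] = {}
    for event in events:
        regions = [
            event.cassette_exon,
            flank(event, "upstream_intron", flank_length),
            flank(event, "downstream_intron", flank_length),
        ]
        regions = [r for r in regions if not r.is_empty]
        sense = by_key.get((event.chrom, event.strand), [])
        other = by_key.get((event.chrom, "-" if event.strand == "+" else "+"), [])
        bound[event.event_id] = any(
            cl.interval.overlaps(region) for cl in sense for region in regions
        )
        antisense[event.event_id] = sum(
            1 for cl in other if any(cl.interval.overlaps(region) for region in regions)
        )
    return bound, antisense


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> OverlapEnrichment:
    """Upper-tail hypergeometric test P(X >= k) for an overlap of k.

    N: population size; K: marked items; n: sample size; k: marked items in
    the sample.  Bounds 0 <= k <= min(K, n) <= N are enforced.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric bounds N={N}, K={K}, n={n}, k={k}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(p, 0.0))
    return OverlapEnrichment(
        population_size=N, marked=K, sample_size=n, overlap=k, p_value=p
    )


def dataset_overlap(
    targets_a: Iterable[str], targets_b: Iterable[str]
) -> tuple[int, int, int]:
    """Partition two target sets into (shared, unique to A, unique to B)."""
    a, b = set(targets_a), set(targets_b)
    shared = len(a & b)
    return shared, len(a) - shared, len(b) - shared


@dataclass
class DirectTargetTally:
    n_repressed: int = 0
    n_activated: int = 0
    n_direction_conflict: int = 0

    @property
    def total(self) -> int:
        return self.n_repressed + self.n_activated


def define_direct_targets(
    kd_results: Mapping[str, DiffSpliceResult],
    diff_results: Mapping[str, DiffSpliceResult],
    bound: Mapping[str, bool],
) -> tuple[list[TargetCall], DirectTargetTally]:
    """Intersect knockdown response, differentiation change and binding.

    Every event appearing in any input is reported exactly once.  A direct
    target must pass both splicing comparisons, be bound, and have
    concordant knockdown/differentiation directions (quadrant not ``other``);
    discordant events are reported with ``direction=None`` and counted in the
    tally's ``n_direction_conflict``.
    """
    event_ids = sorted(set(kd_results) | set(diff_results) | set(bound))
    calls: list[TargetCall] = []
    tally = DirectTargetTally()
    for event_id in event_ids:
        kd = kd_results.get(event_id)
        diff = diff_results.get(event_id)
        responsive = kd is not None and kd.passes
        changed = diff is not None and diff.passes
        is_bound = bool(bound.get(event_id, False))
        direction: str | None = None
        direct = False
        if responsive and changed and is_bound:
            quadrant = classify_quadrant(kd, diff)
            if quadrant == "repressed_neuronal":
                direction, direct = "repressed", True
                tally.n_repressed += 1
            elif quadrant == "activated_neuronal":
                direction, direct = "activated", True
                tally.n_activated += 1
            else:
                tally.n_direction_conflict += 1
        calls.append(
            TargetCall(
                event_id=event_id,
                responsive=responsive,
                bound=is_bound,
                differentiation_changed=changed,
                direction=direction,
                direct_target=direct,
            )
        )
    return calls, tally


def _welch(reference: np.ndarray, test: np.ndarray) -> tuple[float, float]:
    if np.ptp(reference) == 0 and np.ptp(test) == 0:
        # zero variance in both groups: conventional p
        if reference.mean() == test.mean():
            return 0.0, 1.0
        return math.inf if test.mean() > reference.mean() else -math.inf, 0.0
    t, p = sps.ttest_ind(test, reference, equal_var=False)
    return float(t), float(p)


def expression_changes(
    fpkm: pd.DataFrame,
    reference_replicates: Sequence[str],
    test_replicates: Sequence[str],
    cutoffs: Sequence[float] = (2.0, 1.5),
) -> list[ExpressionResult]:
    """Per-gene fold change and Welch's t-test between two replicate groups.

    ``fpkm`` is a gene-by-replicate table of normalized FPKM values.  The
    fold change is mean(test)/mean(reference) with both means floored at a
    0.1-FPKM pseudocount, so zero-expression genes never divide by zero and
    well-expressed genes keep their exact mean ratio.  For each cutoff c, a gene is ``induced`` when fold >= c and
    Welch p < 0.05, ``repressed`` when fold <= 1/c and p < 0.05, otherwise
    ``unchanged``.  Genes with fewer than 2 replicates in a group are
    skipped.
    """
    for group in (reference_replicates, test_replicates):
        if len(group) < 2:
            raise ValueError("each group needs >= 2 replicates")
    results: list[ExpressionResult] = []
    ref_mat = fpkm[list(reference_replicates)].to_numpy(dtype=float)
    test_mat = fpkm[list(test_replicates)].to_numpy(dtype=float)
    for i, gene_id in enumerate(fpkm.index):
        ref, tst = ref_mat[i], test_mat[i]
        mean_ref, mean_tst = float(ref.mean()), float(tst.mean())
        fold = max(mean_tst, FOLD_PSEUDOCOUNT) / max(mean_ref, FOLD_PSEUDOCOUNT)
        t, p = _welch(ref, tst)
        classes = {}
        for c in cutoffs:
            if fold >= c and p < 0.05:
                classes[c] = "induced"
            elif fold <= 1.0 / c and p < 0.05:
                classes[c] = "repressed"
            else:
                classes[c] = "unchanged"
        results.append(
            ExpressionResult(
                gene_id=str(gene_id),
                mean_reference=mean_ref,
                mean_test=mean_tst,
                fold_change=fold,
                welch_t=t,
                welch_p=p,
                classes=classes,
            )
        )
    return results


def chip_gene_overlap(
    gene_models: Sequence[GeneModel],
    chip_clusters: Sequence[GenomicInterval],
    sample_gene_set: Iterable[str],
    expressed_gene_set: Iterable[str] | None = None,
    window: int = CHIP_WINDOW,
) -> tuple[list[ChipAssignment], OverlapEnrichment]:
    """Assign ChIP binding to genes and test enrichment in a gene sample.

    A gene is bound when any ChIP cluster overlaps (>= 1 nt) its span
    extended ``window`` nt on both sides; the assignment is strand-agnostic
    (binding sites are DNA-level features).  Enrichment of bound genes
    within ``sample_gene_set`` is tested against the expressed-gene
    population (defaults to all supplied gene models) with the upper-tail
    hypergeometric test.
    """
    population = set(expressed_gene_set) if expressed_gene_set is not None else {
        g.gene_id for g in gene_models
    }
    if not population:
        raise ValueError("empty expressed-gene population")
    sample = set(sample_gene_set)
    if not sample <= population:
        raise ValueError("sample gene set must be a subset of the expressed population")

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for cl in chip_clusters:
        by_chrom.setdefault(cl.chrom, []).append(cl)

    assignments: list[ChipAssignment] = []
    bound_ids: set[str] = set()
    for gene in gene_models:
        span = gene.span
        win = GenomicInterval(
            span.chrom, max(0, span.start - window), span.end + window, span.strand
        )
        is_bound = any(
            max(win.start, cl.start) < min(win.end, cl.end)
            for cl in by_chrom.get(span.chrom, [])
        )
        assignments.append(ChipAssignment(gene_id=gene.gene_id, bound=is_bound))
        if is_bound:
            bound_ids.add(gene.gene_id)

    marked = len(bound_ids & population)
    overlap = len(bound_ids & sample)
    enrichment = hypergeom_enrichment(
        N=len(population), K=marked, n=len(sample), k=overlap
    )
    return assignments, enrichment
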