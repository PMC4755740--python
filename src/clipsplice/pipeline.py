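"""End-to-end driver: reads -> sites -> clusters -> motifs -> PSI ->
target integration -> enrichment, with a structured summary report.

The pipeline consumes either a :class:`~clipsplice.simulate.SyntheticDataset`
(via a :class:`~clipsplice.simulate.SimulationConfig`) or file-based inputs,
and is fully reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clipsplice import io as csio
from clipsplice.core import CassetteEventAnnotation, GeneModel, GenomicInterval, read_gene_models
from clipsplice.iclip import (
    CrosslinkSite,
    IclipRead,
    PentamerStat,
    SiteCluster,
    assign_site_fdr,
    build_clusters,
    call_crosslink_sites,
    deduplicate,
    filter_clusters,
    pentamer_zscores,
)
from clipsplice.integration import (
    ChipAssignment,
    ExpressionResult,
    OverlapEnrichment,
    TargetCall,
    DirectTargetTally,
    associate_clusters,
    chip_gene_overlap,
    dataset_overlap,
    define_direct_targets,
    expression_changes,
    hypergeom_enrichment,
)
from clipsplice.simulate import (
    CONTROL,
    KNOCKDOWN,
    NEURONAL,
    PROGENITOR,
    GroundTruthManifest,
    SimulationConfig,
    SyntheticDataset,
    simulate_dataset,
)
from clipsplice.splicing import DiffSpliceResult, JunctionCounts, diff_splice


@dataclass
class PipelineInputs:
    genome: Mapping[str, str]
    genes: list[GeneModel]
    events: list[CassetteEventAnnotation]
    reads: list[IclipRead]
    junction_counts: list[JunctionCounts]
    fpkm: pd.DataFrame
    chip_clusters: list[GenomicInterval]
    reference_replicates: list[str]
    test_replicates: list[str]
    truth: GroundTruthManifest | None = None

    @classmethod
    def from_dataset(cls, ds: SyntheticDataset) -> "PipelineInputs":
        return cls(
            genome=ds.genome,
            genes=ds.genes,
            events=ds.events,
            reads=ds.reads,
            junction_counts=ds.junction_counts,
            fpkm=ds.fpkm,
            chip_clusters=ds.chip_clusters,
            reference_replicates=ds.reference_replicates,
            test_replicates=ds.test_replicates,
            truth=ds.truth,
        )

    @classmethod
    def from_paths(
        cls,
        genome_fasta,
        annotation_gtf,
        iclip_bed,
        junction_tsv,
        fpkm_tsv,
        chip_bed,
        reference_replicates: Sequence[str] | None = None,
        test_replicates: Sequence[str] | None = None,
        truth_json=None,
    ) -> "PipelineInputs":
        genome = csio.read_fasta(genome_fasta)
        genes, candidates = read_gene_models(str(annotation_gtf))
        junctions = csio.read_junction_table(junction_tsv)
        measured = {j.event_id for j in junctions}
        events = [e for e in candidates if e.event_id in measured]
        fpkm = csio.read_fpkm_table(fpkm_tsv)
        if reference_replicates is None:
            reference_replicates = [c for c in fpkm.columns if c.startswith("wt_")]
        if test_replicates is None:
            test_replicates = [c for c in fpkm.columns if c.startswith("mut_")]
        truth = None
        if truth_json is not None:
            truth = GroundTruthManifest.from_json(Path(truth_json).read_text())
        return cls(
            genome=genome,
            genes=genes,
            events=events,
            reads=csio.read_iclip_bed(iclip_bed),
            junction_counts=junctions,
            fpkm=fpkm,
            chip_clusters=csio.read_bed6(chip_bed),
            reference_replicates=list(reference_replicates),
            test_replicates=list(test_replicates),
            truth=truth,
        )


@dataclass
class PipelineResult:
    sites: list[CrosslinkSite]
    unannotated_sites: list[CrosslinkSite]
    clusters: list[SiteCluster]
    filtered_clusters: list[SiteCluster]
    pentamer_stats: list[PentamerStat]
    kd_results: dict[str, DiffSpliceResult]
    diff_results: dict[str, DiffSpliceResult]
    bound: dict[str, bool]
    target_calls: list[TargetCall]
    tally: DirectTargetTally
    binding_enrichment: OverlapEnrichment | None
    expression_results: list[ExpressionResult]
    chip_assignments: list[ChipAssignment]
    chip_enrichment: OverlapEnrichment | None
    summary: dict = field(default_factory=dict)


def _diff_splice_by_event(
    junctions: Sequence[JunctionCounts], cond_a: str, cond_b: str
) -> dict[str, DiffSpliceResult]:
    by_event: dict[str, dict[str, list[JunctionCounts]]] = {}
    for j in junctions:
        by_event.setdefault(j.event_id, {}).setdefault(j.condition, []).append(j)
    out: dict[str, DiffSpliceResult] = {}
    for event_id, conds in by_event.items():
        if cond_a in conds and cond_b in conds:
            res = diff_splice(conds[cond_a], conds[cond_b])
            if res is not None:
                out[event_id] = res
    return out


def run_pipeline(
    inputs: PipelineInputs | None = None,
    sim_config: SimulationConfig | None = None,
    out_dir=None,
    seed: int = 0,
    n_perm: int = 100,
    n_rand_motif: int = 100,
    min_cluster_reads: int = 4,
    kd_pair: tuple[str, str] = (CONTROL, KNOCKDOWN),
    diff_pair: tuple[str, str] = (PROGENITOR, NEURONAL),
) -> PipelineResult:
    """Run every stage of the analysis and assemble the summary report.

    Exactly one of ``inputs`` / ``sim_config`` must be provided (with
    ``sim_config`` the synthetic dataset is generated first).  ``seed``
    drives the FDR permutations and motif-null randomization.  When
    ``out_dir`` is given, every stage output and the summary report are
    written there as plain-text files.
    """
    if (inputs is None) == (sim_config is None):
        raise ValueError("provide exactly one of inputs or sim_config")
    if sim_config is not None:
        inputs = PipelineInputs.from_dataset(simulate_dataset(sim_config))
    rng = np.random.default_rng(seed)

    unique_reads, dedup_stats = deduplicate(inputs.reads)
    raw_sites, n_edge_skipped = call_crosslink_sites(unique_reads)
    sites, unannotated = assign_site_fdr(raw_sites, inputs.genes, n_perm=n_perm, rng=rng)
    significant = [s for s in sites if s.significant]
    clusters = build_clusters(significant)
    filtered = filter_clusters(clusters, min_reads=min_cluster_reads)
    pentamers, n_motif_skipped = pentamer_zscores(
        significant, inputs.genome, inputs.genes, n_rand=n_rand_motif, rng=rng
    )

    kd_results = _diff_splice_by_event(inputs.junction_counts, *kd_pair)
    diff_results = _diff_splice_by_event(inputs.junction_counts, *diff_pair)
    bound, antisense = associate_clusters(inputs.events, filtered)
    calls, tally = define_direct_targets(kd_results, diff_results, bound)

    responsive = {e for e, r in kd_results.items() if r.passes}
    changed = {e for e, r in diff_results.items() if r.passes}
    shared, only_kd, only_diff = dataset_overlap(responsive, changed)

    # enrichment of knockdown-responsive events among cluster-bound events
    evaluable = sorted(kd_results)
    binding_enrichment = None
    if evaluable:
        bound_eval = {e for e in evaluable if bound.get(e, False)}
        binding_enrichment = hypergeom_enrichment(
            N=len(evaluable),
            K=len(bound_eval),
            n=len(responsive & set(evaluable)),
            k=len(responsive & bound_eval),
        )

    expression = expression_changes(
        inputs.fpkm, inputs.reference_replicates, inputs.test_replicates
    )
    ref_mean = inputs.fpkm[inputs.reference_replicates].mean(axis=1)
    test_mean = inputs.fpkm[inputs.test_replicates].mean(axis=1)
    expressed = set(inputs.fpkm.index[(ref_mean >= 1.0) | (test_mean >= 1.0)].astype(str))
    induced_15 = {r.gene_id for r in expression if r.classes.get(1.5) == "induced"}
    chip_assignments: list[ChipAssignment] = []
    chip_enrichment = None
    if expressed:
        chip_assignments, chip_enrichment = chip_gene_overlap(
            inputs.genes,
            inputs.chip_clusters,
            sample_gene_set=induced_15 & expressed,
            expressed_gene_set=expressed,
        )

    direct_called = {c.event_id for c in calls if c.direct_target}
    summary: dict = {
        "seed": seed,
        "n_input_reads": dedup_stats.n_input,
        "n_unique_reads": len(unique_reads),
        "n_pcr_duplicates_removed": dedup_stats.n_duplicates_removed,
        "n_missing_barcode": dedup_stats.n_missing_barcode,
        "n_edge_skipped_reads": n_edge_skipped,
        "n_crosslink_sites": len(sites),
        "n_unannotated_sites": len(unannotated),
        "n_significant_sites": len(significant),
        "n_significant_reads": int(sum(s.height for s in significant)),
        "n_clusters": len(clusters),
        "n_filtered_clusters": len(filtered),
        "n_motif_sites_skipped": n_motif_skipped,
        "top_pentamer": pentamers[0].pentamer if pentamers else None,
        "top_pentamer_z": pentamers[0].z if pentamers else None,
        "n_events_evaluated_kd": len(kd_results),
        "n_kd_responsive": len(responsive),
        "n_differentiation_changed": len(changed),
        "overlap_shared": shared,
        "overlap_unique_kd": only_kd,
        "overlap_unique_diff": only_diff,
        "n_bound_events": int(sum(bool(v) for v in bound.values())),
        "n_antisense_only_events": int(
            sum(1 for e, n in antisense.items() if n > 0 and not bound.get(e))
        ),
        "n_direct_targets": tally.total,
        "n_direct_repressed": tally.n_repressed,
        "n_direct_activated": tally.n_activated,
        "n_direction_conflicts": tally.n_direction_conflict,
        "n_expressed_genes": len(expressed),
        "n_induced_2.0": sum(1 for r in expression if r.classes.get(2.0) == "induced"),
        "n_repressed_2.0": sum(1 for r in expression if r.classes.get(2.0) == "repressed"),
        "n_induced_1.5": len(induced_15),
        "n_repressed_1.5": sum(1 for r in expression if r.classes.get(1.5) == "repressed"),
    }
    if binding_enrichment is not None:
        summary["binding_enrichment_p"] = binding_enrichment.p_value
    if chip_enrichment is not None:
        summary.update(
            chip_bound_induced=chip_enrichment.overlap,
            chip_induced_fraction=chip_enrichment.fraction_sample,
            chip_population_fraction=chip_enrichment.fraction_population,
            chip_enrichment_p=chip_enrichment.p_value,
        )
    if inputs.truth is not None:
        truth_set = inputs.truth.direct_target_events
        hit = len(direct_called & truth_set)
        summary["direct_target_sensitivity"] = hit / len(truth_set) if truth_set else float("nan")
        summary["direct_target_precision"] = (
            hit / len(direct_called) if direct_called else float("nan")
        )
        if inputs.truth.motif:
            rank = next(
                (i + 1 for i, s in enumerate(pentamers) if s.pentamer == inputs.truth.motif),
                None,
            )
            summary["planted_motif_rank"] = rank

    result = PipelineResult(
        sites=sites,
        unannotated_sites=unannotated,
        clusters=clusters,
        filtered_clusters=filtered,
        pentamer_stats=pentamers,
        kd_results=kd_results,
        diff_results=diff_results,
        bound=bound,
        target_calls=calls,
        tally=tally,
        binding_enrichment=binding_enrichment,
        expression_results=expression,
        chip_assignments=chip_assignments,
        chip_enrichment=chip_enrichment,
        summary=summary,
    )
    if out_dir is not None:
        _write_outputs(result, inputs, Path(out_dir))
    return result


def _diffsplice_frame(results: dict[str, DiffSpliceResult]) -> pd.DataFrame:
    rows = [
        {
            "event_id": r.event_id,
            "psi_a": round(r.psi_a, 3),
            "psi_b": round(r.psi_b, 3),
            "delta_psi": round(r.delta_psi, 3),
            "p_value": r.p_value,
            "passes": r.passes,
            "class": r.regulation_class,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows).sort_values("event_id") if rows else pd.DataFrame(
        columns=["event_id", "psi_a", "psi_b", "delta_psi", "p_value", "passes", "class"]
    )


def _write_outputs(result: PipelineResult, inputs: PipelineInputs, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    csio.write_sites_bed(result.sites, out_dir / "crosslink_sites.bed")
    csio.write_clusters_bed(result.clusters, out_dir / "clusters.bed")
    csio.write_clusters_bed(result.filtered_clusters, out_dir / "clusters_filtered.bed")
    csio.write_pentamer_table(result.pentamer_stats, out_dir / "pentamer_zscores.tsv")
    _diffsplice_frame(result.kd_results).to_csv(
        out_dir / "diffsplice_knockdown.tsv", sep="\t", index=False
    )
    _diffsplice_frame(result.diff_results).to_csv(
        out_dir / "diffsplice_differentiation.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "responsive": c.responsive,
                "bound": c.bound,
                "differentiation_changed": c.differentiation_changed,
                "direction": c.direction or "NA",
                "direct_target": c.direct_target,
            }
            for c in result.target_calls
        ]
    ).to_csv(out_dir / "target_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_reference": round(r.mean_reference, 4),
                "mean_test": round(r.mean_test, 4),
                "fold_change": round(r.fold_change, 4),
                "welch_t": r.welch_t,
                "welch_p": r.welch_p,
                "class_2.0": r.classes.get(2.0, "NA"),
                "class_1.5": r.classes.get(1.5, "NA"),
            }
            for r in result.expression_results
        ]
    ).to_csv(out_dir / "expression_changes.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(result.summary, indent=1, sort_keys=True))
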