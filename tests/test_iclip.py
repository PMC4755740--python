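"""Deduplication, crosslink-site calling, permutation FDR, clustering and
pentamer enrichment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clipsplice.core import GeneModel, GenomicInterval
from clipsplice.iclip import (
    CrosslinkSite,
    IclipRead,
    assign_site_fdr,
    build_clusters,
    call_crosslink_sites,
    deduplicate,
    filter_clusters,
    pentamer_zscores,
    revcomp,
)


def read(start, end, strand="+", barcode="ACGTACGTA", chrom="chr1", read_id="r"):
    return IclipRead(GenomicInterval(chrom, start, end, strand), barcode, read_id)


def site(pos, height=1, strand="+", fdr=0.0, chrom="chr1"):
    return CrosslinkSite(chrom=chrom, position=pos, strand=strand, height=height, fdr=fdr)


def one_gene(start, end, strand="+", gene_id="g1", chrom="chr1"):
    """Single-exon gene model spanning [start, end)."""
    return GeneModel(gene_id=gene_id, exons=[GenomicInterval(chrom, start, end, strand)])


class TestDeduplicate:
    def test_same_position_same_barcode_collapses(self):
        unique, stats = deduplicate([read(100, 130), read(100, 130)])
        assert len(unique) == 1 and stats.n_duplicates_removed == 1

    def test_same_position_different_barcodes_kept(self):
        unique, _ = deduplicate([read(100, 130, barcode="AAAAAAAAA"), read(100, 130, barcode="CCCCCCCCC")])
        assert len(unique) == 2

    def test_same_barcode_different_starts_kept(self):
        unique, _ = deduplicate([read(100, 130), read(101, 131)])
        assert len(unique) == 2

    def test_minus_strand_key_uses_transcript_start(self):
        # same 3' genomic start but different transcript-orientation 5' ends
        unique, _ = deduplicate([read(100, 130, "-"), read(100, 131, "-")])
        assert len(unique) == 2

    def test_missing_barcode_rejected_and_counted(self):
        unique, stats = deduplicate([read(100, 130, barcode="")])
        assert unique == [] and stats.n_missing_barcode == 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.booleans(), st.sampled_from(["AA", "AC", "CA"])),
            max_size=60,
        )
    )
    def test_matches_pairwise_comparison_oracle(self, raw):
        reads = [
            read(s, s + 30, "+" if plus else "-", barcode=bc, read_id=f"r{i}")
            for i, (s, plus, bc) in enumerate(raw)
        ]
        unique, _ = deduplicate(reads)
        # oracle: a read survives iff no earlier read duplicates it
        survivors = []
        for i, r in enumerate(reads):
            dup = any(
                q.alignment.strand == r.alignment.strand
                and q.random_barcode == r.random_barcode
                and (q.alignment.start if q.alignment.strand == "+" else q.alignment.end)
                == (r.alignment.start if r.alignment.strand == "+" else r.alignment.end)
                for q in reads[:i]
            )
            if not dup:
                survivors.append(r)
        assert len(unique) == len(survivors)
        assert sorted(
            (r.alignment.start, r.alignment.end, r.alignment.strand, r.random_barcode)
            for r in unique
        ) == sorted(
            (r.alignment.start, r.alignment.end, r.alignment.strand, r.random_barcode)
            for r in survivors
        )


class TestCallCrosslinkSites:
    def test_plus_strand_site_one_upstream_of_start(self):
        sites, _ = call_crosslink_sites([read(101, 131)])
        assert (sites[0].position, sites[0].strand) == (100, "+")

    def test_minus_strand_site_at_alignment_end(self):
        sites, _ = call_crosslink_sites([read(200, 230, "-")])
        assert (sites[0].position, sites[0].strand) == (230, "-")

    def test_heights_aggregate_reads(self):
        reads = [read(101, 131, barcode=bc) for bc in ("AAA", "CCC", "GGG")]
        sites, _ = call_crosslink_sites(reads)
        assert len(sites) == 1 and sites[0].height == 3

    def test_contig_edge_read_skipped(self):
        sites, n_skipped = call_crosslink_sites([read(0, 30, "+")])
        assert sites == [] and n_skipped == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 50), st.booleans()), max_size=50))
    def test_height_sum_equals_unique_reads(self, raw):
        reads = [
            read(s, s + 10, "+" if plus else "-", barcode=f"b{i}", read_id=f"r{i}")
            for i, (s, plus) in enumerate(raw)
        ]
        sites, n_skipped = call_crosslink_sites(reads)
        assert sum(s.height for s in sites) + n_skipped == len(reads)


class TestAssignSiteFdr:
    def test_tall_single_position_is_significant(self, rng):
        gene = one_gene(0, 10_000)
        sites = [CrosslinkSite("chr1", 5000, "+", height=50)]
        annotated, _ = assign_site_fdr(sites, [gene], n_perm=100, rng=rng)
        # 50 events on 10 kb almost never stack 50 deep at one position
        assert annotated[0].fdr < 0.01 and annotated[0].significant

    def test_uniform_saturation_is_null(self, rng):
        gene = one_gene(0, 500)
        sites = [CrosslinkSite("chr1", p, "+", height=1) for p in range(500)]
        annotated, _ = assign_site_fdr(sites, [gene], n_perm=50, rng=rng)
        assert all(s.fdr > 0.5 for s in annotated)
        assert not any(s.significant for s in annotated)

    def test_empty_input(self, rng):
        assert assign_site_fdr([], [one_gene(0, 1000)], rng=rng) == ([], [])

    def test_sites_outside_genes_reported_untested(self, rng):
        gene = one_gene(1000, 2000)
        inside = CrosslinkSite("chr1", 1500, "+", height=5)
        outside = CrosslinkSite("chr1", 100, "+", height=5)
        wrong_strand = CrosslinkSite("chr1", 1500, "-", height=5)
        annotated, unannotated = assign_site_fdr(
            [inside, outside, wrong_strand], [gene], n_perm=10, rng=rng
        )
        assert [s.position for s in annotated] == [1500]
        assert {s.position for s in unannotated} == {100, 1500}
        assert all(s.fdr is None for s in unannotated)

    def test_fdr_monotone_in_height(self, rng):
        gene = one_gene(0, 5000)
        sites = [CrosslinkSite("chr1", 100 * i, "+", height=h) for i, h in enumerate([1] * 30 + [2, 2, 5])]
        annotated, _ = assign_site_fdr(sites, [gene], n_perm=200, rng=rng)
        by_height = {}
        for s in annotated:
            by_height[s.height] = s.fdr
        heights = sorted(by_height)
        assert all(by_height[a] >= by_height[b] for a, b in zip(heights, heights[1:]))


class TestClusters:
    def test_nearby_sites_merge(self):
        clusters = build_clusters([site(100, 3), site(130, 2)])
        assert len(clusters) == 1
        assert (clusters[0].interval.start, clusters[0].interval.end) == (80, 151)
        assert clusters[0].significant_read_total == 5

    def test_distant_sites_stay_separate(self):
        clusters = build_clusters([site(100), site(150)])
        spans = [(c.interval.start, c.interval.end) for c in clusters]
        assert spans == [(80, 121), (130, 171)]

    def test_single_site_width_41(self):
        clusters = build_clusters([site(100, 5)])
        assert clusters[0].interval.width == 41
        assert clusters[0].significant_read_total == 5

    def test_strands_never_merge(self):
        clusters = build_clusters([site(100, strand="+"), site(110, strand="-")])
        assert len(clusters) == 2

    def test_rejects_nonsignificant_sites_and_negative_extension(self):
        with pytest.raises(ValueError):
            build_clusters([site(100, fdr=0.5)])
        with pytest.raises(ValueError):
            build_clusters([site(100)], extension=-1)

    def test_every_significant_site_in_exactly_one_cluster(self, default_result):
        clusters = default_result.clusters
        for a, b in itertools.combinations(clusters, 2):
            if a.strand == b.strand:
                assert not a.interval.overlaps(b.interval)
        n_members = sum(len(c.member_sites) for c in clusters)
        n_significant = sum(1 for s in default_result.sites if s.significant)
        assert n_members == n_significant

    @pytest.mark.parametrize(
        "heights, min_reads, kept",
        [((2, 2), 4, True), ((3,), 4, False), ((1,), 0, True)],
    )
    def test_filter_by_significant_read_total(self, heights, min_reads, kept):
        clusters = build_clusters([site(100 + 5 * i, h) for i, h in enumerate(heights)])
        assert len(clusters) == 1
        assert (len(filter_clusters(clusters, min_reads)) == 1) is kept


class TestPentamerZscores:
    @staticmethod
    def genome_and_gene(rng, length=30_000, strand="+"):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        exons = [
            GenomicInterval("chr1", 100, 200, strand),
            GenomicInterval("chr1", length - 200, length - 100, strand),
        ]
        return {"chr1": seq}, GeneModel(gene_id="g1", exons=exons)

    def test_exonic_sites_skipped(self, rng):
        genome, gene = self.genome_and_gene(rng)
        stats, n_skipped = pentamer_zscores(
            [site(150)], genome, [gene], n_rand=10, rng=np.random.default_rng(0)
        )
        assert n_skipped == 1
        assert len(stats) == 1024
        assert all(s.z == 0 for s in stats)  # no windows: all-zero observed and null

    def test_planted_motif_scores_highest(self, rng):
        genome, gene = self.genome_and_gene(rng)
        seq = list(genome["chr1"])
        positions = list(range(1000, 26_000, 500))
        for p in positions:
            seq[p - 10 : p - 5] = "TCTCT"
            seq[p + 4 : p + 9] = "TCTCT"
        genome = {"chr1": "".join(seq)}
        stats, n_skipped = pentamer_zscores(
            [site(p) for p in positions], genome, [gene],
            n_rand=50, rng=np.random.default_rng(0),
        )
        assert n_skipped == 0
        assert stats[0].pentamer == "TCTCT"
        assert stats[0].z > 10

    def test_minus_strand_counts_sense_sequence(self, rng):
        genome, gene = self.genome_and_gene(rng, strand="-")
        seq = list(genome["chr1"])
        p = 5000
        seq[p - 9 : p - 4] = revcomp("TCTCT")  # sense-strand TCTCT downstream of the site
        genome = {"chr1": "".join(seq)}
        stats, _ = pentamer_zscores(
            [site(p, strand="-")], genome, [gene], n_rand=20, rng=np.random.default_rng(0)
        )
        by_name = {s.pentamer: s for s in stats}
        assert by_name["TCTCT"].observed_count >= 1

    def test_constant_null_equal_observed_gives_zero(self):
        genome = {"chr1": "A" * 2000}
        gene = GeneModel(
            gene_id="g1",
            exons=[GenomicInterval("chr1", 10, 20, "+"), GenomicInterval("chr1", 1500, 1600, "+")],
        )
        stats, _ = pentamer_zscores(
            [site(700)], genome, [gene], n_rand=5, rng=np.random.default_rng(0)
        )
        by_name = {s.pentamer: s for s in stats}
        # every window of the poly-A intron holds the same 57 AAAAA matches
        assert by_name["AAAAA"].null_sd == 0 and by_name["AAAAA"].z == 0
        assert not by_name["AAAAA"].degenerate

    def test_degenerate_null_sd_flagged_with_signed_infinity(self, rng):
        # a single null replicate has sd 0 at every pentamer, so any pentamer
        # whose observed count differs must be flagged with a signed infinity
        genome, gene = self.genome_and_gene(rng)
        stats, _ = pentamer_zscores(
            [site(5000), site(9000)], genome, [gene], n_rand=1, rng=np.random.default_rng(0)
        )
        degenerate = [s for s in stats if s.degenerate]
        assert degenerate, "random windows should differ from their null draw somewhere"
        assert all(math.isinf(s.z) for s in degenerate)
        assert all(
            (s.z > 0) == (s.observed_count > s.null_mean) for s in degenerate
        )
        assert all(s.z == 0 for s in stats if not s.degenerate and s.null_sd == 0)
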