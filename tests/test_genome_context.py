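"""Intron arithmetic, intronic classification and the genomic-proportion null."""

from __future__ import annotations

import numpy as np
import pytest

from trnactx.annotation_io import GeneModel, TRNAGene
from trnactx.genome_context import (
    classify_trnas,
    intronic_fraction_test,
    introns_of,
    merged_intron_bp,
    nearest_flanking_genes,
)
from tests.conftest import (
    brute_force_intronic,
    brute_force_neighbors,
    reflect_gene,
    reflect_trna,
)


def gene(gene_id, strand, exons, chrom="chrI"):
    starts = tuple(s for s, _ in exons)
    ends = tuple(e for _, e in exons)
    return GeneModel(gene_id, chrom, strand, starts[0], ends[-1], starts, ends)


def trna(trna_id, start, end, strand="+", chrom="chrI", pseudo=False, ac="CCA"):
    return TRNAGene(trna_id, chrom, strand, start, end, "Trp", ac, pseudo)


THREE_EXONS = [(100, 200), (300, 400), (500, 600)]


class TestIntronsOf:
    def test_plus_strand_indices_follow_genomic_order(self):
        result = introns_of(gene("g", "+", THREE_EXONS))
        assert [(i.start, i.end, idx) for i, idx in result] == [
            (200, 300, 1),
            (400, 500, 2),
        ]

    def test_minus_strand_indices_reverse(self):
        result = introns_of(gene("g", "-", THREE_EXONS))
        assert [(i.start, i.end, idx) for i, idx in result] == [
            (200, 300, 2),
            (400, 500, 1),
        ]

    def test_single_exon_yields_no_introns(self):
        assert introns_of(gene("g", "+", [(10, 500)])) == []

    def test_exon_intron_partition_conserves_span(self, small_bundle):
        for g in small_bundle.ref.genes[:100]:
            exon_bp = sum(e - s for s, e in zip(g.exon_starts, g.exon_ends))
            intron_bp = sum(len(i) for i, _ in introns_of(g))
            assert exon_bp + intron_bp == g.tx_end - g.tx_start


class TestClassify:
    def test_contained_trna_is_intronic(self):
        g = gene("g", "+", THREE_EXONS)
        (a,), summary = classify_trnas([trna("t", 220, 292)], [g])
        assert a.status == "intronic"
        assert a.host_gene_id == "g"
        assert a.host_intron_index == 1
        assert a.same_strand is True
        assert summary["all"].fraction_intronic == 1.0

    def test_boundary_spanning_trna_is_ambiguous_non_intronic(self):
        g = gene("g", "+", THREE_EXONS)
        (a,), _ = classify_trnas([trna("t", 190, 262)], [g])
        assert a.status == "non_intronic"
        assert a.ambiguous_overlap

    def test_transcript_mode_accepts_exon_overlap(self):
        g = gene("g", "+", THREE_EXONS)
        (a,), _ = classify_trnas([trna("t", 190, 262)], [g], containment="transcript")
        assert a.status == "intronic"
        assert a.host_gene_id == "g"

    def test_trna_on_unknown_chromosome_has_no_neighbors(self):
        g = gene("g", "+", THREE_EXONS)
        (a,), _ = classify_trnas([trna("t", 0, 80, chrom="chrY")], [g])
        assert a.status == "non_intronic"
        assert a.upstream_neighbor is None and a.downstream_neighbor is None

    def test_host_tiebreak_prefers_smallest_intron(self):
        big = gene("g_big", "+", [(0, 50), (1000, 1100)])
        small = gene("g_small", "-", [(150, 200), (400, 450)])
        (a,), _ = classify_trnas([trna("t", 220, 300)], [big, small])
        assert a.host_gene_id == "g_small"
        assert a.same_strand is False

    def test_partition_is_exhaustive_per_subset(self, small_bundle):
        ref = small_bundle.ref
        _, summary = classify_trnas(ref.trnas, ref.genes)
        for name in ("all", "pseudo", "functional"):
            c = summary[name]
            assert c.n_intronic + c.n_non_intronic == c.n_trnas
        assert summary["pseudo"].n_trnas + summary["functional"].n_trnas == summary[
            "all"
        ].n_trnas

    def test_matches_per_base_oracle_on_tiny_genome(self, tiny_bundle):
        ref = tiny_bundle.ref
        assignments, _ = classify_trnas(ref.trnas, ref.genes)
        by_id = {t.trna_id: t for t in ref.trnas}
        for a in assignments:
            t = by_id[a.trna_id]
            covering = brute_force_intronic(t, ref.genes)
            if a.status == "intronic":
                expected_host = min(covering, key=lambda c: (c[2], c[0]))
                assert (a.host_gene_id, a.host_intron_index) == expected_host[:2]
            else:
                assert not covering
                up, down = brute_force_neighbors(t, ref.genes)
                assert a.upstream_neighbor == up
                assert a.downstream_neighbor == down

    def test_strand_reflection_symmetry(self, tiny_bundle):
        """Mirroring all coordinates and flipping strands must leave every
        status, intron index and neighbor distance unchanged."""
        ref = tiny_bundle.ref
        L = max(ref.chrom_sizes.values()) + 10
        fwd, _ = classify_trnas(ref.trnas, ref.genes)
        genes_r = [reflect_gene(g, L) for g in ref.genes]
        trnas_r = [reflect_trna(t, L) for t in ref.trnas]
        rev, _ = classify_trnas(trnas_r, genes_r)
        for a, b in zip(fwd, rev):
            assert a.status == b.status
            assert a.host_gene_id == b.host_gene_id
            assert a.host_intron_index == b.host_intron_index
            assert a.same_strand == b.same_strand
            assert a.upstream_neighbor == b.upstream_neighbor
            assert a.downstream_neighbor == b.downstream_neighbor


class TestNeighbors:
    def test_hand_arithmetic(self):
        ga = gene("geneA", "+", [(0, 200)])
        gb = gene("geneB", "+", [(800, 1000)])
        up, down = nearest_flanking_genes(trna("t", 500, 572), [ga, gb])
        assert up == ("geneA", 300)
        assert down == ("geneB", 228)

    def test_minus_strand_swaps_roles(self):
        ga = gene("geneA", "+", [(0, 200)])
        gb = gene("geneB", "+", [(800, 1000)])
        up, down = nearest_flanking_genes(trna("t", 500, 572, strand="-"), [ga, gb])
        assert up == ("geneB", 228)
        assert down == ("geneA", 300)

    def test_absent_side_is_none_and_abutting_distance_zero(self):
        ga = gene("geneA", "+", [(0, 200)])
        up, down = nearest_flanking_genes(trna("t", 200, 272), [ga])
        assert up == ("geneA", 0)
        assert down is None

    def test_overlapping_gene_excluded(self):
        host = gene("host", "+", [(0, 100), (900, 1000)])
        other = gene("other", "+", [(1200, 1400)])
        up, down = nearest_flanking_genes(trna("t", 150, 222), [host, other])
        assert up is None
        assert down == ("other", 978)


class TestIntronicFractionTest:
    def test_expected_proportion_from_merged_introns(self):
        g1 = gene("g1", "+", [(0, 100), (300, 400)])  # intron (100,300)
        g2 = gene("g2", "+", [(50, 150), (300, 350)])  # overlapping intron (150,300)
        assert merged_intron_bp([g1, g2]) == 200

    def test_statistic_matches_hand_arithmetic(self):
        # 30 of 100 intronic vs 25% genomic introns: 25/25 + 25/75 = 1.3333
        g = gene("g", "+", [(0, 100), (350, 400)])  # 250 intronic bp
        trnas = [trna(f"t{i}", 10_000 + 200 * i, 10_080 + 200 * i) for i in range(100)]
        hosts = [
            gene(f"h{i}", "+", [(10_000 + 200 * i - 20, 10_000 + 200 * i - 10),
                                (10_090 + 200 * i, 10_100 + 200 * i)])
            for i in range(30)
        ]
        _, summary = classify_trnas(trnas[:30], hosts)
        # craft a summary with 30/70 split by classifying all 100 against hosts
        _, summary = classify_trnas(trnas, hosts)
        assert summary["all"].n_intronic == 30
        res = intronic_fraction_test(summary, [g], genome_size=1000)
        assert res.expected_probs[0] == pytest.approx(0.25)
        assert res.statistic == pytest.approx(4.0 / 3.0, abs=1e-4)
        assert res.df == 1

    def test_degenerate_null_rejected(self):
        g = gene("g", "+", [(0, 500)])  # no introns
        _, summary = classify_trnas([trna("t", 600, 700)], [g])
        with pytest.raises(Exception, match="degenerate"):
            intronic_fraction_test(summary, [g], genome_size=1000)
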