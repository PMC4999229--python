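"""Intron computation and genomic-context classification of tRNA genes.

A tRNA is *intronic* when its interval lies wholly inside a single intron of
a protein-coding gene model (the host); all other tRNAs are non-intronic and
get their nearest non-overlapping flanking genes, oriented relative to the
tRNA's own strand. The observed intronic fraction is tested against the
genomic-proportion null (merged intronic bp over genome size) with a 1-df
chi-square goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_io import GeneModel, GenomeInterval, TRNAGene, ValidationError
from .stats_core import ChiSquareResult, chisq_gof

__all__ = [
    "IntronicAssignment",
    "SubsetCounts",
    "ContextSummary",
    "introns_of",
    "classify_trnas",
    "nearest_flanking_genes",
    "merged_intron_bp",
    "intronic_fraction_test",
]


@dataclass(frozen=True)
class IntronicAssignment:
    trna_id: str
    status: str  # "intronic" | "non_intronic"
    host_gene_id: str | None = None
    host_intron_index: int | None = None  # 1-based, transcription order
    same_strand: bool | None = None
    upstream_neighbor: tuple[str, int] | None = None  # (gene_id, distance bp)
    downstream_neighbor: tuple[str, int] | None = None
    ambiguous_overlap: bool = False
    host_tie: bool = False

    def __post_init__(self) -> None:
        intronic = self.status == "intronic"
        if self.status not in ("intronic", "non_intronic"):
            raise ValueError(f"invalid status {self.status!r}")
        if intronic and self.host_gene_id is None:
            raise ValueError(f"{self.trna_id}: intronic assignment without host")
        if not intronic and self.host_gene_id is not None:
            raise ValueError(f"{self.trna_id}: non-intronic assignment with host")


@dataclass(frozen=True)
class SubsetCounts:
    n_trnas: int
    n_intronic: int
    n_non_intronic: int
    fraction_intronic: float
    fraction_same_strand_of_intronic: float  # NaN when no intronic tRNAs


@dataclass(frozen=True)
class ContextSummary:
    """Counts for the three reporting subsets: all, pseudo, functional."""

    subsets: dict[str, SubsetCounts]

    def __getitem__(self, key: str) -> SubsetCounts:
        return self.subsets[key]


def introns_of(gene: GeneModel) -> list[tuple[GenomeInterval, int]]:
    """Gaps between consecutive exons, indexed 1..n-1 in transcription order.

    On the minus strand the genomically-last intron is intron 1.
    """
    n_introns = gene.n_exons - 1
    out = []
    for i in range(n_introns):
        start, end = gene.exon_ends[i], gene.exon_starts[i + 1]
        index = i + 1 if gene.strand == "+" else n_introns - i
        out.append((GenomeInterval(gene.chrom, start, end, gene.strand), index))
    return out


def _subset_counts(assignments: Sequence[IntronicAssignment]) -> SubsetCounts:
    n = len(assignments)
    intronic = [a for a in assignments if a.status == "intronic"]
    n_int = len(intronic)
    same = sum(1 for a in intronic if a.same_strand)
    return SubsetCounts(
        n_trnas=n,
        n_intronic=n_int,
        n_non_intronic=n - n_int,
        fraction_intronic=n_int / n if n else float("nan"),
        fraction_same_strand_of_intronic=same / n_int if n_int else float("nan"),
    )


def nearest_flanking_genes(
    trna: TRNAGene, genes: Sequence[GeneModel]
) -> tuple[tuple[str, int] | None, tuple[str, int] | None]:
    """Nearest non-overlapping protein-coding genes on the tRNA's 5' and 3' sides.

    Candidates whose transcript span overlaps the tRNA are excluded; distance
    is the gap between the nearest boundaries (0 when abutting). Returns
    (upstream, downstream) relative to the tRNA's own strand; an absent side
    is None.
    """
    best_left: tuple[int, str] | None = None  # (distance, gene_id)
    best_right: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != trna.chrom:
            continue
        if g.tx_start < trna.end and trna.start < g.tx_end:
            continue  # overlapping genes are not neighbors
        if g.tx_end <= trna.start:
            d = trna.start - g.tx_end
            if best_left is None or (d, g.gene_id) < best_left:
                best_left = (d, g.gene_id)
        elif g.tx_start >= trna.end:
            d = g.tx_start - trna.end
            if best_right is None or (d, g.gene_id) < best_right:
                best_right = (d, g.gene_id)
    left = (best_left[1], best_left[0]) if best_left else None
    right = (best_right[1], best_right[0]) if best_right else None
    return (left, right) if trna.strand == "+" else (right, left)


def classify_trnas(
    trnas: Sequence[TRNAGene],
    genes: Sequence[GeneModel],
    containment: str = "intron",
) -> tuple[list[IntronicAssignment], ContextSummary]:
    """Classify every tRNA as intronic or non-intronic with context metadata.

    ``containment='intron'`` (default) requires full containment inside a
    single intron; ``'transcript'`` accepts containment anywhere within a
    gene's transcript span. When several gene models contain the tRNA, the
    host is the gene with the smallest containing intron (smallest transcript
    span in transcript mode), ties broken lexicographically by gene id and
    flagged.
    """
    if containment not in ("intron", "transcript"):
        raise ValueError(f"unknown containment mode {containment!r}")

    # per-chromosome intron and transcript inventories
    by_chrom_introns: dict[str, list[tuple[int, int, int, GeneModel]]] = {}
    by_chrom_genes: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)
        for interval, index in introns_of(g):
            by_chrom_introns.setdefault(g.chrom, []).append(
                (interval.start, interval.end, index, g)
            )

    assignments: list[IntronicAssignment] = []
    for t in trnas:
        chrom_genes = by_chrom_genes.get(t.chrom, [])
        candidates: list[tuple[int, str, int, GeneModel]] = []
        if containment == "intron":
            for istart, iend, index, g in by_chrom_introns.get(t.chrom, []):
                if istart <= t.start and t.end <= iend:
                    candidates.append((iend - istart, g.gene_id, index, g))
        else:
            for g in chrom_genes:
                if g.tx_start <= t.start and t.end <= g.tx_end:
                    intron_index = None
                    for interval, index in introns_of(g):
                        if interval.start <= t.start and t.end <= interval.end:
                            intron_index = index
                            break
                    candidates.append(
                        (g.tx_end - g.tx_start, g.gene_id, intron_index, g)
                    )
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1]))
            size, gene_id, index, host = candidates[0]
            tie = len(candidates) > 1 and candidates[1][0] == size
            assignments.append(
                IntronicAssignment(
                    trna_id=t.trna_id,
                    status="intronic",
                    host_gene_id=gene_id,
                    host_intron_index=index,
                    same_strand=t.strand == host.strand,
                    host_tie=tie,
                )
            )
        else:
            overlaps = any(
                g.tx_start < t.end and t.start < g.tx_end for g in chrom_genes
            )
            up, down = nearest_flanking_genes(t, chrom_genes)
            assignments.append(
                IntronicAssignment(
                    trna_id=t.trna_id,
                    status="non_intronic",
                    upstream_neighbor=up,
                    downstream_neighbor=down,
                    ambiguous_overlap=overlaps,
                )
            )

    by_id = {t.trna_id: t for t in trnas}
    pseudo = [a for a in assignments if by_id[a.trna_id].is_pseudo]
    functional = [a for a in assignments if not by_id[a.trna_id].is_pseudo]
    summary = ContextSummary(
        {
            "all": _subset_counts(assignments),
            "pseudo": _subset_counts(pseudo),
            "functional": _subset_counts(functional),
        }
    )
    return assignments, summary


def merged_intron_bp(genes: Sequence[GeneModel]) -> int:
    """Total genomic bp covered by >=1 intron, merged across overlapping models."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for interval, _ in introns_of(g):
            by_chrom.setdefault(g.chrom, []).append((interval.start, interval.end))
    total = 0
    for ivals in by_chrom.values():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def intronic_fraction_test(
    summary: ContextSummary,
    genes: Sequence[GeneModel],
    genome_size: int,
    subset: str = "all",
) -> ChiSquareResult:
    """Chi-square test of the intronic count against the genomic intron proportion."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    counts = summary[subset]
    p_intron = merged_intron_bp(genes) / genome_size
    if p_intron <= 0.0 or p_intron >= 1.0:
        raise ValidationError(
            f"degenerate null: genomic intron proportion {p_intron:.4g}"
        )
    return chisq_gof(
        [counts.n_intronic, counts.n_non_intronic], [p_intron, 1.0 - p_intron]
    )
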