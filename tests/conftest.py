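"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from trnactx.annotation_io import GeneModel, SignalTrack, TRNAGene
from trnactx.genome_context import introns_of
from trnactx.synthetic_data import SyntheticTruth, generate_dataset

# ---------------------------------------------------------------------------
# bundles


@pytest.fixture(scope="session")
def small_truth() -> SyntheticTruth:
    return SyntheticTruth(
        seed=3,
        n_species=3,
        n_genes=250,
        n_trnas_functional=150,
        n_trnas_pseudo=60,
        n_target_background_trnas=80,
    )


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return generate_dataset(small_truth, tracks_for="ref", expression_for="ref")


@pytest.fixture(scope="session")
def tiny_truth() -> SyntheticTruth:
    """A genome small enough for per-base brute-force oracles (<10 kb/chrom)."""
    return SyntheticTruth(
        seed=7,
        n_species=1,
        n_chromosomes=2,
        n_genes=10,
        n_trnas_functional=24,
        n_trnas_pseudo=6,
        exon_len_range=(50, 120),
        intron_len_range=(150, 400),
        n_exons_range=(2, 5),
        intergenic_gap_mean=700.0,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_truth):
    return generate_dataset(tiny_truth, tracks_for="ref", expression_for="ref")


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_intronic(trna: TRNAGene, genes: list[GeneModel]):
    """Per-base oracle: the set of (gene, intron index, intron length) whose
    intron covers *every* base of the tRNA."""
    covering = None
    for base in range(trna.start, trna.end):
        here = set()
        for g in genes:
            if g.chrom != trna.chrom:
                continue
            for interval, idx in introns_of(g):
                if interval.start <= base < interval.end:
                    here.add((g.gene_id, idx, len(interval)))
        covering = here if covering is None else covering & here
        if not covering:
            return set()
    return covering or set()


def brute_force_neighbors(trna: TRNAGene, genes: list[GeneModel]):
    """Linear-scan oracle for nearest non-overlapping genes left/right,
    returned strand-relatively as (upstream, downstream)."""
    left = right = None
    for g in genes:
        if g.chrom != trna.chrom:
            continue
        if g.tx_start < trna.end and trna.start < g.tx_end:
            continue
        if g.tx_end <= trna.start:
            cand = (trna.start - g.tx_end, g.gene_id)
            if left is None or cand < left:
                left = cand
        else:
            cand = (g.tx_start - trna.end, g.gene_id)
            if right is None or cand < right:
                right = cand
    to_pair = lambda c: None if c is None else (c[1], c[0])
    if trna.strand == "+":
        return to_pair(left), to_pair(right)
    return to_pair(right), to_pair(left)


def expand_track(track: SignalTrack, chrom: str, length: int) -> np.ndarray:
    """Materialize a track as a dense per-base array (NaN = missing)."""
    arr = np.full(length, np.nan)
    if chrom in track.chroms:
        for s, e, v in track.intervals(chrom):
            arr[max(0, s) : min(length, e)] = v
    return arr


# ---------------------------------------------------------------------------
# strand-reflection helpers (genome mirrored at length L, strands flipped)


def reflect_gene(g: GeneModel, L: int) -> GeneModel:
    starts = tuple(L - e for e in reversed(g.exon_ends))
    ends = tuple(L - s for s in reversed(g.exon_starts))
    return GeneModel(
        g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
        L - g.tx_end, L - g.tx_start, starts, ends,
    )


def reflect_trna(t: TRNAGene, L: int) -> TRNAGene:
    return TRNAGene(
        t.trna_id, t.chrom, "-" if t.strand == "+" else "+",
        L - t.end, L - t.start, t.amino_acid, t.anticodon, t.is_pseudo, t.score,
    )


def reflect_track(track: SignalTrack, L: int) -> SignalTrack:
    return SignalTrack(
        {
            chrom: [(L - e, L - s, v) for s, e, v in track.intervals(chrom)]
            for chrom in track.chroms
        }
    )
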