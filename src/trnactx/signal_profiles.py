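"""Anchor-aligned signal profiles and group comparisons.

Signal tracks are anchored at each tRNA's first mature nucleotide and read
out strand-relatively: offset +x is x bases 3' of the anchor, so minus-strand
rows run against genome order. Unmeasured positions stay missing (NaN) and
per-offset sample sizes are reported alongside every mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import SignalTrack, TRNAGene
from .stats_core import CorrelationResult, RankSumResult, ranksum, spearman

__all__ = [
    "ProfileMatrix",
    "build_profile_matrix",
    "mean_profile",
    "window_stat",
    "window_scores",
    "compare_groups",
    "correlate_scores",
]

DEFAULT_FLANK = 1000
DEFAULT_OCCUPANCY_WINDOW = (-100, 100)


@dataclass(frozen=True)
class ProfileMatrix:
    anchors: tuple[str, ...]  # tRNA ids, row order
    offsets: np.ndarray  # -F .. F-1, strand-relative
    values: np.ndarray  # shape (n_anchors, 2F); NaN = missing

    def row(self, trna_id: str) -> np.ndarray:
        return self.values[self.anchors.index(trna_id)]


def _strand_positions(trna: TRNAGene, offsets: np.ndarray) -> np.ndarray:
    # +x means 3' of the anchor on the tRNA's own strand
    return trna.anchor + offsets if trna.strand == "+" else trna.anchor - offsets


def build_profile_matrix(
    track: SignalTrack, trnas: Sequence[TRNAGene], flank: int = DEFAULT_FLANK
) -> ProfileMatrix:
    """Strand-aware per-base signal matrix over offsets [-flank, flank)."""
    offsets = np.arange(-flank, flank)
    values = np.empty((len(trnas), offsets.size))
    for i, t in enumerate(trnas):
        values[i] = track.values_at(t.chrom, _strand_positions(t, offsets))
    return ProfileMatrix(tuple(t.trna_id for t in trnas), offsets, values)


def mean_profile(matrix: ProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset mean over non-missing cells and the per-offset n.

    Offsets with zero defined cells are NaN in the mean.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    defined = ~np.isnan(matrix.values)
    n = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, np.nansum(matrix.values, axis=0) / np.maximum(n, 1), np.nan)
    return means, n


def window_stat(
    track: SignalTrack,
    trna: TRNAGene,
    from_offset: int,
    to_offset: int,
    stat: str = "max",
) -> float:
    """Statistic of the signal in the strand-relative offset window [from, to)."""
    if from_offset >= to_offset:
        raise ValueError("from_offset must be < to_offset")
    if stat not in ("max", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    offsets = np.arange(from_offset, to_offset)
    vals = track.values_at(trna.chrom, _strand_positions(trna, offsets))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.max() if stat == "max" else vals.mean())


def window_scores(
    track: SignalTrack,
    trnas: Sequence[TRNAGene],
    window: tuple[int, int] = DEFAULT_OCCUPANCY_WINDOW,
    stat: str = "max",
) -> dict[str, float]:
    """Per-tRNA window statistic, e.g. the Pol III occupancy proxy over [-100, 100)."""
    return {t.trna_id: window_stat(track, t, window[0], window[1], stat) for t in trnas}


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two score groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one defined score")
    return ranksum(a, b)


def correlate_scores(
    x_scores: Mapping[str, float], y_scores: Mapping[str, float]
) -> CorrelationResult:
    """Spearman correlation over features with defined scores on both sides."""
    shared = sorted(
        fid
        for fid in set(x_scores) & set(y_scores)
        if not (np.isnan(x_scores[fid]) or np.isnan(y_scores[fid]))
    )
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features with defined scores")
    return spearman([x_scores[f] for f in shared], [y_scores[f] for f in shared])
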