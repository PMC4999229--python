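"""Anticodon-host pairing and its cross-species conservation.

A pair is a distinct (anticodon, protein-coding gene) combination: intronic
tRNAs pair with their host gene, non-intronic tRNAs with their nearest
upstream or downstream neighbor. Conservation of a reference pair in a
target species requires the gene's ortholog to carry the same anticodon in
the same relation; reference pairs whose gene has no ortholog are excluded
from the denominator. The distance-windowed analysis slides fixed-size
windows over distance-sorted non-intronic records and extrapolates a cubic
fit of conservation back to distance zero, the intronic comparison point.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_io import OrthologMap, TRNAGene
from .genome_context import IntronicAssignment
from .stats_core import CorrelationResult, polyfit_predict, spearman

__all__ = [
    "AnticodonHostPair",
    "ConservationResult",
    "WindowConfig",
    "WindowPoint",
    "ExtrapolationResult",
    "build_pairs",
    "neighbor_pairs",
    "neighbor_records",
    "conservation_fraction",
    "windowed_conservation",
    "extrapolate_zero",
    "copy_number_vector",
    "copy_number_similarity",
]


@dataclass(frozen=True)
class AnticodonHostPair:
    anticodon: str
    host_gene_id: str
    species: str = ""


@dataclass(frozen=True)
class ConservationResult:
    ref_species: str
    target_species: str
    pair_class: str
    n_pairs: int
    n_no_ortholog: int
    n_evaluable: int
    n_conserved: int
    fraction: float | None  # None when no pair is evaluable

    def __post_init__(self) -> None:
        if self.n_evaluable != self.n_pairs - self.n_no_ortholog:
            raise ValueError("n_evaluable must equal n_pairs - n_no_ortholog")


@dataclass(frozen=True)
class WindowConfig:
    window_size: int = 40
    n_windows: int = 20

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.n_windows < 2:
            raise ValueError("need window_size >= 1 and n_windows >= 2")

    def step(self, n_records: int) -> int:
        """Stride between window starts; reproduces ~57% overlap at N=363, w=40, k=20."""
        return max(1, round((n_records - self.window_size) / (self.n_windows - 1)))


@dataclass(frozen=True)
class WindowPoint:
    index: int
    median_distance: float
    fraction: float | None
    n_evaluable: int
    n_conserved: int
    n_records: int


@dataclass(frozen=True)
class ExtrapolationResult:
    degree: int
    coefficients: tuple[float, ...]  # ascending powers
    value_at_zero: float
    se_at_zero: float


def _pair_key(anticodon: str, gene_id: str) -> tuple[str, str]:
    return (anticodon, gene_id)


def build_pairs(
    assignments: Sequence[IntronicAssignment],
    trnas: Sequence[TRNAGene],
    trna_class: str = "functional",
    species: str = "",
) -> set[AnticodonHostPair]:
    """Distinct (anticodon, host gene) pairs among intronic tRNAs of one class.

    Several same-anticodon tRNAs inside one host contribute a single pair;
    different anticodons in the same host each contribute one.
    """
    want_pseudo = _class_flag(trna_class)
    by_id = {t.trna_id: t for t in trnas}
    pairs = set()
    for a in assignments:
        if a.status != "intronic":
            continue
        t = by_id[a.trna_id]
        if t.is_pseudo != want_pseudo:
            continue
        pairs.add(AnticodonHostPair(t.anticodon, a.host_gene_id, species))
    return pairs


def _class_flag(trna_class: str) -> bool:
    if trna_class not in ("functional", "pseudo"):
        raise ValueError(f"unknown tRNA class {trna_class!r}")
    return trna_class == "pseudo"


def neighbor_pairs(
    assignments: Sequence[IntronicAssignment],
    trnas: Sequence[TRNAGene],
    side: str,
    trna_class: str = "functional",
    species: str = "",
) -> set[AnticodonHostPair]:
    """Distinct (anticodon, flanking gene) pairs of non-intronic tRNAs."""
    return {
        AnticodonHostPair(ac, gene, species)
        for ac, gene, _ in neighbor_records(assignments, trnas, side, trna_class)
    }


def neighbor_records(
    assignments: Sequence[IntronicAssignment],
    trnas: Sequence[TRNAGene],
    side: str,
    trna_class: str = "functional",
) -> list[tuple[str, str, int]]:
    """Per-tRNA (anticodon, neighbor gene, distance) records for one flank side."""
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    want_pseudo = _class_flag(trna_class)
    by_id = {t.trna_id: t for t in trnas}
    records = []
    for a in assignments:
        if a.status != "non_intronic":
            continue
        t = by_id[a.trna_id]
        if t.is_pseudo != want_pseudo:
            continue
        neighbor = a.upstream_neighbor if side == "upstream" else a.downstream_neighbor
        if neighbor is None:
            continue
        gene_id, distance = neighbor
        records.append((t.anticodon, gene_id, distance))
    return records


def conservation_fraction(
    ref_pairs: Iterable[AnticodonHostPair],
    target_pairs: Iterable[AnticodonHostPair],
    ortholog_map: OrthologMap,
    pair_class: str = "intronic_host",
    ref_species: str = "",
    target_species: str = "",
) -> ConservationResult:
    """Fraction of reference pairs conserved in the target species.

    A reference pair (ac, g) is conserved iff g has an ortholog g' and
    (ac, g') is a target pair; pairs whose gene lacks an ortholog leave the
    denominator.
    """
    ref = set(ref_pairs)
    target_keys = {_pair_key(p.anticodon, p.host_gene_id) for p in target_pairs}
    n_pairs = len(ref)
    n_no_orth = 0
    n_conserved = 0
    for p in ref:
        ortholog = ortholog_map.get(p.host_gene_id)
        if ortholog is None:
            n_no_orth += 1
        elif _pair_key(p.anticodon, ortholog) in target_keys:
            n_conserved += 1
    n_eval = n_pairs - n_no_orth
    return ConservationResult(
        ref_species=ref_species,
        target_species=target_species,
        pair_class=pair_class,
        n_pairs=n_pairs,
        n_no_ortholog=n_no_orth,
        n_evaluable=n_eval,
        n_conserved=n_conserved,
        fraction=n_conserved / n_eval if n_eval else None,
    )


def windowed_conservation(
    records: Sequence[tuple[str, str, int]],
    target_pairs: Iterable[AnticodonHostPair],
    ortholog_map: OrthologMap,
    cfg: WindowConfig = WindowConfig(),
    dedup: bool = False,
) -> list[WindowPoint]:
    """Conservation in sliding windows over distance-sorted non-intronic records.

    Window i covers sorted record indices [i*step, i*step + w). With
    ``dedup`` the records inside a window are first reduced to distinct
    (anticodon, gene) tuples; by default every tRNA record is scored.
    """
    n = len(records)
    w, k = cfg.window_size, cfg.n_windows
    if n < w:
        raise ValueError(
            f"{n} records < window size {w}; use a smaller window_size"
        )
    ordered = sorted(records, key=lambda r: (r[2], r[0], r[1]))
    step = cfg.step(n)
    target_keys = {_pair_key(p.anticodon, p.host_gene_id) for p in target_pairs}
    points = []
    last_covered = 0
    for i in range(k):
        lo = i * step
        hi = lo + w
        if hi > n:
            break
        window = ordered[lo:hi]
        last_covered = hi
        scored: Iterable[tuple[str, str]] = (
            {(ac, gene) for ac, gene, _ in window}
            if dedup
            else [(ac, gene) for ac, gene, _ in window]
        )
        n_eval = n_cons = 0
        for ac, gene in scored:
            ortholog = ortholog_map.get(gene)
            if ortholog is None:
                continue
            n_eval += 1
            if _pair_key(ac, ortholog) in target_keys:
                n_cons += 1
        points.append(
            WindowPoint(
                index=i,
                median_distance=float(np.median([d for _, _, d in window])),
                fraction=n_cons / n_eval if n_eval else None,
                n_evaluable=n_eval,
                n_conserved=n_cons,
                n_records=len(window),
            )
        )
    if last_covered < n:
        warnings.warn(
            f"windowed_conservation: {n - last_covered} largest-distance records "
            "fall outside all windows",
            stacklevel=2,
        )
    return points


def extrapolate_zero(
    points: Sequence[WindowPoint], degree: int = 3
) -> ExtrapolationResult:
    """Least-squares polynomial of window conservation vs median distance at x=0."""
    usable = [p for p in points if p.fraction is not None]
    if len(usable) < degree + 2:
        raise ValueError(f"need at least {degree + 2} windows with defined fractions")
    x = [p.median_distance for p in usable]
    y = [p.fraction for p in usable]
    coeffs, value, se = polyfit_predict(x, y, degree, 0.0)
    return ExtrapolationResult(degree, tuple(float(c) for c in coeffs), value, se)


def copy_number_vector(
    trnas: Sequence[TRNAGene], trna_class: str = "pseudo"
) -> dict[str, int]:
    """Gene copies per anticodon for one tRNA class (the species' tRNA pool)."""
    want_pseudo = _class_flag(trna_class)
    counts = Counter(t.anticodon for t in trnas if t.is_pseudo == want_pseudo)
    return dict(counts)


def copy_number_similarity(
    vec_a: Mapping[str, int],
    vec_b: Mapping[str, int],
    mode: str = "union",
) -> CorrelationResult:
    """Spearman similarity of two anticodon copy-number pools.

    ``union`` (default) scores every anticodon present in either pool with
    absent entries as 0; ``intersection`` restricts to shared anticodons.
    """
    if mode == "union":
        keys = sorted(set(vec_a) | set(vec_b))
    elif mode == "intersection":
        keys = sorted(set(vec_a) & set(vec_b))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(keys) < 3:
        raise ValueError("need at least 3 anticodons in the compared pools")
    a = [vec_a.get(k, 0) for k in keys]
    b = [vec_b.get(k, 0) for k in keys]
    return spearman(a, b)
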