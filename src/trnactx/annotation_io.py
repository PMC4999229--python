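"""Readers, writers and domain types for genome annotation inputs.

All coordinates are 0-based half-open internally (the UCSC convention of the
source tracks); 1-based inputs (tRNAscan tabular) are converted at the
boundary. Writers emit canonical TSV with a ``#``-prefixed header and an
optional ``##`` provenance comment, so canonicalized fixtures round-trip
byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__version__ = "0.1.0"

__all__ = [
    "ValidationError",
    "GenomeInterval",
    "GeneModel",
    "TRNAGene",
    "OrthologMap",
    "ExpressionTable",
    "SignalTrack",
    "read_gene_models",
    "write_gene_models",
    "read_trna_genes",
    "write_trna_genes",
    "read_signal_track",
    "write_signal_track",
    "read_mapping_table",
    "write_mapping_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_table",
]

TRNA_MIN_LEN = 60
TRNA_MAX_LEN = 200


class ValidationError(ValueError):
    """An input record violates a format or domain invariant."""


@dataclass(frozen=True)
class GenomeInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model: transcript span plus its exon chain."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        es, ee = self.exon_starts, self.exon_ends
        if len(es) != len(ee) or len(es) == 0:
            raise ValidationError(f"{self.gene_id}: exon start/end lists mismatch")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        for s, e in zip(es, ee):
            if not (0 <= s < e):
                raise ValidationError(f"{self.gene_id}: bad exon ({s},{e})")
        for i in range(1, len(es)):
            if es[i] <= ee[i - 1]:
                raise ValidationError(
                    f"{self.gene_id}: exons unsorted or overlapping at index {i}"
                )
        if es[0] != self.tx_start or ee[-1] != self.tx_end:
            raise ValidationError(
                f"{self.gene_id}: exon chain does not span [tx_start, tx_end)"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


@dataclass(frozen=True)
class TRNAGene:
    trna_id: str
    chrom: str
    strand: str
    start: int
    end: int
    amino_acid: str
    anticodon: str
    is_pseudo: bool = False
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT"):
            raise ValidationError(
                f"{self.trna_id}: anticodon {self.anticodon!r} is not 3 nt over ACGT"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.trna_id}: invalid strand {self.strand!r}")
        length = self.end - self.start
        if not (TRNA_MIN_LEN <= length <= TRNA_MAX_LEN):
            raise ValidationError(
                f"{self.trna_id}: length {length} outside "
                f"[{TRNA_MIN_LEN}, {TRNA_MAX_LEN}]"
            )

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def anchor(self) -> int:
        """Genomic position of the first mature nucleotide (5' end on own strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class OrthologMap:
    """One-to-one gene correspondence between a reference and a target species.

    ``entries`` maps every reference gene id either to its target ortholog or
    to None for an explicit "no ortholog" record.
    """

    species_pair: tuple[str, str]
    entries: dict[str, str | None]

    def get(self, ref_gene_id: str) -> str | None:
        return self.entries.get(ref_gene_id)


@dataclass
class ExpressionTable:
    """Gene-by-life-stage mean FPKM values (non-negative; NaN = missing)."""

    df: pd.DataFrame  # index: gene_id, columns: stages

    def __post_init__(self) -> None:
        if (self.df.to_numpy(dtype=float) < 0).any():
            raise ValidationError("expression table contains negative FPKM values")

    @property
    def stages(self) -> list[str]:
        return list(self.df.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)


class SignalTrack:
    """Piecewise-constant per-base signal; positions outside intervals are missing."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals.items():
            ivals = sorted(ivals)
            starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
            scores = np.array([v for _, _, v in ivals], dtype=float)
            if np.any(starts >= ends):
                bad = int(np.argmax(starts >= ends))
                raise ValidationError(
                    f"{chrom}: empty/inverted interval at {starts[bad]}-{ends[bad]}"
                )
            collide = np.nonzero(starts[1:] < ends[:-1])[0]
            if collide.size:
                i = int(collide[0])
                raise ValidationError(
                    f"{chrom}: overlapping intervals "
                    f"({starts[i]},{ends[i]}) and ({starts[i + 1]},{ends[i + 1]})"
                )
            self._data[chrom] = (starts, ends, scores)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> list[tuple[int, int, float]]:
        starts, ends, scores = self._data[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, scores)]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-base lookup; NaN where the position is unmeasured."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        if chrom not in self._data:
            return out
        starts, ends, scores = self._data[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions >= 0)
        safe = np.where(valid, idx, 0)
        inside = valid & (positions < ends[safe])
        out[inside] = scores[safe[inside]]
        return out

    def value_at(self, chrom: str, position: int) -> float:
        return float(self.values_at(chrom, np.array([position]))[0])


# ---------------------------------------------------------------------------
# low-level text helpers


def _fmt(v: float) -> str:
    """Canonical numeric formatting: integers bare, floats with repr precision."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    f = float(v)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _open_lines(path: str | Path) -> list[tuple[int, str]]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##") or line.startswith("track"):
                continue
            out.append((lineno, line))
    return out


def _write_text(path: str | Path, lines: Iterable[str], provenance: str | None) -> None:
    with open(path, "w") as fh:
        if provenance is not None:
            fh.write(f"## {provenance}\n")
        for line in lines:
            fh.write(line + "\n")


def write_table(
    path: str | Path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    provenance: str | None = None,
) -> None:
    """Write a generic result table as TSV with a #-prefixed header."""
    body = ["#" + "\t".join(columns)]
    for row in rows:
        body.append(
            "\t".join(
                _fmt(v) if isinstance(v, (int, float, np.floating, np.integer))
                and not isinstance(v, bool)
                else ("NA" if v is None else str(v))
                for v in row
            )
        )
    _write_text(path, body, provenance)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "genePred") -> list[GeneModel]:
    """Read gene models from genePred (refFlat dialect) or BED12."""
    if format not in ("genePred", "BED12"):
        raise ValueError(f"unknown gene-model format {format!r}")
    genes: list[GeneModel] = []
    for lineno, line in _open_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if format == "genePred":
                if len(fields) < 11:
                    raise ValidationError(f"expected 11 genePred fields, got {len(fields)}")
                gene_id, _, chrom, strand = fields[0], fields[1], fields[2], fields[3]
                tx_start, tx_end = int(fields[4]), int(fields[5])
                starts = tuple(int(x) for x in fields[9].rstrip(",").split(","))
                ends = tuple(int(x) for x in fields[10].rstrip(",").split(","))
            else:
                if len(fields) < 12:
                    raise ValidationError(f"expected 12 BED12 fields, got {len(fields)}")
                chrom, gene_id, strand = fields[0], fields[3], fields[5]
                tx_start, tx_end = int(fields[1]), int(fields[2])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                starts = tuple(tx_start + o for o in offsets)
                ends = tuple(s + z for s, z in zip(starts, sizes))
            genes.append(
                GeneModel(gene_id, chrom, strand, tx_start, tx_end, starts, ends)
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(
    path: str | Path,
    genes: Sequence[GeneModel],
    format: str = "genePred",
    provenance: str | None = None,
) -> None:
    lines = []
    for g in genes:
        if format == "genePred":
            lines.append(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.n_exons),
                        ",".join(map(str, g.exon_starts)) + ",",
                        ",".join(map(str, g.exon_ends)) + ",",
                    ]
                )
            )
        elif format == "BED12":
            sizes = [e - s for s, e in zip(g.exon_starts, g.exon_ends)]
            offs = [s - g.tx_start for s in g.exon_starts]
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(g.n_exons),
                        ",".join(map(str, sizes)) + ",",
                        ",".join(map(str, offs)) + ",",
                    ]
                )
            )
        else:
            raise ValueError(f"unknown gene-model format {format!r}")
    _write_text(path, lines, provenance)


# ---------------------------------------------------------------------------
# tRNA genes


def _normalize_anticodon(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_trna_genes(path: str | Path, format: str = "tRNAscan_tabular") -> list[TRNAGene]:
    """Read tRNA gene predictions.

    The tabular dialect carries 1-based inclusive coordinates with begin > end
    encoding the minus strand; the pseudo flag is parsed from the note column.
    """
    if format not in ("tRNAscan_tabular", "BED"):
        raise ValueError(f"unknown tRNA format {format!r}")
    trnas: list[TRNAGene] = []
    for lineno, line in _open_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if format == "tRNAscan_tabular":
                if len(fields) < 10:
                    raise ValidationError(
                        f"expected 10 tRNAscan fields, got {len(fields)}"
                    )
                name, chrom = fields[0], fields[1]
                begin, end1 = int(fields[2]), int(fields[3])
                aa, anticodon = fields[4], _normalize_anticodon(fields[5])
                score = None if fields[8] in (".", "") else float(fields[8])
                note = fields[9]
                strand = "+" if begin <= end1 else "-"
                start = min(begin, end1) - 1  # 1-based inclusive -> 0-based half-open
                end = max(begin, end1)
                is_pseudo = "pseudo" in note.lower()
            else:
                if len(fields) < 6:
                    raise ValidationError(f"expected 6 BED fields, got {len(fields)}")
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name_parts = fields[3].split("|")
                if len(name_parts) != 4:
                    raise ValidationError(
                        "BED name must be id|aa|anticodon|{trna,pseudo}"
                    )
                name, aa, anticodon, flag = name_parts
                anticodon = _normalize_anticodon(anticodon)
                is_pseudo = flag == "pseudo"
                score = None if fields[4] in (".", "0") else float(fields[4])
                strand = fields[5]
            trnas.append(
                TRNAGene(name, chrom, strand, start, end, aa, anticodon, is_pseudo, score)
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return trnas


def write_trna_genes(
    path: str | Path,
    trnas: Sequence[TRNAGene],
    format: str = "tRNAscan_tabular",
    provenance: str | None = None,
) -> None:
    lines = []
    for t in trnas:
        if format == "tRNAscan_tabular":
            begin, end1 = (t.start + 1, t.end) if t.strand == "+" else (t.end, t.start + 1)
            lines.append(
                "\t".join(
                    [
                        t.trna_id,
                        t.chrom,
                        str(begin),
                        str(end1),
                        t.amino_acid,
                        t.anticodon,
                        "0",
                        "0",
                        "." if t.score is None else _fmt(t.score),
                        "pseudo" if t.is_pseudo else "",
                    ]
                )
            )
        elif format == "BED":
            name = "|".join(
                [t.trna_id, t.amino_acid, t.anticodon, "pseudo" if t.is_pseudo else "trna"]
            )
            lines.append(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        name,
                        "0" if t.score is None else _fmt(t.score),
                        t.strand,
                    ]
                )
            )
        else:
            raise ValueError(f"unknown tRNA format {format!r}")
    _write_text(path, lines, provenance)


# ---------------------------------------------------------------------------
# signal tracks (bedGraph)


def read_signal_track(path: str | Path) -> SignalTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _open_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 bedGraph fields")
        try:
            chrom = fields[0]
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        intervals.setdefault(chrom, []).append((start, end, value))
    try:
        return SignalTrack(intervals)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_signal_track(
    path: str | Path, track: SignalTrack, provenance: str | None = None
) -> None:
    lines = []
    for chrom in sorted(track.chroms):
        for start, end, value in track.intervals(chrom):
            lines.append(f"{chrom}\t{start}\t{end}\t{_fmt(value)}")
    _write_text(path, lines, provenance)


# ---------------------------------------------------------------------------
# mapping tables (orthologs, expression) and chromosome sizes


def read_mapping_table(path: str | Path, kind: str) -> OrthologMap | ExpressionTable:
    lines = _open_lines(path)
    if not lines:
        raise ValidationError(f"{path}: empty mapping table (header required)")
    first_lineno, header_line = lines[0]
    if not header_line.startswith("#"):
        raise ValidationError(f"{path}:{first_lineno}: header row required")
    header = header_line.lstrip("#").split("\t")
    body = lines[1:]
    if kind == "ortholog":
        if len(header) < 2:
            raise ValidationError(f"{path}: ortholog table needs 2 columns")
        entries: dict[str, str | None] = {}
        for lineno, line in body:
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            ref, target = fields[0], fields[1]
            if ref in entries:
                raise ValidationError(f"{path}:{lineno}: duplicate reference key {ref!r}")
            entries[ref] = None if target in ("NA", "", ".") else target
        return OrthologMap((header[0], header[1]), entries)
    if kind == "expression":
        stages = header[1:]
        if not stages:
            raise ValidationError(f"{path}: expression table needs stage columns")
        index, values = [], []
        for lineno, line in body:
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValidationError(f"{path}:{lineno}: column count mismatch")
            gene = fields[0]
            if gene in index:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            row = []
            for stage, raw in zip(stages, fields[1:]):
                if raw == "NA":
                    row.append(math.nan)
                    continue
                try:
                    v = float(raw)
                except ValueError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
                if v < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative FPKM {v} for {gene!r} at {stage}"
                    )
                row.append(v)
            index.append(gene)
            values.append(row)
        df = pd.DataFrame(values, index=index, columns=stages)
        df.index.name = "gene_id"
        return ExpressionTable(df)
    raise ValueError(f"unknown mapping-table kind {kind!r}")


def write_mapping_table(
    path: str | Path,
    table: OrthologMap | ExpressionTable,
    provenance: str | None = None,
) -> None:
    if isinstance(table, OrthologMap):
        lines = ["#" + "\t".join(table.species_pair)]
        for ref in table.entries:
            target = table.entries[ref]
            lines.append(f"{ref}\t{'NA' if target is None else target}")
    elif isinstance(table, ExpressionTable):
        lines = ["#gene_id\t" + "\t".join(table.stages)]
        for gene, row in table.df.iterrows():
            lines.append(gene + "\t" + "\t".join(_fmt(v) for v in row))
    else:
        raise TypeError(f"cannot write {type(table).__name__}")
    _write_text(path, lines, provenance)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in _open_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
        chrom, size = fields[0], int(fields[1])
        if size <= 0 or chrom in sizes:
            raise ValidationError(f"{path}:{lineno}: bad chrom-sizes entry")
        sizes[chrom] = size
    return sizes


def write_chrom_sizes(
    path: str | Path, sizes: Mapping[str, int], provenance: str | None = None
) -> None:
    _write_text(path, [f"{c}\t{s}" for c, s in sizes.items()], provenance)
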