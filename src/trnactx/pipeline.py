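"""End-to-end orchestration: classification, conservation, profiles, breadth.

``run_all`` consumes a directory bundle (one sub-directory per species, as
written by :mod:`trnactx.synthetic_data` or assembled from real annotation
exports), runs every analysis stage, and writes one TSV per result family
plus a summary report. All outputs are pure functions of the inputs and the
configured seed, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import annotation_io as aio
from .annotation_io import ValidationError, write_table
from .expression_breadth import resampling_test
from .genome_context import classify_trnas, intronic_fraction_test, merged_intron_bp
from .pairing_conservation import (
    WindowConfig,
    build_pairs,
    conservation_fraction,
    copy_number_similarity,
    copy_number_vector,
    extrapolate_zero,
    neighbor_pairs,
    neighbor_records,
    windowed_conservation,
)
from .signal_profiles import (
    build_profile_matrix,
    compare_groups,
    correlate_scores,
    mean_profile,
    window_scores,
)

__version__ = "0.1.0"

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_all"]


@dataclass
class RunConfig:
    ref_dir: str
    out_dir: str
    target_dirs: list[str] = field(default_factory=list)
    ortholog_files: list[str] = field(default_factory=list)  # parallel to target_dirs
    flank: int = 1000
    occupancy_window: tuple[int, int] = (-100, 100)
    h3k4me3_window: tuple[int, int] = (-500, -100)
    h3k27ac_window: tuple[int, int] = (-200, 200)
    window_size: int = 40
    n_windows: int = 20
    n_resamples: int = 500
    seed: int = 0
    containment: str = "intron"

    def validate(self) -> None:
        if len(self.target_dirs) != len(self.ortholog_files):
            raise ValidationError("target_dirs and ortholog_files must align")
        for p in (self.ref_dir, *self.target_dirs, *self.ortholog_files):
            if not Path(p).exists():
                raise ValidationError(f"missing input path: {p}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("occupancy_window", "h3k4me3_window", "h3k27ac_window"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass
class _Species:
    name: str
    genes: list
    trnas: list
    chrom_sizes: dict[str, int]
    occupancy: aio.SignalTrack | None = None
    h3k4me3: aio.SignalTrack | None = None
    h3k27ac: aio.SignalTrack | None = None
    expression: aio.ExpressionTable | None = None


def _load_species(dir_path: str | Path, with_tracks: bool) -> _Species:
    d = Path(dir_path)
    sp = _Species(
        name=d.name,
        genes=aio.read_gene_models(d / "genes.genePred", "genePred"),
        trnas=aio.read_trna_genes(d / "trnas.tsv", "tRNAscan_tabular"),
        chrom_sizes=aio.read_chrom_sizes(d / "chrom.sizes"),
    )
    if with_tracks:
        for attr, fname in (
            ("occupancy", "occupancy.bedGraph"),
            ("h3k4me3", "h3k4me3.bedGraph"),
            ("h3k27ac", "h3k27ac.bedGraph"),
        ):
            if (d / fname).exists():
                setattr(sp, attr, aio.read_signal_track(d / fname))
        if (d / "expression.tsv").exists():
            sp.expression = aio.read_mapping_table(d / "expression.tsv", "expression")
    return sp


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every analysis stage and write the report bundle.

    Stages: classify -> pairs -> conservation (host / neighbor / pseudo
    nulls) -> distance windows + cubic extrapolation -> signal profiles and
    group tests -> pseudo-pool similarity -> expression breadth. Returns the
    in-memory results keyed by report section.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"trnactx {__version__} seed={config.seed}"
    results: dict[str, Any] = {}
    report_rows: list[tuple] = []

    ref = _stage("load_ref")(_load_species)(config.ref_dir, with_tracks=True)

    # --- classification -----------------------------------------------------
    assignments, summary = _stage("classify")(classify_trnas)(
        ref.trnas, ref.genes, config.containment
    )
    results["assignments"] = assignments
    results["summary"] = summary
    write_table(
        out / "assignments.tsv",
        [
            "trna_id", "status", "host_gene_id", "host_intron_index", "same_strand",
            "upstream_gene", "upstream_distance", "downstream_gene",
            "downstream_distance", "ambiguous_overlap", "host_tie",
        ],
        [
            (
                a.trna_id, a.status, a.host_gene_id, a.host_intron_index,
                a.same_strand,
                a.upstream_neighbor[0] if a.upstream_neighbor else None,
                a.upstream_neighbor[1] if a.upstream_neighbor else None,
                a.downstream_neighbor[0] if a.downstream_neighbor else None,
                a.downstream_neighbor[1] if a.downstream_neighbor else None,
                a.ambiguous_overlap, a.host_tie,
            )
            for a in assignments
        ],
        prov,
    )
    genome_size = sum(ref.chrom_sizes.values())
    chisq = _stage("intronic_fraction_test")(intronic_fraction_test)(
        summary, ref.genes, genome_size, "all"
    )
    results["chisq"] = chisq
    write_table(
        out / "summary.tsv",
        [
            "subset", "n_trnas", "n_intronic", "n_non_intronic",
            "fraction_intronic", "fraction_same_strand_of_intronic",
        ],
        [
            (
                name, c.n_trnas, c.n_intronic, c.n_non_intronic,
                round(c.fraction_intronic, 6),
                round(c.fraction_same_strand_of_intronic, 6),
            )
            for name, c in summary.subsets.items()
        ],
        prov,
    )
    report_rows.append(
        ("intronic_fraction_all", round(summary["all"].fraction_intronic, 6))
    )
    report_rows.append(("intronic_chisq_statistic", round(chisq.statistic, 6)))
    report_rows.append(("intronic_chisq_p", round(chisq.p, 6)))
    report_rows.append(
        ("genome_intron_proportion", round(merged_intron_bp(ref.genes) / genome_size, 6))
    )

    # --- pairing and conservation -------------------------------------------
    ref_pairs = build_pairs(assignments, ref.trnas, "functional", ref.name)
    ref_pairs_pseudo = build_pairs(assignments, ref.trnas, "pseudo", ref.name)
    up_records = neighbor_records(assignments, ref.trnas, "upstream")
    results["ref_pairs"] = ref_pairs
    report_rows.append(("n_anticodon_host_pairs", len(ref_pairs)))
    report_rows.append(
        ("n_unique_host_genes", len({p.host_gene_id for p in ref_pairs}))
    )

    conservation_rows = []
    window_rows = []
    extrap_rows = []
    copy_rows = []
    results["conservation"] = {}
    results["extrapolation"] = {}
    cfg_windows = WindowConfig(config.window_size, config.n_windows)
    for target_dir, orth_file in zip(config.target_dirs, config.ortholog_files):
        target = _stage("load_target")(_load_species)(target_dir, with_tracks=False)
        omap = aio.read_mapping_table(orth_file, "ortholog")
        t_assign, _ = classify_trnas(target.trnas, target.genes, config.containment)
        t_pairs = {
            "intronic_host": build_pairs(t_assign, target.trnas, "functional"),
            "pseudo_intronic_host": build_pairs(t_assign, target.trnas, "pseudo"),
            "upstream_neighbor": neighbor_pairs(t_assign, target.trnas, "upstream"),
            "downstream_neighbor": neighbor_pairs(t_assign, target.trnas, "downstream"),
        }
        ref_sets = {
            "intronic_host": ref_pairs,
            "pseudo_intronic_host": ref_pairs_pseudo,
            "upstream_neighbor": neighbor_pairs(assignments, ref.trnas, "upstream"),
            "downstream_neighbor": neighbor_pairs(assignments, ref.trnas, "downstream"),
        }
        for pair_class, rset in ref_sets.items():
            res = conservation_fraction(
                rset, t_pairs[pair_class], omap, pair_class, ref.name, target.name
            )
            results["conservation"][(target.name, pair_class)] = res
            conservation_rows.append(
                (
                    res.ref_species, res.target_species, res.pair_class,
                    res.n_pairs, res.n_no_ortholog, res.n_evaluable,
                    res.n_conserved,
                    None if res.fraction is None else round(res.fraction, 6),
                )
            )
        if len(up_records) >= cfg_windows.window_size:
            points = windowed_conservation(
                up_records, t_pairs["upstream_neighbor"], omap, cfg_windows
            )
            for p in points:
                window_rows.append(
                    (
                        target.name, p.index, p.median_distance,
                        None if p.fraction is None else round(p.fraction, 6),
                        p.n_evaluable, p.n_conserved, p.n_records,
                    )
                )
            try:
                ext = extrapolate_zero(points)
                results["extrapolation"][target.name] = ext
                extrap_rows.append(
                    (
                        target.name, ext.degree,
                        round(ext.value_at_zero, 6), round(ext.se_at_zero, 6),
                    )
                )
            except ValueError as exc:
                logger.warning("extrapolation skipped for %s: %s", target.name, exc)
        ref_pool = copy_number_vector(ref.trnas, "pseudo")
        t_pool = copy_number_vector(target.trnas, "pseudo")
        if len(set(ref_pool) | set(t_pool)) >= 3:
            corr = copy_number_similarity(ref_pool, t_pool)
            copy_rows.append(
                (
                    ref.name, target.name, "pseudo",
                    round(corr.rho, 6), corr.n, round(corr.p_two_sided, 6),
                )
            )
            results.setdefault("copy_number", {})[target.name] = corr

    write_table(
        out / "conservation.tsv",
        [
            "ref_species", "target_species", "pair_class", "n_pairs",
            "n_no_ortholog", "n_evaluable", "n_conserved", "fraction",
        ],
        conservation_rows, prov,
    )
    write_table(
        out / "windows.tsv",
        [
            "target_species", "window", "median_distance", "fraction",
            "n_evaluable", "n_conserved", "n_records",
        ],
        window_rows, prov,
    )
    write_table(
        out / "extrapolation.tsv",
        ["target_species", "degree", "value_at_zero", "se_at_zero"],
        extrap_rows, prov,
    )
    write_table(
        out / "copy_number.tsv",
        ["ref_species", "target_species", "class", "spearman_rho", "n", "p"],
        copy_rows, prov,
    )
    host_fracs = [
        r[7] for r in conservation_rows if r[2] == "intronic_host" and r[7] is not None
    ]
    if host_fracs:
        report_rows.append(("conservation_host_min", min(host_fracs)))
        report_rows.append(("conservation_host_max", max(host_fracs)))

    # --- signal profiles and group comparisons ------------------------------
    functional = [t for t in ref.trnas if not t.is_pseudo]
    intronic_ids = {a.trna_id for a in assignments if a.status == "intronic"}
    same_strand_ids = {
        a.trna_id for a in assignments if a.status == "intronic" and a.same_strand
    }
    if ref.occupancy is not None:
        occ = _stage("occupancy_scores")(window_scores)(
            ref.occupancy, functional, config.occupancy_window
        )
        results["occupancy_scores"] = occ
        write_table(
            out / "window_scores.tsv",
            ["trna_id", "occupancy", "status"],
            [
                (
                    tid, round(v, 6),
                    "intronic" if tid in intronic_ids else "non_intronic",
                )
                for tid, v in occ.items()
            ],
            prov,
        )
        a = [v for k, v in occ.items() if k in intronic_ids]
        b = [v for k, v in occ.items() if k not in intronic_ids]
        group_rows = []
        test = compare_groups(a, b)
        results["occupancy_test"] = test
        group_rows.append(
            (
                "intronic_vs_non_intronic", test.n_a, test.n_b,
                round(test.statistic, 2), test.method, repr(test.p_two_sided),
            )
        )
        report_rows.append(("occupancy_ranksum_p", repr(test.p_two_sided)))
        a_same = [v for k, v in occ.items() if k in same_strand_ids]
        a_opp = [
            v for k, v in occ.items()
            if k in intronic_ids and k not in same_strand_ids
        ]
        if a_same and a_opp:
            strand_test = compare_groups(a_same, a_opp)
            results["strand_test"] = strand_test
            group_rows.append(
                (
                    "same_strand_vs_opposite", strand_test.n_a, strand_test.n_b,
                    round(strand_test.statistic, 2), strand_test.method,
                    repr(strand_test.p_two_sided),
                )
            )
            report_rows.append(
                ("same_strand_ranksum_p", repr(strand_test.p_two_sided))
            )
        write_table(
            out / "group_tests.tsv",
            ["comparison", "n_a", "n_b", "ranksum_statistic", "method", "p_two_sided"],
            group_rows, prov,
        )
        corr_rows = []
        for mark, track, window in (
            ("h3k4me3", ref.h3k4me3, config.h3k4me3_window),
            ("h3k27ac", ref.h3k27ac, config.h3k27ac_window),
        ):
            if track is None:
                continue
            mark_scores = window_scores(track, functional, window)
            corr = correlate_scores(occ, mark_scores)
            results[f"corr_{mark}"] = corr
            corr_rows.append(
                (f"occupancy_vs_{mark}", round(corr.rho, 6), corr.n,
                 round(corr.p_two_sided, 6))
            )
            report_rows.append((f"occupancy_{mark}_spearman", round(corr.rho, 6)))
            profile_means, profile_n = mean_profile(
                build_profile_matrix(track, functional, config.flank)
            )
            write_table(
                out / f"profile_{mark}.tsv",
                ["offset", "mean", "n"],
                [
                    (int(off), None if np.isnan(m) else round(float(m), 6), int(nn))
                    for off, m, nn in zip(
                        range(-config.flank, config.flank), profile_means, profile_n
                    )
                ],
                prov,
            )
        write_table(
            out / "correlations.tsv",
            ["comparison", "spearman_rho", "n", "p_two_sided"],
            corr_rows, prov,
        )

    # --- expression breadth --------------------------------------------------
    if ref.expression is not None:
        host_genes = sorted(
            {
                a.host_gene_id
                for a in assignments
                if a.status == "intronic" and a.trna_id in {t.trna_id for t in functional}
            }
        )
        breadth = _stage("breadth")(resampling_test)(
            host_genes, ref.expression, config.n_resamples, config.seed
        )
        results["breadth"] = breadth
        write_table(
            out / "breadth.tsv",
            [
                "stage", "observed_sd", "n_resamples", "n_as_or_more_extreme",
                "empirical_p", "resample_min", "resample_median", "resample_max",
                "n_hosts",
            ],
            [
                (
                    r.stage, round(r.observed_stat, 6), r.n_resamples,
                    r.n_as_or_more_extreme, round(r.empirical_p, 6),
                    round(r.resample_min, 6), round(r.resample_median, 6),
                    round(r.resample_max, 6), r.n_hosts_used,
                )
                for r in breadth.values()
            ],
            prov,
        )
        for stage_name, r in breadth.items():
            report_rows.append(
                (f"breadth_p_{stage_name}", round(r.empirical_p, 6))
            )

    write_table(out / "report.tsv", ["quantity", "value"], report_rows, prov)
    results["report"] = dict(report_rows)
    return results
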