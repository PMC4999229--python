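"""Resampling test for the expression breadth of tRNA-hosting genes.

Asks whether the distribution of host-gene expression is *narrower* than
expected for an equally-sized random gene set. Width is the sample standard
deviation of log10(FPKM + 1) (IQR available); the null is built by drawing
random gene sets of the same size and the one-sided empirical p is
(r + 1) / (N + 1), r counting resamples at least as narrow as observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation_io import ExpressionTable
from .stats_core import empirical_p

__all__ = ["BreadthResult", "breadth_statistic", "resampling_test"]

logger = logging.getLogger(__name__)

DEFAULT_N_RESAMPLES = 500


@dataclass(frozen=True)
class BreadthResult:
    stage: str
    observed_stat: float
    n_resamples: int
    n_as_or_more_extreme: int
    empirical_p: float
    resample_min: float
    resample_median: float
    resample_max: float
    n_hosts_used: int


def _transform(values: np.ndarray) -> np.ndarray:
    return np.log10(values + 1.0)


def breadth_statistic(expr_values: Sequence[float], stat: str = "sd") -> float:
    """Width of an expression-level distribution on the log10(x+1) scale."""
    v = np.asarray(expr_values, dtype=float)
    if v.size < 2:
        raise ValueError("breadth statistic needs at least 2 values")
    t = _transform(v)
    if stat == "sd":
        return float(t.std(ddof=1))
    if stat == "iqr":
        q75, q25 = np.percentile(t, [75, 25])
        return float(q75 - q25)
    raise ValueError(f"unknown stat {stat!r}")


def resampling_test(
    host_gene_ids: Sequence[str],
    expr: ExpressionTable,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    stat: str = "sd",
    set_size: int | None = None,
) -> dict[str, BreadthResult]:
    """Per-stage one-sided resampling test for narrow host-gene expression.

    For each life stage, draws ``n_resamples`` random gene sets (without
    replacement within a set, sets independent) matching the host-set size
    from the genes with a defined value at that stage. Host genes missing a
    stage value are dropped for that stage and the effective size used for
    resampling. Deterministic given ``seed``.
    """
    hosts = set(host_gene_ids)
    results: dict[str, BreadthResult] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(expr.stages))
    for stage, stage_seed in zip(expr.stages, seeds):
        col = expr.df[stage].dropna()
        background = col.index.to_numpy()
        stage_hosts = sorted(hosts & set(background))
        dropped = len(hosts) - len(stage_hosts)
        if dropped:
            logger.info(
                "stage %s: dropped %d host genes without expression values",
                stage,
                dropped,
            )
        m = set_size if set_size is not None else len(stage_hosts)
        if m < 2:
            raise ValueError(f"stage {stage}: host set too small ({m})")
        if m > background.size:
            raise ValueError(
                f"stage {stage}: set size {m} exceeds {background.size} genes"
            )
        observed = breadth_statistic(col.loc[stage_hosts].to_numpy(), stat)
        rng = np.random.default_rng(stage_seed)
        log_values = _transform(col.to_numpy(dtype=float))
        stats = np.empty(n_resamples)
        for i in range(n_resamples):
            idx = rng.choice(background.size, size=m, replace=False)
            sample = log_values[idx]
            if stat == "sd":
                stats[i] = sample.std(ddof=1)
            else:
                q75, q25 = np.percentile(sample, [75, 25])
                stats[i] = q75 - q25
        r = int((stats <= observed).sum())
        results[stage] = BreadthResult(
            stage=stage,
            observed_stat=observed,
            n_resamples=n_resamples,
            n_as_or_more_extreme=r,
            empirical_p=empirical_p(observed, stats, tail="lower"),
            resample_min=float(stats.min()),
            resample_median=float(np.median(stats)),
            resample_max=float(stats.max()),
            n_hosts_used=len(stage_hosts),
        )
    return results
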