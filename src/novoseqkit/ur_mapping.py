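"""Flag-filtered unmapped-read counting and cross-population statistics.

Counting follows the samtools idiom ``view -F 2048 | view -F 256`` for
totals with an additional ``-F 4`` for mapped reads: secondary (0x100)
and supplementary (0x800) records never contribute, so each read counts
exactly once through its primary record.

Per-individual mapped fractions feed a one-way ANOVA with Tukey HSD
across populations; two NS catalogs are compared with a two-sided
Mann-Whitney U test.  Depletion curves report the fraction of mapped
reads remaining when clusters below an allele-frequency threshold are
removed (boundary inclusive: a cluster survives threshold t iff
AF >= t), with the denominator fixed at the total mapped-read count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .formats_io import (
    SAM_FLAG_SECONDARY,
    SAM_FLAG_SUPPLEMENTARY,
    SAM_FLAG_UNMAPPED,
    SamFlagRecord,
)

__all__ = [
    "MappingFraction",
    "DepletionCurve",
    "DEFAULT_AF_THRESHOLDS",
    "count_reads",
    "mapping_fraction",
    "primary_assignments",
    "depletion_curve",
    "compare_two_references",
    "population_anova_tukey",
]

DEFAULT_AF_THRESHOLDS = (0.005, 0.01, 0.025, 0.05, 0.075, 0.10)


@dataclass
class MappingFraction:
    individual_id: str
    population: str
    n_total: int
    n_mapped: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_mapped <= self.n_total):
            raise ValueError("need 0 <= n_mapped <= n_total")

    @property
    def fraction(self) -> float:
        return self.n_mapped / self.n_total if self.n_total else float("nan")


@dataclass
class DepletionCurve:
    individual_id: str
    remaining_fraction: dict[float, float]

    def __post_init__(self) -> None:
        ordered = sorted(self.remaining_fraction)
        values = [self.remaining_fraction[t] for t in ordered]
        if any(b > a + 1e-12 for a, b in zip(values, values[1:])):
            raise ValueError("remaining fraction must be non-increasing")


def count_reads(stream: Iterable[SamFlagRecord]) -> tuple[int, int]:
    """(n_total, n_mapped) with secondary and supplementary records
    excluded from both counts."""
    n_total = n_mapped = 0
    for rec in stream:
        if rec.flag & (SAM_FLAG_SECONDARY | SAM_FLAG_SUPPLEMENTARY):
            continue
        n_total += 1
        if not rec.flag & SAM_FLAG_UNMAPPED:
            n_mapped += 1
    return n_total, n_mapped


def mapping_fraction(
    stream: Iterable[SamFlagRecord], individual_id: str, population: str = "."
) -> MappingFraction:
    n_total, n_mapped = count_reads(stream)
    return MappingFraction(individual_id, population, n_total, n_mapped)


def primary_assignments(
    stream: Iterable[SamFlagRecord],
) -> Iterator[tuple[str, str]]:
    """(read_id, cluster_id) for every mapped primary record."""
    for rec in stream:
        if rec.flag & (SAM_FLAG_SECONDARY | SAM_FLAG_SUPPLEMENTARY):
            continue
        if rec.flag & SAM_FLAG_UNMAPPED:
            continue
        yield rec.read_id, rec.target_id


def depletion_curve(
    assignments: Iterable[tuple[str, str]],
    cluster_af: dict[str, float],
    thresholds=DEFAULT_AF_THRESHOLDS,
    individual_id: str = ".",
) -> DepletionCurve:
    """Fraction of mapped reads remaining after removing clusters with
    allele frequency below each threshold.

    The denominator is the total mapped-read count, fixed across
    thresholds, so the curve starts at 1 for threshold 0 and is
    non-increasing.
    """
    afs = []
    for read_id, cluster_id in assignments:
        if cluster_id not in cluster_af:
            raise ValueError(f"read {read_id!r} assigned to unknown cluster {cluster_id!r}")
        afs.append(cluster_af[cluster_id])
    afs_arr = np.asarray(afs, dtype=np.float64)
    n = len(afs_arr)
    curve = {0.0: 1.0}
    for t in thresholds:
        curve[float(t)] = float((afs_arr >= t).sum() / n) if n else float("nan")
    return DepletionCurve(individual_id=individual_id, remaining_fraction=curve)


def compare_two_references(
    fractions_ref_a, fractions_ref_b, exact_max_n: int = 20
) -> dict:
    """Two-sided Mann-Whitney U comparison of per-individual mapped
    fractions under two NS catalogs.

    Exact U distribution for small samples (combined n <= 20, no ties),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(list(fractions_ref_a), dtype=np.float64)
    b = np.asarray(list(fractions_ref_b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_value": float(res.pvalue), "method": method}


def population_anova_tukey(populations: dict[str, list[float]]) -> dict:
    """One-way fixed-effects ANOVA plus Tukey HSD on all population pairs.

    Returns the F statistic, the ANOVA p-value, and a dict of pairwise
    Tukey-adjusted p-values keyed by (population_a, population_b).
    """
    if len(populations) < 2:
        raise ValueError("need at least two groups")
    for name, vals in populations.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    names = sorted(populations)
    groups = [np.asarray(populations[n], dtype=np.float64) for n in names]
    values_all = np.concatenate(groups)
    if np.ptp(values_all) == 0:  # degenerate: no variation anywhere
        from itertools import combinations

        return {
            "F": 0.0,
            "p_value": 1.0,
            "tukey_p": {pair: 1.0 for pair in combinations(names, 2)},
        }
    f_stat, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([[n] * len(g) for n, g in zip(names, groups)])
    tukey = pairwise_tukeyhsd(values, labels)
    # result rows follow combinations() over the sorted unique group labels
    from itertools import combinations

    pairwise = {
        (str(g1), str(g2)): float(pv)
        for (g1, g2), pv in zip(combinations(tukey.groupsunique, 2), tukey.pvalues)
    }
    return {"F": float(f_stat), "p_value": float(p), "tukey_p": pairwise}
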