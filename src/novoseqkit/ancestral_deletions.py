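"""Ancestral NS as deletions relative to a chimp-like reference.

High-quality (PASS, symbolic <DEL>) deletion calls from many individuals
are merged by reciprocal overlap >= 0.7 (single-linkage components),
intersected with the NS intervals on chimp coordinates, checked for
novelty against the human reference (liftover verdict consumed as a
status flag), and summarised as chimpanzee-reference-allele (CRA)
carrier frequencies: an individual carries the CRA iff it is NOT
homozygous for the deletion, so carriers = N - #hom_alt; missing
genotypes and individuals without a call count as carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .formats_io import DeletionRecord, GenomicInterval

__all__ = [
    "MergedDeletion",
    "filter_deletions",
    "merge_by_reciprocal_overlap",
    "intersect_with_ns",
    "check_novelty",
    "cra_frequency",
]

logger = logging.getLogger(__name__)

_GT_RANK = {"hom_alt": 3, "het": 2, "hom_ref": 1, "missing": 0}


@dataclass
class MergedDeletion:
    chrom: str
    start: int
    end: int
    genotypes: dict[str, str]  # individual -> genotype
    records: list[DeletionRecord] = field(default_factory=list)
    overlapping_ns_ids: set[str] = field(default_factory=set)
    novel_vs_human: bool | None = None
    cra_carriers: int | None = None
    cra_carrier_freq: float | None = None
    cra_allele_freq: float | None = None
    common: bool | None = None

    @property
    def n_individuals_with_call(self) -> int:
        return len(self.genotypes)

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_deletions(
    records: list[DeletionRecord],
) -> list[DeletionRecord]:
    """Keep only PASS records with SVTYPE DEL; removal counts are logged."""
    kept = [r for r in records if r.filter_status == "PASS" and r.svtype == "DEL"]
    n_filter = sum(1 for r in records if r.filter_status != "PASS")
    n_type = sum(1 for r in records if r.filter_status == "PASS" and r.svtype != "DEL")
    logger.info(
        "filter_deletions: kept %d of %d (removed %d non-PASS, %d non-DEL)",
        len(kept), len(records), n_filter, n_type,
    )
    return kept


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _reciprocal(a: DeletionRecord, b: DeletionRecord, t: float) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov > 0 and ov / a.length >= t and ov / b.length >= t


def merge_by_reciprocal_overlap(
    records: list[DeletionRecord], min_overlap: float = 0.7
) -> list[MergedDeletion]:
    """Single-linkage merge of deletions linked by reciprocal overlap.

    Two records link iff the shared span is at least ``min_overlap`` of
    BOTH lengths.  The representative coordinates come from the longest
    member (ties: leftmost); an individual with several linked calls
    keeps its most deleted genotype (hom_alt > het > hom_ref > missing).
    """
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].start))
    uf = _UnionFind(len(records))
    active: list[int] = []
    for i in order:
        rec = records[i]
        still = []
        for j in active:
            other = records[j]
            if other.chrom != rec.chrom or other.end <= rec.start:
                continue
            still.append(j)
            if _reciprocal(rec, other, min_overlap):
                uf.union(i, j)
        active = still + [i]

    components: dict[int, list[int]] = {}
    for i in range(len(records)):
        components.setdefault(uf.find(i), []).append(i)
    merged = []
    for comp in components.values():
        members = [records[i] for i in comp]
        rep = min(members, key=lambda r: (-r.length, r.start, r.chrom))
        genotypes: dict[str, str] = {}
        for r in members:
            prev = genotypes.get(r.individual_id)
            if prev is None or _GT_RANK[r.genotype] > _GT_RANK[prev]:
                genotypes[r.individual_id] = r.genotype
        merged.append(
            MergedDeletion(
                chrom=rep.chrom,
                start=rep.start,
                end=rep.end,
                genotypes=genotypes,
                records=members,
            )
        )
    merged.sort(key=lambda m: (m.chrom, m.start, m.end))
    return merged


def intersect_with_ns(
    merged: list[MergedDeletion], ns_intervals: list[GenomicInterval]
) -> list[MergedDeletion]:
    """Annotate each merged deletion with the NS ids it overlaps
    (>= 1 shared base); returns the input list, annotated in place."""
    trees: dict[str, IntervalTree] = {}
    for iv in ns_intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.label)
    for m in merged:
        tree = trees.get(m.chrom)
        m.overlapping_ns_ids = (
            {hit.data for hit in tree.overlap(m.start, m.end)} if tree else set()
        )
    return merged


def check_novelty(
    merged: list[MergedDeletion],
    novelty_status: list[tuple[GenomicInterval, str]],
) -> list[MergedDeletion]:
    """Flag each merged deletion novel iff it overlaps a status interval
    with verdict ``deleted_in_new`` (the liftover error message case)."""
    trees: dict[str, IntervalTree] = {}
    for iv, status in novelty_status:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, status)
    for m in merged:
        tree = trees.get(m.chrom)
        hits = tree.overlap(m.start, m.end) if tree else set()
        m.novel_vs_human = any(h.data == "deleted_in_new" for h in hits)
    return merged


def cra_frequency(
    merged: MergedDeletion, n_individuals: int, common_threshold: float = 0.05
) -> MergedDeletion:
    """CRA carrier count and frequency for one merged deletion.

    Carriers are individuals NOT homozygous for the deletion: genotypes
    hom_ref, het and missing all count, as do individuals absent from
    the genotype map (no deletion call).  ``common`` iff the carrier
    frequency exceeds the threshold.  An allele-frequency estimate
    (2N - 2 hom_alt - het) / 2N is reported alongside, clearly a
    different quantity from the carrier frequency.
    """
    if n_individuals < len(merged.genotypes):
        raise ValueError(
            f"{len(merged.genotypes)} genotyped individuals exceed cohort size "
            f"{n_individuals}"
        )
    n_hom = sum(1 for g in merged.genotypes.values() if g == "hom_alt")
    n_het = sum(1 for g in merged.genotypes.values() if g == "het")
    merged.cra_carriers = n_individuals - n_hom
    merged.cra_carrier_freq = merged.cra_carriers / n_individuals
    merged.cra_allele_freq = (2 * n_individuals - 2 * n_hom - n_het) / (
        2 * n_individuals
    )
    merged.common = merged.cra_carrier_freq > common_threshold
    return merged
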