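"""Contig QC and greedy identity/coverage clustering.

The stages mirror a CD-HIT-style workflow: a 301 bp size filter, removal
of contaminant clusters (significant non-primate BLAST-like hit, no
significant primate hit, E < 1e-40), greedy longest-first clustering with
join rule identity >= c (0.95) and per-sequence coverage >= aS/aL (0.90)
against the cluster representative, and allele-frequency estimation from
the distinct individuals contributing members to each cluster.

Pairwise identity/coverage is computed from a minimum-edit-distance
alignment (edlib, infix mode with the shorter sequence as query, both
strands) from which the maximum-scoring local segment under match +1 /
mismatch -1 / gap -2 is extracted.  Two exact bounds let the greedy pass
skip or cap hopeless comparisons without ever changing the partition
relative to a brute-force application of the join rule:

* length window — a joinable pair needs aL * len_long <= columns <=
  len_short / c, hence len_long <= len_short / (c * aL);
* distance cap — a pair passing the join rule admits an infix alignment
  of the shorter sequence with edit distance at most
  (1-c)/c * len_short + (1-aS) * len_short (segment errors plus the
  unaligned query tails), so the edit-distance search can stop there.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .formats_io import Contig
from .synthetic_cohort import revcomp

__all__ = [
    "BlastLikeHit",
    "SequenceCluster",
    "filter_by_size",
    "classify_contaminants",
    "pairwise_identity_coverage",
    "satisfies_join",
    "greedy_cluster",
    "allele_frequencies",
]


@dataclass(frozen=True)
class BlastLikeHit:
    query_id: str
    taxon_group: str  # primate | non_primate
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.taxon_group not in ("primate", "non_primate"):
            raise ValueError(f"bad taxon_group {self.taxon_group!r}")


@dataclass
class SequenceCluster:
    """A set of contigs deemed the same allele."""

    cluster_id: str
    representative: Contig
    members: list[Contig] = field(default_factory=list)
    allele_frequency: float | None = None

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(m.individual_id for m in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# size and contaminant filters
# ---------------------------------------------------------------------------


def filter_by_size(
    contigs: list[Contig], min_len: int = 301
) -> tuple[list[Contig], list[Contig]]:
    """Partition contigs into (kept, removed) by ``length >= min_len``."""
    kept = [c for c in contigs if c.length >= min_len]
    removed = [c for c in contigs if c.length < min_len]
    return kept, removed


def filter_clusters_by_size(
    clusters: list[SequenceCluster], min_len: int = 301
) -> tuple[list[SequenceCluster], list[SequenceCluster]]:
    """Size filter applied at cluster level: a cluster is kept iff its
    representative is at least ``min_len`` long."""
    kept = [cl for cl in clusters if cl.representative.length >= min_len]
    removed = [cl for cl in clusters if cl.representative.length < min_len]
    return kept, removed


def classify_contaminants(
    clusters: list[SequenceCluster],
    hits: list[BlastLikeHit],
    e_threshold: float = 1e-40,
) -> tuple[list[SequenceCluster], list[SequenceCluster]]:
    """Split clusters into (clean, contaminant).

    A cluster is contaminant iff its representative has a significant
    (E < threshold) non-primate hit and no significant primate hit.
    Clusters without hits are clean.
    """
    sig_primate: set[str] = set()
    sig_nonprimate: set[str] = set()
    for h in hits:
        if h.e_value < e_threshold:
            (sig_primate if h.taxon_group == "primate" else sig_nonprimate).add(
                h.query_id
            )
    clean, contaminant = [], []
    for cl in clusters:
        rep = cl.representative.name
        if rep in sig_nonprimate and rep not in sig_primate:
            contaminant.append(cl)
        else:
            clean.append(cl)
    return clean, contaminant


# ---------------------------------------------------------------------------
# pairwise identity / coverage
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_MATCH, _MISMATCH, _GAP = 1.0, -1.0, -2.0


def _best_local_segment(cigar: str) -> tuple[float, int, int, int, int]:
    """Maximum-scoring contiguous run segment of an extended-CIGAR path
    under +1/-1/-2 scoring.

    Returns (score, matches, columns, query_span, target_span) of the best
    segment; segment boundaries lie at run boundaries because trimming
    part of a positive run or including part of a negative one never
    helps.
    """
    runs = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    best = (0.0, 0, 0, 0, 0)
    cur_score = 0.0
    cur = [0, 0, 0, 0]  # matches, columns, qspan, tspan
    for n, op in runs:
        if op == "=":
            score = _MATCH * n
            dm, dq, dt = n, n, n
        elif op in ("X", "M"):
            score = _MISMATCH * n
            dm, dq, dt = 0, n, n
        elif op == "I":  # consumes query only
            score = _GAP * n
            dm, dq, dt = 0, n, 0
        else:  # 'D': consumes target only
            score = _GAP * n
            dm, dq, dt = 0, 0, n
        if cur_score + score < score:
            cur_score = score
            cur = [dm, n, dq, dt]
        else:
            cur_score += score
            cur = [cur[0] + dm, cur[1] + n, cur[2] + dq, cur[3] + dt]
        if cur_score > best[0]:
            best = (cur_score, *cur)
    return best


def _segment_stats(
    query: str, target: str, max_distance: int = -1
) -> tuple[float, float, int, int, int]:
    res = edlib.align(query, target, mode="HW", task="path", k=max_distance)
    if res["editDistance"] < 0:  # distance cap exceeded
        return -math.inf, 0, 1, 0, 0
    score, matches, columns, qspan, tspan = _best_local_segment(res["cigar"] or "")
    return score, matches, columns, qspan, tspan


def pairwise_identity_coverage(
    a: Contig | str, b: Contig | str, max_distance: int | None = None
) -> tuple[float, float, float]:
    """(identity_fraction, cov_short, cov_long) of the best local alignment
    between ``a`` and ``b``, considering both strands of ``b``.

    identity = matches / alignment columns; cov_short and cov_long are the
    aligned span over the shorter (resp. longer) sequence length.  With
    ``max_distance`` set, pairs whose infix edit distance exceeds it on
    both strands report (0, 0, 0).
    """
    sa = a.sequence if isinstance(a, Contig) else a
    sb = b.sequence if isinstance(b, Contig) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    if short == long_:
        return 1.0, 1.0, 1.0
    cap = -1 if max_distance is None else max_distance
    best = (-math.inf, 0, 1, 0, 0)
    for target in (long_, revcomp(long_)):
        stats = _segment_stats(short, target, cap)
        if stats[0] > best[0]:
            best = stats
        if short == target:
            break
    _score, matches, columns, qspan, tspan = best
    if _score == -math.inf or columns == 0:
        return 0.0, 0.0, 0.0
    return matches / columns, qspan / len(short), tspan / len(long_)


def _join_distance_cap(len_short: int, c: float, aS: float) -> int:
    # segment errors <= (1-c)/c * len_short; unaligned query tails
    # <= (1-aS) * len_short, each costing at most one edit to complete
    return int(math.ceil(len_short * ((1.0 - c) / c + (1.0 - aS)))) + 2


def satisfies_join(
    a: Contig | str,
    b: Contig | str,
    c: float = 0.95,
    aS: float = 0.90,
    aL: float = 0.90,
) -> bool:
    """The CD-HIT-style join rule: identity >= c, coverage of the shorter
    sequence >= aS and of the longer >= aL.

    The edit-distance search is capped at the largest distance any pair
    passing the rule can attain, which cannot change the decision.
    """
    sa = a.sequence if isinstance(a, Contig) else a
    sb = b.sequence if isinstance(b, Contig) else b
    short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    if short == long_:
        return True
    cap = _join_distance_cap(len(short), c, aS)
    # evaluate strands one at a time: a passing forward segment decides
    for target in (long_, revcomp(long_)):
        score, matches, columns, qspan, tspan = _segment_stats(short, target, cap)
        if score == -math.inf or columns == 0:
            continue
        if (
            matches / columns >= c
            and qspan / len(short) >= aS
            and tspan / len(long_) >= aL
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------


def greedy_cluster(
    contigs: list[Contig],
    c: float = 0.95,
    aS: float = 0.90,
    aL: float = 0.90,
) -> list[SequenceCluster]:
    """CD-HIT-style greedy clustering.

    Contigs are sorted by decreasing length (ties: name); each joins the
    FIRST existing cluster whose representative satisfies the join rule,
    else founds a new cluster.  Output is in founding order, so the
    partition is independent of input file order.

    Representatives outside the length window len_rep <= len_contig /
    (c * aL) are skipped: the longer sequence's coverage cannot reach aL,
    so the shortcut is decision-preserving.
    """
    ordered = sorted(contigs, key=lambda x: (-x.length, x.name))
    clusters: list[SequenceCluster] = []
    max_ratio = 1.0 / (c * aL) if c * aL > 0 else math.inf

    for contig in ordered:
        joined = None
        for ci, cl in enumerate(clusters):
            rep = cl.representative
            if rep.length > contig.length * max_ratio:
                continue
            if satisfies_join(contig, rep, c, aS, aL):
                joined = ci
                break
        if joined is None:
            clusters.append(
                SequenceCluster(
                    cluster_id=f"cluster{len(clusters):06d}",
                    representative=contig,
                    members=[contig],
                )
            )
        else:
            clusters[joined].members.append(contig)
    return clusters


# ---------------------------------------------------------------------------
# cluster output
# ---------------------------------------------------------------------------


def write_clusters(
    clusters: list[SequenceCluster], tsv_path, clstr_path=None
) -> None:
    """Write the cluster table (TSV) and optionally a .clstr-style text
    listing of members per cluster."""
    with open(tsv_path, "w") as fh:
        fh.write("cluster_id\trepresentative\trep_length\tn_members\tn_individuals\tallele_frequency\n")
        for cl in clusters:
            af = "" if cl.allele_frequency is None else f"{cl.allele_frequency:.6f}"
            fh.write(
                f"{cl.cluster_id}\t{cl.representative.name}\t{cl.representative.length}\t"
                f"{cl.n_members}\t{len(cl.individuals)}\t{af}\n"
            )
    if clstr_path is not None:
        with open(clstr_path, "w") as fh:
            for i, cl in enumerate(clusters):
                fh.write(f">Cluster {i}\n")
                for j, m in enumerate(
                    sorted(cl.members, key=lambda m: (-m.length, m.name))
                ):
                    mark = "*" if m.name == cl.representative.name else ""
                    fh.write(f"{j}\t{m.length}nt, >{m.name}... {mark}\n")


def read_blast_hits_tsv(path) -> list[BlastLikeHit]:
    """(contig, taxon_group, e_value) TSV with a header line."""
    hits = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            name, group, e = line.rstrip("\n").split("\t")
            hits.append(BlastLikeHit(name, group, float(e)))
    return hits


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    clusters: list[SequenceCluster],
    n_individuals: int,
    rare_threshold: float = 0.05,
) -> dict:
    """Set each cluster's allele frequency (distinct member individuals /
    N) and return a spectrum summary.

    Returns a dict with ``n_clusters``, ``fraction_rare`` (AF < 5%) and a
    20-bin histogram of AFs over (0, 1].
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    edges = np.linspace(0.0, 1.0, 21)
    hist = np.zeros(20, dtype=int)
    n_rare = 0
    for cl in clusters:
        k = len(cl.individuals)
        if k > n_individuals:
            raise ValueError(
                f"{cl.cluster_id}: {k} member individuals exceeds cohort size "
                f"{n_individuals}"
            )
        af = k / n_individuals
        cl.allele_frequency = af
        if af < rare_threshold:
            n_rare += 1
        hist[min(int(af * 20), 19) if af < 1.0 else 19] += 1
    return {
        "n_clusters": len(clusters),
        "fraction_rare": n_rare / len(clusters) if clusters else float("nan"),
        "histogram_edges": edges,
        "histogram_counts": hist,
    }
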