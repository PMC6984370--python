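"""Classification of cluster representatives against reference genomes.

A minimal seed-and-extend aligner (exact 31-mer anchors, chained per
target/strand/diagonal band, ungapped extension) stands in for a
whole-genome aligner: it reports per-hit percent identity and percent
query coverage, which is all the downstream thresholds consume.

Thresholds follow the printed rules strictly: a hit is *confident* iff
identity > 95 and query coverage > 90; a cluster is NS iff NO hit to the
designated human reference has identity > 80 and coverage > 50 (boundary
values fail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import AlignmentHit, Contig
from .synthetic_cohort import revcomp

__all__ = [
    "ClassificationThresholds",
    "ClusterClassification",
    "ReferenceIndex",
    "align_to_reference",
    "classify_cluster",
    "classify_clusters",
    "catalog_membership",
    "bin_positions",
    "subset_by_af",
]


@dataclass(frozen=True)
class ClassificationThresholds:
    confident_identity: float = 95.0
    confident_coverage: float = 90.0
    ns_identity: float = 80.0
    ns_coverage: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.ns_identity <= self.confident_identity <= 100):
            raise ValueError("need 0 < ns_identity <= confident_identity <= 100")
        if not (0 < self.ns_coverage <= self.confident_coverage <= 100):
            raise ValueError("need 0 < ns_coverage <= confident_coverage <= 100")


@dataclass
class ClusterClassification:
    cluster_id: str
    best_hits: dict[str, tuple[float, float]] = field(default_factory=dict)
    confident_refs: set[str] = field(default_factory=set)
    is_ns: bool = False


# ---------------------------------------------------------------------------
# k-mer anchor aligner
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-mer start position of ``seq``."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col >= 0
        out = (out << 2) | np.where(col >= 0, col, 0)
    return out, valid


class ReferenceIndex:
    """Sorted exact k-mer index over a set of named target sequences."""

    def __init__(self, targets: dict[str, str], k: int = 31):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        self.targets = targets
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in targets.items():
            codes, valid = _kmer_codes(seq, k)
            pos = np.nonzero(valid)[0]
            vals = codes[pos]
            order = np.argsort(vals, kind="stable")
            self._index[name] = (vals[order], pos[order])

    def lookup(self, query_codes: np.ndarray, target: str, max_occ: int = 100):
        """(query_pos, target_pos) anchor pairs; k-mers occurring more than
        ``max_occ`` times in the target are skipped."""
        vals, pos = self._index[target]
        lo = np.searchsorted(vals, query_codes, side="left")
        hi = np.searchsorted(vals, query_codes, side="right")
        counts = hi - lo
        qpos_list, tpos_list = [], []
        for qp in np.nonzero((counts > 0) & (counts <= max_occ))[0]:
            tp = pos[lo[qp] : hi[qp]]
            qpos_list.append(np.full(len(tp), qp, dtype=np.int64))
            tpos_list.append(tp)
        if not qpos_list:
            return (np.empty(0, dtype=np.int64),) * 2
        return np.concatenate(qpos_list), np.concatenate(tpos_list)


def _band_hits(
    query: str,
    target_name: str,
    target_seq: str,
    qpos: np.ndarray,
    tpos: np.ndarray,
    strand: str,
    k: int,
    band: int,
    qlen_orig: int,
) -> list[AlignmentHit]:
    """Chain anchors per diagonal band and report one hit per band."""
    hits = []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    diag, qpos, tpos = diag[order], qpos[order], tpos[order]
    tlen = len(target_seq)
    # split where the diagonal jumps by more than the band width
    breaks = np.nonzero(np.diff(diag) > band)[0] + 1
    for seg in np.split(np.arange(len(diag)), breaks):
        # tandem repeats anchor one band on many shifted diagonals; score
        # the best-supported diagonals separately and keep the band's best
        dvals, dcounts = np.unique(diag[seg], return_counts=True)
        candidates = dvals[np.argsort(-dcounts, kind="stable")][:5]
        best = None
        for d0 in candidates:
            d0 = int(d0)
            on_diag = seg[diag[seg] == d0]
            qs_arr = qpos[on_diag]
            qs, qe = int(qs_arr.min()), int(qs_arr.max()) + k
            # ungapped extension along the diagonal
            while qs > 0 and qs + d0 > 0 and query[qs - 1] == target_seq[qs - 1 + d0]:
                qs -= 1
            while qe < len(query) and qe + d0 < tlen and query[qe] == target_seq[qe + d0]:
                qe += 1
            ts, te = max(0, qs + d0), min(tlen, qe + d0)
            span = qe - qs
            if span <= 0 or te <= ts:
                continue
            qseg = query[qs:qe]
            tseg = target_seq[qs + d0 : qe + d0] if qs + d0 >= 0 else ""
            m = sum(1 for x, y in zip(qseg, tseg) if x == y)
            identity = 100.0 * m / span
            # query coverage: the extended chain span over the query length
            cov = 100.0 * span / qlen_orig
            cand = (cov, identity, d0, qs, qe, ts, te)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            continue
        cov, identity, d0, qs, qe, ts, te = best
        q_start, q_end = qs, qe
        if strand == "-":
            q_start, q_end = qlen_orig - qe, qlen_orig - qs
        hits.append(
            AlignmentHit(
                query_id="query",
                target_id=target_name,
                query_start=q_start,
                query_end=q_end,
                target_start=ts,
                target_end=te,
                strand=strand,
                identity_pct=min(identity, 100.0),
                query_cov_pct=min(cov, 100.0),
            )
        )
    return hits


def align_to_reference(
    query: Contig | str,
    reference: ReferenceIndex | dict[str, str],
    k: int = 31,
    band: int = 50,
) -> list[AlignmentHit]:
    """Anchor, chain and extend the query against every target on both
    strands; hits are sorted by descending query coverage.

    A query shorter than k yields an empty result.
    """
    seq = query.sequence if isinstance(query, Contig) else query
    name = query.name if isinstance(query, Contig) else "query"
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, k)
    if len(seq) < index.k:
        import warnings

        warnings.warn(f"query {name} shorter than k={index.k}; no hits")
        return []
    hits: list[AlignmentHit] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        codes, valid = _kmer_codes(s, index.k)
        codes = np.where(valid, codes, -1)
        for tname, tseq in index.targets.items():
            qpos, tpos = index.lookup(codes, tname)
            if len(qpos) == 0:
                continue
            ok = valid[qpos]
            qpos, tpos = qpos[ok], tpos[ok]
            if len(qpos) == 0:
                continue
            hits.extend(
                _band_hits(s, tname, tseq, qpos, tpos, strand, index.k, band, len(seq))
            )
    for h in hits:
        h.query_id = name
    hits.sort(key=lambda h: (-h.query_cov_pct, -h.identity_pct, h.target_id, h.target_start))
    return hits


# ---------------------------------------------------------------------------
# threshold classification
# ---------------------------------------------------------------------------


def _best_hit(hits: list[AlignmentHit]) -> AlignmentHit | None:
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.query_cov_pct, -h.identity_pct, h.target_start))


def classify_cluster(
    hits_by_ref: dict[str, list[AlignmentHit]],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    human_ref: str = "human",
    cluster_id: str = "",
) -> ClusterClassification:
    """Apply the confident-alignment and NS rules to per-reference hits.

    A reference is confidently matched iff SOME hit has identity > 95 and
    coverage > 90 (strict).  The cluster is NS iff no hit to the human
    reference has identity > 80 AND coverage > 50: a hit failing either
    criterion is not a significant match and does not block NS status.
    """
    cc = ClusterClassification(cluster_id=cluster_id)
    for ref, hits in hits_by_ref.items():
        best = _best_hit(hits)
        if best is not None:
            cc.best_hits[ref] = (best.identity_pct, best.query_cov_pct)
        if any(
            h.identity_pct > thresholds.confident_identity
            and h.query_cov_pct > thresholds.confident_coverage
            for h in hits
        ):
            cc.confident_refs.add(ref)
    human_hits = hits_by_ref.get(human_ref, [])
    cc.is_ns = not any(
        h.identity_pct > thresholds.ns_identity
        and h.query_cov_pct > thresholds.ns_coverage
        for h in human_hits
    )
    return cc


def classify_clusters(
    clusters,
    references: dict[str, dict[str, str]],
    human_ref: str = "human",
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    k: int = 31,
) -> dict[str, ClusterClassification]:
    """Align every cluster representative to every reference and classify.

    ``references`` maps reference name -> {target name: sequence}.
    """
    indexes = {name: ReferenceIndex(targets, k) for name, targets in references.items()}
    out: dict[str, ClusterClassification] = {}
    for cl in clusters:
        hits_by_ref = {
            name: align_to_reference(cl.representative, idx)
            for name, idx in indexes.items()
        }
        cc = classify_cluster(hits_by_ref, thresholds, human_ref, cl.cluster_id)
        out[cl.cluster_id] = cc
    return out


def catalog_membership(
    classifications: dict[str, ClusterClassification],
    references: list[str],
) -> dict:
    """Per-cluster confident-reference subsets and aggregate set sizes."""
    subsets: dict[str, frozenset[str]] = {}
    counts: dict[frozenset[str], int] = {}
    n_any = 0
    for cid, cc in classifications.items():
        sub = frozenset(r for r in references if r in cc.confident_refs)
        subsets[cid] = sub
        counts[sub] = counts.get(sub, 0) + 1
        if sub:
            n_any += 1
    return {"subsets": subsets, "subset_counts": counts, "n_confident_any": n_any}


def bin_positions(
    best_hits: dict[str, AlignmentHit],
    chrom_lengths: dict[str, int],
    bin_size: int = 3_000_000,
) -> dict:
    """Assign each uniquely-placed cluster to the bin of its best hit's
    target midpoint; densities are percentages of placed clusters."""
    n_bins = {
        chrom: max(1, -(-length // bin_size)) for chrom, length in chrom_lengths.items()
    }
    counts: dict[tuple[str, int], int] = {
        (c, i): 0 for c, nb in n_bins.items() for i in range(nb)
    }
    for hit in best_hits.values():
        mid = (hit.target_start + hit.target_end) // 2
        counts[(hit.target_id, min(mid // bin_size, n_bins[hit.target_id] - 1))] += 1
    total = sum(counts.values())
    density = {
        key: (100.0 * v / total if total else 0.0) for key, v in counts.items()
    }
    zero_fraction = (
        sum(1 for v in counts.values() if v == 0) / len(counts) if counts else 1.0
    )
    return {
        "bin_counts": counts,
        "bin_density_pct": density,
        "zero_bin_fraction": zero_fraction,
        "n_placed": total,
    }


def subset_by_af(ns_clusters, min_af: float):
    """Clusters with allele frequency >= min_af (boundary inclusive);
    subsets are nested in the threshold."""
    return [cl for cl in ns_clusters if (cl.allele_frequency or 0.0) >= min_af]
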