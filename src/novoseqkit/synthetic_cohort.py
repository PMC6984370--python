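"""Synthetic cohort generator with full truth bookkeeping.

Emulates the situation the pipeline is built for: a population of N
individuals whose de-novo assemblies contain sequence absent from the
human reference ("novel sequence", NS).  The generator plants

* a human-like reference (random backbone with planted repeat copies),
* a chimp-like reference equal to the human one plus "ancestral" NS
  inserted at recorded positions (so each ancestral NS is a deletion in
  the human lineage relative to chimp),
* an NS catalog with a skewed allele-frequency spectrum (most NS rare,
  carrier frequency < 5%), per-NS repeat-class composition, and
  carrier sets,
* per-individual contig sets: carried NS copies (with assembly-error
  substitutions and occasional fragmentation), decoy contigs that match
  the human reference, sub-threshold small contigs, and long contaminant
  contigs with non-primate BLAST-like hits,
* per-individual insertion breakpoint calls, deletion VCFs against the
  chimp-like reference, and SAM-text unmapped-read alignments.

Every random choice flows from one seed through named substreams, so any
emission can be regenerated independently and a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    Contig,
    DeletionRecord,
    GenomicInterval,
    RepeatAnnotation,
    SamFlagRecord,
    write_bed,
    write_deletion_vcf,
    write_fasta,
    write_plain_fasta,
    write_repeat_annotation_tsv,
    write_sam_flag_stream,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# named substreams: one global seed, one child stream per emission
_STREAMS = {
    "references": 0,
    "catalog": 1,
    "individuals": 2,
    "calls": 3,
    "deletions": 4,
    "reads": 5,
    "hits": 6,
}


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply substitutions at the given per-base rate (new base != old)."""
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    buf = bytearray(seq, "ascii")
    shifts = rng.integers(1, 4, size=k)
    lut = {65: "ACGT", 67: "CGTA", 71: "GTAC", 84: "TACG"}  # cyclic shift
    for p, s in zip(pos, shifts):
        buf[p] = ord("ACGT"[("ACGT".index(chr(buf[p])) + s) % 4])
    return buf.decode()


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions: N=100 individuals, 300 NS sized
    301-22,701 bp with 90% rare (carrier frequency < 5%), repeat mix
    dominated by simple repeats / satellites / unmasked sequence,
    contaminants sized 22.7-60 kb, assembly-error substitution rate 0.005
    and fragmentation probability 0.1.
    """

    seed: int = 0
    n_individuals: int = 100
    ref_length: int = 2_000_000
    n_chromosomes: int = 2
    n_ns: int = 300
    rare_fraction: float = 0.90
    rare_af_max: float = 0.05
    common_af_range: tuple[float, float] = (0.05, 0.5)
    ns_length_range: tuple[int, int] = (301, 22_701)
    repeat_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Simple_repeat": 0.28,
            "Satellite": 0.15,
            "LINE": 0.10,
            "SINE": 0.03,
            "Unmasked": 0.44,
        }
    )
    min_unmasked: float = 0.15
    repeat_divergence: float = 0.08  # per-instance divergence of planted repeats
    # NS repeat blocks are private: strongly diverged from the library
    # consensus (novel satellite/LINE arrays do not resemble reference
    # copies at alignment-significant identity)
    ns_repeat_divergence: float = 0.20
    n_contaminants: int = 8
    contaminant_len_range: tuple[int, int] = (22_701, 60_000)
    contaminant_af_range: tuple[float, float] = (0.01, 0.04)
    fragmentation_prob: float = 0.1
    mutation_rate: float = 0.005
    revcomp_prob: float = 0.2
    n_decoys_per_individual: int = 6
    decoy_len_range: tuple[int, int] = (400, 3_000)
    n_small_per_individual: int = 8
    small_len_range: tuple[int, int] = (73, 300)
    ancestral_fraction: float = 0.10
    positioned_fraction: float = 0.30
    # insertion breakpoint calls
    breakpoint_jitter_sd: float = 30.0
    false_call_rate: float = 2.0  # Poisson mean of false calls per individual
    hybrid_fraction: float = 0.02
    # deletion VCFs vs the chimp-like reference
    deletion_pad_max: int = 2_000
    lowqual_fraction: float = 0.05
    background_dup_rate: float = 1.0
    background_del_rate: float = 0.5
    liftover_fail_fraction: float = 0.05
    # unmapped reads
    n_ur_per_individual: int = 2_000
    ur_mapped_fraction: float = 0.074
    read_length: int = 150
    dup_read_fraction: float = 0.10
    populations: tuple[str, ...] = ("ACB", "CEU", "FIN", "YRI")
    # probability a mapped read is drawn from a common (AF >= 5%) carried NS
    pop_common_bias: dict[str, float] = field(
        default_factory=lambda: {"ACB": 0.30, "CEU": 0.50, "FIN": 0.45, "YRI": 0.32}
    )

    def __post_init__(self) -> None:
        total = sum(self.repeat_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"repeat_mix proportions sum to {total}, not 1")
        if self.ns_length_range[0] <= 0 or self.ns_length_range[0] > self.ns_length_range[1]:
            raise ValueError("invalid ns_length_range")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")

    @property
    def individual_ids(self) -> list[str]:
        width = max(4, len(str(self.n_individuals - 1)))
        return [f"Ind{str(i).zfill(width)}" for i in range(self.n_individuals)]


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------


@dataclass
class NsTruth:
    ns_id: str
    sequence: str
    true_af: float
    carriers: frozenset[str]
    annotation: RepeatAnnotation
    site: tuple[str, int] | None  # insertion position on the human reference
    is_ancestral: bool
    novel_vs_human: bool  # False for the liftover "lifts_over" fraction

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ContaminantTruth:
    contaminant_id: str
    sequence: str
    carriers: frozenset[str]


@dataclass
class CohortTruth:
    """Planted ground truth for parameter-recovery tests."""

    config: SimConfig
    human_ref: dict[str, str]
    chimp_ref: dict[str, str]
    human_repeat_track: list[GenomicInterval]
    ns: dict[str, NsTruth]
    contaminants: dict[str, ContaminantTruth]
    deleted_regions: list[GenomicInterval]  # chimp coords, label = ns_id
    gene_track: list[GenomicInterval] = field(default_factory=list)
    populations: dict[str, str] = field(default_factory=dict)
    # ns_id -> individual -> ancestral allele copies (0/1/2); ancestral NS only
    ancestral_copies: dict[str, dict[str, int]] = field(default_factory=dict)
    # contig name -> ("ns", ns_id) | ("decoy",) | ("small",) | ("contaminant", cid)
    contig_sources: dict[str, tuple] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return self.config.individual_ids


def carrier_count(af: float, n: int) -> int:
    return min(n, max(1, round(af * n)))


# ---------------------------------------------------------------------------
# references and catalog
# ---------------------------------------------------------------------------


def _repeat_library(rng: np.random.Generator) -> dict[str, str]:
    """Consensus monomers per repeat class; instances are mutated copies."""
    return {
        "LINE": random_dna(rng, 6000),
        "SINE": random_dna(rng, 300),
        "LTR": random_dna(rng, 1000),
        "DNA": random_dna(rng, 800),
        "Satellite": random_dna(rng, 171),
    }


def _simple_motif(rng: np.random.Generator, min_len: int = 2) -> str:
    return random_dna(rng, int(rng.integers(min_len, 7)))


def _class_block(
    cls: str,
    length: int,
    library: dict[str, str],
    rng: np.random.Generator,
    divergence: float,
    motif_min_len: int = 2,
) -> str:
    """A class-pure sequence block of the requested length."""
    if length <= 0:
        return ""
    if cls == "Unmasked":
        return random_dna(rng, length)
    if cls in ("Simple_repeat", "Low_complexity"):
        motif = _simple_motif(rng, motif_min_len)
        reps = math.ceil(length / len(motif))
        return mutate((motif * reps)[:length], divergence / 4, rng)
    monomer = library.get(cls) or random_dna(rng, 200)
    reps = math.ceil(length / len(monomer))
    return mutate((monomer * reps)[:length], divergence, rng)


def _build_ns_sequence(
    length: int,
    mix: dict[str, float],
    min_unmasked: float,
    library: dict[str, str],
    rng: np.random.Generator,
    divergence: float,
) -> tuple[str, RepeatAnnotation]:
    """Concatenate class-pure blocks realising a per-NS repeat composition.

    The per-NS proportions are a Dirichlet draw around the global mix with
    the unmasked fraction floored, so every NS retains unique sequence and
    distinct NS never satisfy the clustering join rule by shared repeats
    alone.  Repeat blocks are strongly diverged from the library consensus
    (novel arrays, not reference copies) and simple-repeat motifs are
    drawn at length >= 4 so NS tandem arrays rarely share a motif with
    planted reference arrays.
    """
    classes = list(mix)
    alpha = np.array([max(mix[c], 1e-3) for c in classes]) * 12.0
    props = rng.dirichlet(alpha)
    props = dict(zip(classes, props))
    unmasked = max(props.get("Unmasked", 0.0), min_unmasked)
    other_total = sum(v for c, v in props.items() if c != "Unmasked")
    scale = (1.0 - unmasked) / other_total if other_total > 0 else 0.0
    props = {c: (unmasked if c == "Unmasked" else v * scale) for c, v in props.items()}

    # split each class share into 1-2 blocks and shuffle the block order
    blocks: list[tuple[str, int]] = []
    remaining = length
    items = [(c, int(round(p * length))) for c, p in props.items()]
    items[-1] = (items[-1][0], length - sum(n for _, n in items[:-1]))
    for cls, n in items:
        n = max(0, min(n, remaining)) if cls != items[-1][0] else remaining
        if n <= 0:
            continue
        if n >= 80 and rng.random() < 0.5:
            cut = int(rng.integers(20, n - 19))
            blocks += [(cls, cut), (cls, n - cut)]
        else:
            blocks.append((cls, n))
        remaining -= n
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    parts: list[str] = []
    intervals: list[tuple[int, int, str]] = []
    pos = 0
    for cls, n in blocks:
        parts.append(_class_block(cls, n, library, rng, divergence, motif_min_len=4))
        if cls != "Unmasked":
            intervals.append((pos, pos + n, cls))
        pos += n
    seq = "".join(parts)
    return seq, RepeatAnnotation("", len(seq), sorted(intervals))


def _plant_reference_repeats(
    chrom_seqs: dict[str, str],
    library: dict[str, str],
    rng: np.random.Generator,
    divergence: float,
    target_fraction: float = 0.45,
) -> list[GenomicInterval]:
    """Overwrite stretches of the backbone with repeat copies; returns the
    resulting repeat track (non-overlapping, class-labelled)."""
    track: list[GenomicInterval] = []
    weights = {"LINE": 0.35, "SINE": 0.15, "LTR": 0.12, "DNA": 0.08,
               "Satellite": 0.15, "Simple_repeat": 0.15}
    classes = list(weights)
    probs = np.array(list(weights.values()))
    probs /= probs.sum()
    for chrom in chrom_seqs:
        buf = bytearray(chrom_seqs[chrom], "ascii")
        n = len(buf)
        occupied = np.zeros(n, dtype=bool)
        planted = 0
        attempts = 0
        while planted < target_fraction * n and attempts < 10_000:
            attempts += 1
            cls = classes[rng.choice(len(classes), p=probs)]
            block = _class_block(
                cls, int(rng.integers(150, 4000)), library, rng, divergence
            )
            start = int(rng.integers(0, n - len(block)))
            if occupied[start : start + len(block)].any():
                continue
            buf[start : start + len(block)] = block.encode()
            occupied[start : start + len(block)] = True
            track.append(GenomicInterval(chrom, start, start + len(block), cls))
            planted += len(block)
        chrom_seqs[chrom] = buf.decode()
    return sorted(track, key=lambda iv: (iv.chrom, iv.start))


def generate_truth(config: SimConfig) -> CohortTruth:
    """Build references and the planted NS/contaminant catalog."""
    rng_ref = substream(config.seed, "references")
    rng_cat = substream(config.seed, "catalog")
    n = config.n_individuals

    chrom_len = config.ref_length // config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    library = _repeat_library(rng_ref)
    human = {c: random_dna(rng_ref, chrom_len) for c in chrom_names}
    track = _plant_reference_repeats(human, library, rng_ref, config.repeat_divergence)

    # --- NS catalog -------------------------------------------------------
    lo, hi = config.ns_length_range
    ns: dict[str, NsTruth] = {}
    n_positioned = int(round(config.positioned_fraction * config.n_ns))
    n_ancestral = int(round(config.ancestral_fraction * config.n_ns))

    # non-overlapping insertion sites for positioned NS, well separated so
    # padded deletion intervals of different NS stay disjoint
    sep = max(5_000, 2 * config.deletion_pad_max + 10)
    sites: list[tuple[str, int]] = []
    attempts = 0
    while len(sites) < n_positioned:
        attempts += 1
        if attempts > 1000 * max(1, n_positioned):
            raise RuntimeError("could not place non-overlapping insertion sites")
        chrom = chrom_names[int(rng_cat.integers(0, len(chrom_names)))]
        pos = int(rng_cat.integers(1000, chrom_len - 1000))
        if all(c != chrom or abs(p - pos) >= sep for c, p in sites):
            sites.append((chrom, pos))

    # a configurable fraction of positioned NS share a site with a previous
    # one (hybrid insertion artifact)
    hybrid_of: dict[int, int] = {}
    for i in range(1, n_positioned):
        if rng_cat.random() < config.hybrid_fraction:
            hybrid_of[i] = int(rng_cat.integers(0, i))

    for i in range(config.n_ns):
        ns_id = f"NS{i:04d}"
        length = int(
            round(math.exp(rng_cat.uniform(math.log(lo), math.log(hi))))
        )
        length = min(max(length, lo), hi)
        seq, ann = _build_ns_sequence(
            length, config.repeat_mix, config.min_unmasked, library, rng_cat,
            config.ns_repeat_divergence,
        )
        ann.seq_id = ns_id
        if rng_cat.random() < config.rare_fraction:
            af = rng_cat.uniform(1.0 / n, config.rare_af_max)
        else:
            af = rng_cat.uniform(*config.common_af_range)
        k = carrier_count(af, n)
        carriers = frozenset(
            config.individual_ids[j]
            for j in rng_cat.choice(n, size=k, replace=False)
        )
        site = None
        if i < n_positioned:
            if i in hybrid_of:
                c, p = sites[hybrid_of[i]]
                site = (c, p + int(rng_cat.integers(-20, 21)))
            else:
                site = sites[i]
        is_ancestral = i < n_ancestral and i not in hybrid_of
        novel = True
        if is_ancestral and rng_cat.random() < config.liftover_fail_fraction:
            novel = False
        ns[ns_id] = NsTruth(
            ns_id=ns_id,
            sequence=seq,
            true_af=af,
            carriers=carriers,
            annotation=ann,
            site=site,
            is_ancestral=is_ancestral,
            novel_vs_human=novel,
        )

    # --- chimp-like reference: insert ancestral NS ------------------------
    chimp: dict[str, str] = {}
    deleted_regions: list[GenomicInterval] = []
    by_chrom: dict[str, list[NsTruth]] = {c: [] for c in chrom_names}
    for t in ns.values():
        if t.is_ancestral and t.site is not None:
            by_chrom[t.site[0]].append(t)
    for chrom in chrom_names:
        inserts = sorted(by_chrom[chrom], key=lambda t: t.site[1])
        pieces = []
        prev = 0
        offset = 0
        for t in inserts:
            pos = t.site[1]
            pieces.append(human[chrom][prev:pos])
            deleted_regions.append(
                GenomicInterval(chrom, pos + offset, pos + offset + t.length, t.ns_id)
            )
            pieces.append(t.sequence)
            offset += t.length
            prev = pos
        pieces.append(human[chrom][prev:])
        chimp[chrom] = "".join(pieces)

    # --- contaminant catalog ---------------------------------------------
    contaminants: dict[str, ContaminantTruth] = {}
    for i in range(config.n_contaminants):
        cid = f"CONTAM{i:03d}"
        length = int(rng_cat.integers(*config.contaminant_len_range))
        af = rng_cat.uniform(*config.contaminant_af_range)
        k = carrier_count(af, n)
        carriers = frozenset(
            config.individual_ids[j]
            for j in rng_cat.choice(n, size=k, replace=False)
        )
        contaminants[cid] = ContaminantTruth(cid, random_dna(rng_cat, length), carriers)

    # gene-like feature track (non-overlapping intervals, ~25% of the genome)
    gene_track: list[GenomicInterval] = []
    for chrom in chrom_names:
        pos = int(rng_ref.integers(0, 30_000))
        while pos < chrom_len - 40_000:
            glen = int(rng_ref.integers(5_000, 30_000))
            gene_track.append(GenomicInterval(chrom, pos, pos + glen, "gene"))
            pos += glen + int(rng_ref.integers(20_000, 80_000))

    populations = {
        ind: config.populations[i % len(config.populations)]
        for i, ind in enumerate(config.individual_ids)
    }
    return CohortTruth(
        config=config,
        human_ref=human,
        chimp_ref=chimp,
        human_repeat_track=track,
        ns=ns,
        contaminants=contaminants,
        deleted_regions=deleted_regions,
        gene_track=gene_track,
        populations=populations,
    )


def build_references(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], list[GenomicInterval]]:
    """(human_ref, chimp_ref, deleted_region_table).

    The chimp-like reference equals the human one with every ancestral NS
    inserted at its recorded position; the table lists each inserted
    segment's chimp coordinates (label = ns_id).
    """
    truth = generate_truth(config)
    return truth.human_ref, truth.chimp_ref, truth.deleted_regions


# ---------------------------------------------------------------------------
# per-individual contigs
# ---------------------------------------------------------------------------


def simulate_individuals(
    config: SimConfig, truth: CohortTruth
) -> dict[str, list[Contig]]:
    """Emit each individual's contig set and record contig sources in the
    truth table.

    Carried NS contigs get assembly-error substitutions at
    ``mutation_rate`` and are split into two >= 301 bp fragments with
    probability ``fragmentation_prob``; a fraction are reverse-
    complemented.  Decoys are slices of the human reference (mappable,
    hence removable), small contigs sit below the size filter, and
    contaminant contigs carry non-primate BLAST-like hits.
    """
    parent = substream(config.seed, "individuals")
    seeds = parent.spawn(config.n_individuals)
    min_len = 301
    out: dict[str, list[Contig]] = {}
    chrom_names = list(truth.human_ref)
    for ind, rng in zip(config.individual_ids, seeds):
        contigs: list[Contig] = []
        counter = 0

        def emit(seq: str, source: tuple) -> None:
            nonlocal counter
            counter += 1
            c = Contig(ind, str(counter), seq)
            contigs.append(c)
            truth.contig_sources[c.name] = source

        for t in truth.ns.values():
            if ind not in t.carriers:
                continue
            seq = mutate(t.sequence, config.mutation_rate, rng)
            frag = (
                len(seq) >= 2 * min_len
                and rng.random() < config.fragmentation_prob
            )
            pieces = []
            if frag:
                cut = int(rng.integers(min_len, len(seq) - min_len + 1))
                pieces = [seq[:cut], seq[cut:]]
            else:
                pieces = [seq]
            for piece in pieces:
                if rng.random() < config.revcomp_prob:
                    piece = revcomp(piece)
                emit(piece, ("ns", t.ns_id))
        for cid, ct in truth.contaminants.items():
            if ind in ct.carriers:
                emit(mutate(ct.sequence, config.mutation_rate, rng), ("contaminant", cid))
        for _ in range(config.n_decoys_per_individual):
            length = int(rng.integers(*config.decoy_len_range))
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(rng.integers(0, len(truth.human_ref[chrom]) - length))
            seq = truth.human_ref[chrom][start : start + length]
            seq = mutate(seq, config.mutation_rate, rng)
            emit(seq, ("decoy", chrom, start, start + length))
        for _ in range(config.n_small_per_individual):
            emit(random_dna(rng, int(rng.integers(*config.small_len_range))), ("small",))
        out[ind] = contigs
    return out


def emit_blast_hits(config: SimConfig, truth: CohortTruth) -> list[tuple[str, str, float]]:
    """BLAST-like hit table keyed by contig name:
    (contig_name, taxon_group, e_value).

    Contaminant contigs get strong non-primate hits (a minority also a
    weak primate hit); decoys get strong primate hits half the time; NS
    contigs occasionally a weak non-primate hit (non-significant).
    """
    rng = substream(config.seed, "hits")
    hits: list[tuple[str, str, float]] = []
    for name, source in truth.contig_sources.items():
        kind = source[0]
        if kind == "contaminant":
            hits.append((name, "non_primate", 10.0 ** -rng.uniform(45, 120)))
            if rng.random() < 0.2:
                hits.append((name, "primate", 10.0 ** -rng.uniform(5, 30)))
        elif kind == "decoy":
            if rng.random() < 0.5:
                hits.append((name, "primate", 10.0 ** -rng.uniform(60, 120)))
        elif kind == "ns":
            if rng.random() < 0.05:
                hits.append((name, "non_primate", 10.0 ** -rng.uniform(1, 30)))
    return hits


# ---------------------------------------------------------------------------
# insertion calls, deletion VCFs, unmapped reads
# ---------------------------------------------------------------------------


def emit_insertion_calls(truth: CohortTruth, config: SimConfig):
    """Per-individual insertion breakpoint calls for every positioned NS.

    Each carrier of a positioned NS produces a breakpoint at the true
    site plus rounded Normal(0, jitter_sd) noise, with a Poisson
    background of false calls per individual.
    """
    from .positioning_enrichment import InsertionCall

    rng = substream(config.seed, "calls")
    chrom_len = {c: len(s) for c, s in truth.human_ref.items()}
    positioned = [t for t in truth.ns.values() if t.site is not None]
    out: dict[str, list] = {ind: [] for ind in truth.individuals}
    for t in positioned:
        chrom, pos = t.site
        for ind in sorted(t.carriers):
            jit = int(round(rng.normal(0.0, config.breakpoint_jitter_sd)))
            p = min(max(pos + jit, 0), chrom_len[chrom] - 1)
            out[ind].append(
                InsertionCall(individual_id=ind, chrom=chrom, position=p,
                              ns_cluster_id=t.ns_id)
            )
    ns_ids = [t.ns_id for t in positioned]
    if ns_ids:
        for ind in truth.individuals:
            for _ in range(rng.poisson(config.false_call_rate)):
                t = truth.ns[ns_ids[int(rng.integers(0, len(ns_ids)))]]
                chrom = list(chrom_len)[int(rng.integers(0, len(chrom_len)))]
                out[ind].append(
                    InsertionCall(
                        individual_id=ind,
                        chrom=chrom,
                        position=int(rng.integers(0, chrom_len[chrom])),
                        ns_cluster_id=t.ns_id,
                    )
                )
    return out


def emit_deletion_vcfs(
    truth: CohortTruth, config: SimConfig
) -> dict[str, list[DeletionRecord]]:
    """Per-individual deletion records against the chimp-like reference.

    Diploid ancestral-allele copies are drawn consistently with the
    planted carrier set: non-carriers hold 0 copies (hom_alt deletion),
    carriers hold 2 copies with probability p/(2-p) where the per-allele
    frequency p solves 2p - p^2 = carrier frequency, else 1 copy (het
    deletion).  Deletion intervals are the chimp-coordinate region padded
    by Uniform(0, pad_max) per side.  A fraction of records are LowQual
    and a Poisson background of non-DEL and off-target records is added.
    """
    rng = substream(config.seed, "deletions")
    chimp_len = {c: len(s) for c, s in truth.chimp_ref.items()}
    out: dict[str, list[DeletionRecord]] = {ind: [] for ind in truth.individuals}
    regions = {iv.label: iv for iv in truth.deleted_regions}
    for ns_id, region in regions.items():
        t = truth.ns[ns_id]
        af = min(t.true_af, 1.0 - 1e-12)
        p_allele = 1.0 - math.sqrt(1.0 - af)
        p_two = p_allele / (2.0 - p_allele)
        copies_map: dict[str, int] = {}
        for ind in truth.individuals:
            if ind in t.carriers:
                copies = 2 if rng.random() < p_two else 1
            else:
                copies = 0
            copies_map[ind] = copies
            if copies == 2:
                continue
            pad_l = int(rng.integers(0, config.deletion_pad_max + 1))
            pad_r = int(rng.integers(0, config.deletion_pad_max + 1))
            start = max(0, region.start - pad_l)
            end = min(chimp_len[region.chrom], region.end + pad_r)
            status = (
                "LowQual" if rng.random() < config.lowqual_fraction else "PASS"
            )
            out[ind].append(
                DeletionRecord(
                    individual_id=ind,
                    chrom=region.chrom,
                    start=start,
                    end=end,
                    filter_status=status,
                    svtype="DEL",
                    genotype="hom_alt" if copies == 0 else "het",
                )
            )
        truth.ancestral_copies[ns_id] = copies_map
    # background noise: DUP records and off-target PASS DELs
    for ind in truth.individuals:
        for _ in range(rng.poisson(config.background_dup_rate)):
            chrom = list(chimp_len)[int(rng.integers(0, len(chimp_len)))]
            start = int(rng.integers(0, chimp_len[chrom] - 5000))
            out[ind].append(
                DeletionRecord(ind, chrom, start, start + int(rng.integers(200, 5000)),
                               "PASS", "other", "het")
            )
        for _ in range(rng.poisson(config.background_del_rate)):
            chrom = list(chimp_len)[int(rng.integers(0, len(chimp_len)))]
            start = int(rng.integers(0, chimp_len[chrom] - 3000))
            end = start + int(rng.integers(200, 3000))
            if any(
                iv.chrom == chrom and iv.start - 5000 < end and start < iv.end + 5000
                for iv in truth.deleted_regions
            ):
                continue
            out[ind].append(
                DeletionRecord(ind, chrom, start, end, "PASS", "DEL", "het")
            )
    return out


def emit_unmapped_reads(
    truth: CohortTruth, config: SimConfig
) -> dict[str, list[tuple[SamFlagRecord, str]]]:
    """Per-individual SAM records of unmapped-read alignments vs the NS
    catalog.

    Mapped reads (flag 0, target = the owning NS) are windows from the
    individual's carried NS; the rest are random reads with the unmapped
    flag.  A fraction of mapped reads is duplicated as secondary (0x100)
    and supplementary (0x800) records, which flag-filtered counting must
    ignore.  The probability that a mapped read comes from a common
    (AF >= 5%) carried NS depends on the individual's population,
    producing population-specific depletion curves.
    """
    rng = substream(config.seed, "reads")
    L = config.read_length
    out: dict[str, list[tuple[SamFlagRecord, str]]] = {}
    for ind in truth.individuals:
        pop = truth.populations[ind]
        bias = config.pop_common_bias.get(pop, 0.4)
        carried = [t for t in truth.ns.values() if ind in t.carriers and t.length > L]
        common = [t for t in carried if t.true_af >= 0.05]
        rare = [t for t in carried if t.true_af < 0.05]
        records: list[tuple[SamFlagRecord, str]] = []
        n_mapped = rng.binomial(config.n_ur_per_individual, config.ur_mapped_fraction)
        if not carried:
            n_mapped = 0
        for i in range(config.n_ur_per_individual):
            rid = f"{ind}_r{i}"
            if i < n_mapped:
                pool = common if (common and (not rare or rng.random() < bias)) else (rare or common)
                t = pool[int(rng.integers(0, len(pool)))]
                start = int(rng.integers(0, t.length - L + 1))
                seq = t.sequence[start : start + L]
                records.append((SamFlagRecord(rid, 0, t.ns_id), seq))
                if rng.random() < config.dup_read_fraction:
                    records.append((SamFlagRecord(rid, 0x100, t.ns_id), seq))
                    records.append((SamFlagRecord(rid, 0x800, t.ns_id), seq))
            else:
                records.append((SamFlagRecord(rid, 4, None), random_dna(rng, L)))
        out[ind] = records
    return out


# ---------------------------------------------------------------------------
# whole-cohort convenience + on-disk emission
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    truth: CohortTruth
    contigs: dict[str, list[Contig]]
    blast_hits: list[tuple[str, str, float]]
    insertion_calls: dict[str, list]
    deletion_records: dict[str, list[DeletionRecord]]
    ur_records: dict[str, list[tuple[SamFlagRecord, str]]]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the complete cohort in memory."""
    truth = generate_truth(config)
    contigs = simulate_individuals(config, truth)
    hits = emit_blast_hits(config, truth)
    calls = emit_insertion_calls(truth, config)
    dels = emit_deletion_vcfs(truth, config)
    reads = emit_unmapped_reads(truth, config)
    return Cohort(truth, contigs, hits, calls, dels, reads)


def write_cohort(cohort: Cohort, outdir: str | os.PathLike) -> None:
    """Write every emission as plain text (FASTA/BED/VCF/SAM/TSV)."""
    out = Path(outdir)
    truth = cohort.truth
    config = truth.config
    for sub in ("contigs", "calls", "vcfs", "urs"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    write_plain_fasta(truth.human_ref.items(), out / "human_ref.fa")
    write_plain_fasta(truth.chimp_ref.items(), out / "chimp_ref.fa")
    write_plain_fasta(
        ((t.ns_id, t.sequence) for t in truth.ns.values()), out / "ns_catalog.fa"
    )
    write_bed(truth.deleted_regions, out / "deleted_regions.bed")
    write_bed(truth.human_repeat_track, out / "human_repeats.bed")
    write_bed(truth.gene_track, out / "genes.bed")
    write_repeat_annotation_tsv(
        (t.annotation for t in truth.ns.values()), out / "ns_annotations.tsv"
    )

    ns_lengths = {t.ns_id: t.length for t in truth.ns.values()}
    chimp_lengths = {c: len(s) for c, s in truth.chimp_ref.items()}
    for ind in truth.individuals:
        write_fasta(cohort.contigs[ind], out / "contigs" / f"{ind}.fa")
        write_bed(
            (GenomicInterval(c.chrom, c.position, c.position + 1, c.ns_cluster_id)
             for c in cohort.insertion_calls[ind]),
            out / "calls" / f"{ind}.bed",
        )
        write_deletion_vcf(
            cohort.deletion_records[ind], out / "vcfs" / f"{ind}.vcf", ind,
            chimp_lengths,
        )
        write_sam_flag_stream(
            cohort.ur_records[ind], out / "urs" / f"{ind}.sam", ns_lengths
        )

    import dataclasses

    import yaml

    with open(out / "config.yaml", "w") as fh:
        cfg = dataclasses.asdict(config)
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()
        }
        yaml.safe_dump(cfg, fh, sort_keys=True)
    with open(out / "blast_hits.tsv", "w") as fh:
        fh.write("contig\ttaxon_group\te_value\n")
        for name, group, e in cohort.blast_hits:
            fh.write(f"{name}\t{group}\t{e:.3e}\n")
    with open(out / "sample_sheet.tsv", "w") as fh:
        fh.write("individual_id\tpopulation\n")
        for ind in truth.individuals:
            fh.write(f"{ind}\t{truth.populations[ind]}\n")
    with open(out / "truth_ns.tsv", "w") as fh:
        fh.write(
            "ns_id\tlength\ttrue_af\tn_carriers\tis_ancestral\tnovel_vs_human\t"
            "site_chrom\tsite_pos\tcarriers\n"
        )
        for t in truth.ns.values():
            chrom, pos = t.site if t.site else (".", -1)
            fh.write(
                f"{t.ns_id}\t{t.length}\t{t.true_af:.6f}\t{len(t.carriers)}\t"
                f"{int(t.is_ancestral)}\t{int(t.novel_vs_human)}\t{chrom}\t{pos}\t"
                f"{','.join(sorted(t.carriers))}\n"
            )
    with open(out / "truth_contig_sources.tsv", "w") as fh:
        fh.write("contig\tsource\tsource_id\n")
        for name, src in truth.contig_sources.items():
            fh.write(f"{name}\t{src[0]}\t{src[1] if len(src) > 1 else '.'}\n")
    with open(out / "novelty_status.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tns_id\tstatus\n")
        for iv in truth.deleted_regions:
            status = (
                "deleted_in_new"
                if truth.ns[iv.label].novel_vs_human
                else "lifts_over"
            )
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{status}\n")
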