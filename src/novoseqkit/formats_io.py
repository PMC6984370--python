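"""Readers and writers for the plain-text formats the pipeline touches.

All coordinates are normalised to a single internal convention: 0-based,
half-open.  BED is native; VCF positions, show-coords rows and RepeatMasker
intervals (both 1-based inclusive) are converted at the boundary.

Domain types shared by every stage live here as small dataclasses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "AlignmentHit",
    "GenomicInterval",
    "RepeatAnnotation",
    "DeletionRecord",
    "SamFlagRecord",
    "REPEAT_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_coords_table",
    "write_coords_table",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "read_bed",
    "write_bed",
    "read_deletion_vcf",
    "write_deletion_vcf",
    "read_sam_flag_stream",
    "write_sam_flag_stream",
    "map_repeat_class",
]

#: The fixed repeat-class vocabulary.  ``Unmasked`` is implicit: the
#: complement of all annotated bases of a sequence.
REPEAT_CLASSES = (
    "LINE",
    "SINE",
    "LTR",
    "DNA",
    "Simple_repeat",
    "Satellite",
    "RNA",
    "Low_complexity",
    "Other",
    "Unmasked",
)

SAM_FLAG_UNMAPPED = 0x4
SAM_FLAG_SECONDARY = 0x100
SAM_FLAG_SUPPLEMENTARY = 0x800


class FormatError(ValueError):
    """Raised on malformed input in any of the text formats."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    """One assembled sequence owned by one individual.

    The sequence name follows the ``IndividualXYZ_I`` convention: the
    individual id and a per-individual local id joined by the LAST
    underscore, so individual ids may themselves contain underscores.
    """

    individual_id: str
    local_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"contig {self.name!r} has an empty sequence")

    @property
    def name(self) -> str:
        return f"{self.individual_id}_{self.local_id}"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_name(cls, name: str, sequence: str) -> "Contig":
        if "_" not in name:
            raise FormatError(
                f"contig name {name!r} has no underscore; expected IndividualXYZ_I"
            )
        ind, local = name.rsplit("_", 1)
        return cls(individual_id=ind, local_id=local, sequence=sequence)


@dataclass
class AlignmentHit:
    """One query-vs-target local alignment with percent identity and
    percent query coverage."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    identity_pct: float
    query_cov_pct: float
    target_cov_pct: float = 0.0

    def __post_init__(self) -> None:
        if not (self.query_start < self.query_end):
            raise FormatError(f"hit {self.query_id}: query_start >= query_end")
        if not (self.target_start < self.target_end):
            raise FormatError(f"hit {self.query_id}: target_start >= target_end")
        for v in (self.identity_pct, self.query_cov_pct):
            if not (0.0 <= v <= 100.0):
                raise FormatError(f"hit {self.query_id}: percentage {v} out of [0,100]")
        if self.strand not in ("+", "-"):
            raise FormatError(f"hit {self.query_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end} is not a valid "
                "0-based half-open interval"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RepeatAnnotation:
    """Per-sequence repeat annotation: non-overlapping (start, end, class)
    intervals on the sequence; unannotated bases are implicitly Unmasked."""

    seq_id: str
    seq_length: int
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e, c in self.intervals:
            if not (0 <= s < e <= self.seq_length):
                raise FormatError(
                    f"{self.seq_id}: repeat interval [{s},{e}) outside "
                    f"[0,{self.seq_length})"
                )
            if c not in REPEAT_CLASSES or c == "Unmasked":
                raise FormatError(f"{self.seq_id}: unknown repeat class {c!r}")

    def class_base_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(REPEAT_CLASSES, 0)
        for s, e, c in self.intervals:
            counts[c] += e - s
        counts["Unmasked"] = self.seq_length - sum(
            v for k, v in counts.items() if k != "Unmasked"
        )
        return counts


@dataclass
class DeletionRecord:
    individual_id: str
    chrom: str
    start: int
    end: int
    filter_status: str
    svtype: str
    genotype: str  # hom_ref | het | hom_alt | missing

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"deletion {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.genotype not in ("hom_ref", "het", "hom_alt", "missing"):
            raise FormatError(f"bad genotype {self.genotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SamFlagRecord:
    read_id: str
    flag: int
    target_id: str | None = None

    def __post_init__(self) -> None:
        if self.flag < 0:
            raise FormatError(f"read {self.read_id}: negative flag")

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & SAM_FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & SAM_FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & SAM_FLAG_SUPPLEMENTARY)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read per-individual contigs from FASTA.

    The individual id and local id are parsed from the record id at the
    last underscore.  Sequences are uppercased.
    """
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        contigs.append(Contig.from_name(rec.id, seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike) -> None:
    records = (
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs
    )
    SeqIO.write(records, str(path), "fasta")


def write_plain_fasta(named_seqs: Iterable[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs that need not follow the contig naming
    convention (references, catalogs)."""
    records = (
        SeqRecord(Seq(s), id=n, description="") for n, s in named_seqs
    )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# show-coords tab dialect
# ---------------------------------------------------------------------------

# Column layout of the headerless `show-coords -H -T -c` tab dialect used
# throughout: [S1 E1 S2 E2 LEN1 LEN2 %IDY %COVR %COVQ TAGR TAGQ] where the
# S1/E1 pair is on the query, S2/E2 on the target, both 1-based inclusive.
_COORDS_NCOL = 11


def read_coords_table(path: str | os.PathLike) -> list[AlignmentHit]:
    """Parse a headerless show-coords tab table into alignment hits.

    1-based inclusive coordinates become 0-based half-open.  A row whose
    target start exceeds its target end is a reverse-strand hit; the
    coordinates are swapped and the strand set to ``-``.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _COORDS_NCOL:
                raise FormatError(
                    f"{path}:{lineno}: expected {_COORDS_NCOL} columns, "
                    f"got {len(fields)}"
                )
            qs, qe, ts, te = (int(x) for x in fields[:4])
            idy, covr, covq = float(fields[6]), float(fields[7]), float(fields[8])
            tag_r, tag_q = fields[9], fields[10]
            strand = "+"
            if ts > te:
                ts, te = te, ts
                strand = "-"
            hits.append(
                AlignmentHit(
                    query_id=tag_q,
                    target_id=tag_r,
                    query_start=qs - 1,
                    query_end=qe,
                    target_start=ts - 1,
                    target_end=te,
                    strand=strand,
                    identity_pct=idy,
                    query_cov_pct=covq,
                    target_cov_pct=covr,
                )
            )
    return hits


def write_coords_table(hits: Iterable[AlignmentHit], path: str | os.PathLike) -> None:
    """Inverse of :func:`read_coords_table` for canonical hits."""
    with open(path, "w") as fh:
        for h in hits:
            ts, te = h.target_start + 1, h.target_end
            if h.strand == "-":
                ts, te = te, ts
            len1 = h.query_end - h.query_start
            len2 = h.target_end - h.target_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_start + 1,
                        h.query_end,
                        ts,
                        te,
                        len1,
                        len2,
                        f"{h.identity_pct:.2f}",
                        f"{h.target_cov_pct:.2f}",
                        f"{h.query_cov_pct:.2f}",
                        h.target_id,
                        h.query_id,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------


def map_repeat_class(raw: str) -> str:
    """Map a RepeatMasker class/family string onto the 10-class vocabulary."""
    if raw.startswith("LINE"):
        return "LINE"
    if raw.startswith("SINE"):
        return "SINE"
    if raw.startswith("LTR"):
        return "LTR"
    if raw.startswith("DNA"):
        return "DNA"
    if raw == "Simple_repeat":
        return "Simple_repeat"
    if raw.startswith("Satellite"):
        return "Satellite"
    if raw.endswith("RNA"):
        return "RNA"
    if raw == "Low_complexity":
        return "Low_complexity"
    return "Other"


def parse_repeatmasker_out(
    path: str | os.PathLike, seq_lengths: dict[str, int]
) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file into per-sequence annotations.

    Overlapping annotations are resolved in favour of the row with the
    higher Smith-Waterman score (ties: the earlier row).  Every id in
    ``seq_lengths`` yields an annotation, fully Unmasked if unannotated.
    """
    rows_by_seq: dict[str, list[tuple[int, int, int, int, str]]] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], 4):  # 3 header lines
        fields = line.split()
        if not fields:
            continue
        try:
            score = int(fields[0])
            seq_id = fields[4]
            begin, end = int(fields[5]), int(fields[6])
            raw_class = fields[10]
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed row") from exc
        if seq_id not in seq_lengths:
            raise FormatError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
        cls = map_repeat_class(raw_class)
        # 1-based inclusive -> 0-based half-open
        rows_by_seq.setdefault(seq_id, []).append(
            (score, lineno, begin - 1, end, cls)
        )

    annotations = []
    for seq_id, seq_len in seq_lengths.items():
        rows = rows_by_seq.get(seq_id, [])
        # paint bases, higher score first; ties resolved by earlier row
        owner = [-1] * seq_len
        ordered = sorted(rows, key=lambda r: (-r[0], r[1]))
        classes = []
        for idx, (_score, _lineno, s, e, cls) in enumerate(ordered):
            classes.append(cls)
            for pos in range(max(s, 0), min(e, seq_len)):
                if owner[pos] == -1:
                    owner[pos] = idx
        intervals: list[tuple[int, int, str]] = []
        run_start, run_owner = 0, owner[0] if seq_len else -1
        for pos in range(1, seq_len + 1):
            cur = owner[pos] if pos < seq_len else -2
            if cur != run_owner:
                if run_owner >= 0:
                    intervals.append((run_start, pos, classes[run_owner]))
                run_start, run_owner = pos, cur
        annotations.append(RepeatAnnotation(seq_id, seq_len, intervals))
    return annotations


def write_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation], path: str | os.PathLike
) -> None:
    """Write annotations in a minimal RepeatMasker ``.out`` layout (used for
    round-trip tests and synthetic fixtures)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query  matching repeat\n"
            "score  div. del. ins.  sequence  begin end (left)   repeat class/family\n"
            "\n"
        )
        for ann in annotations:
            for s, e, cls in ann.intervals:
                fh.write(
                    f"  500  0.0  0.0  0.0  {ann.seq_id}  {s + 1}  {e}  "
                    f"(0)  +  rep  {cls}  1  {e - s}  (0)  1\n"
                )


def write_repeat_annotation_tsv(
    annotations: Iterable[RepeatAnnotation], path: str | os.PathLike
) -> None:
    """seq_id, length and semicolon-joined start-end:class intervals."""
    with open(path, "w") as fh:
        fh.write("seq_id\tlength\tintervals\n")
        for ann in annotations:
            ivs = ";".join(f"{s}-{e}:{c}" for s, e, c in ann.intervals)
            fh.write(f"{ann.seq_id}\t{ann.seq_length}\t{ivs}\n")


def read_repeat_annotation_tsv(path: str | os.PathLike) -> list[RepeatAnnotation]:
    annotations = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            seq_id, length, ivs = (line.rstrip("\n").split("\t") + [""])[:3]
            intervals = []
            for part in filter(None, ivs.split(";")):
                rng, cls = part.rsplit(":", 1)
                s, e = rng.split("-")
                intervals.append((int(s), int(e), cls))
            annotations.append(RepeatAnnotation(seq_id, int(length), intervals))
    return annotations


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else "."
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            intervals.append(GenomicInterval(chrom, start, end, label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# VCF (minimal, symbolic <DEL>)
# ---------------------------------------------------------------------------

_GT_MAP = {
    (0, 0): "hom_ref",
    (0, 1): "het",
    (1, 0): "het",
    (1, 1): "hom_alt",
}


def read_deletion_vcf(
    path: str | os.PathLike, individual_id: str | None = None
) -> list[DeletionRecord]:
    """Read a minimal single-sample VCF of structural-variant calls.

    1-based POS becomes a 0-based start; the end comes from INFO/END or,
    failing that, POS - 1 + \\|SVLEN\\|.  Records are NOT filtered here:
    FILTER and SVTYPE are carried through for a later filtering stage.
    """
    records = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if individual_id is None:
            individual_id = samples[0] if samples else "unknown"
        for rec in vf:
            svtype = rec.info.get("SVTYPE", "other")
            svtype = svtype if svtype == "DEL" else "other"
            start = rec.pos - 1
            if "END" in rec.info:
                end = rec.stop
            elif "SVLEN" in rec.info:
                svlen = rec.info["SVLEN"]
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                end = start + abs(int(svlen))
            elif rec.stop > rec.pos:  # explicit REF allele span
                end = rec.stop
            else:
                raise FormatError(
                    f"{path}: {rec.chrom}:{rec.pos}: DEL with neither END nor SVLEN"
                )
            if end <= start:
                raise FormatError(f"{path}: {rec.chrom}:{rec.pos}: empty interval")
            filters = list(rec.filter.keys())
            filter_status = filters[0] if filters else "PASS"
            genotype = "missing"
            if samples:
                gt = rec.samples[samples[0]].get("GT")
                genotype = _GT_MAP.get(tuple(gt) if gt else None, "missing")
            records.append(
                DeletionRecord(
                    individual_id=individual_id,
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    filter_status=filter_status,
                    svtype=svtype,
                    genotype=genotype,
                )
            )
    return records


_GT_INV = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_deletion_vcf(
    records: list[DeletionRecord],
    path: str | os.PathLike,
    sample_id: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal single-sample VCF 4.2 with symbolic ALT alleles."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.start)):
            alt = "<DEL>" if rec.svtype == "DEL" else "<DUP>"
            svtype = "DEL" if rec.svtype == "DEL" else "DUP"
            fh.write(
                f"{rec.chrom}\t{rec.start + 1}\t.\tN\t{alt}\t.\t{rec.filter_status}\t"
                f"SVTYPE={svtype};END={rec.end}\tGT\t{_GT_INV[rec.genotype]}\n"
            )


# ---------------------------------------------------------------------------
# SAM text
# ---------------------------------------------------------------------------


def read_sam_flag_stream(path: str | os.PathLike) -> Iterator[SamFlagRecord]:
    """Yield (read_id, flag, target) per alignment line of a text SAM file.

    No filtering is applied here; flag-based counting is a later stage.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 SAM columns")
            try:
                flag = int(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer flag {fields[1]!r}"
                ) from exc
            target = None if flag & SAM_FLAG_UNMAPPED else fields[2]
            if target == "*":
                target = None
            yield SamFlagRecord(read_id=fields[0], flag=flag, target_id=target)


def write_sam_flag_stream(
    records: Iterable[tuple[SamFlagRecord, str]],
    path: str | os.PathLike,
    target_lengths: dict[str, int],
) -> None:
    """Write (record, read_sequence) pairs as text SAM with a full header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid, ln in target_lengths.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{ln}\n")
        for rec, seq in records:
            if rec.target_id is None:
                fh.write(
                    f"{rec.read_id}\t{rec.flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
                )
            else:
                fh.write(
                    f"{rec.read_id}\t{rec.flag}\t{rec.target_id}\t1\t60\t"
                    f"{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
                )
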