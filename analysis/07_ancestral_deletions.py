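#!/usr/bin/env python
"""Ancestral deletions and chimpanzee-reference-allele frequencies.

Filters per-individual deletion VCFs (PASS, symbolic <DEL>), merges
calls by reciprocal overlap >= 0.7, intersects the merged events with
the NS regions on chimp coordinates, keeps events whose region is
absent from the human reference (liftover verdict "deleted_in_new"),
and counts CRA carriers (every individual not homozygous for the
deletion).  Writes results/cra_events.tsv.
"""

import argparse
from pathlib import Path

from novoseqkit import ancestral_deletions as ad
from novoseqkit.formats_io import GenomicInterval, read_bed, read_deletion_vcf

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default=ROOT / "scratch" / "cohort", type=Path)
    parser.add_argument("--results", default=ROOT / "results", type=Path)
    args = parser.parse_args()

    vcfs = sorted((args.cohort / "vcfs").glob("*.vcf"))
    records = []
    for vcf in vcfs:
        records.extend(read_deletion_vcf(vcf, individual_id=vcf.stem))
    n_individuals = len(vcfs)

    kept = ad.filter_deletions(records)
    merged = ad.merge_by_reciprocal_overlap(kept)
    merged = ad.intersect_with_ns(merged, read_bed(args.cohort / "deleted_regions.bed"))
    merged = [m for m in merged if m.overlapping_ns_ids]
    status = []
    with open(args.cohort / "novelty_status.tsv") as fh:
        next(fh)
        for line in fh:
            chrom, s, e, ns_id, st = line.split()
            status.append((GenomicInterval(chrom, int(s), int(e), ns_id), st))
    merged = ad.check_novelty(merged, status)
    merged = [m for m in merged if m.novel_vs_human]
    for m in merged:
        ad.cra_frequency(m, n_individuals)

    with open(args.results / "cra_events.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tlength\tn_calls\tcra_carriers\t"
                 "cra_carrier_freq\tcra_allele_freq\tcommon\tns_ids\n")
        for m in merged:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.length}\t"
                f"{m.n_individuals_with_call}\t{m.cra_carriers}\t"
                f"{m.cra_carrier_freq:.4f}\t{m.cra_allele_freq:.4f}\t"
                f"{int(m.common)}\t{','.join(sorted(m.overlapping_ns_ids))}\n"
            )

    n_common = sum(1 for m in merged if m.common)
    n_all = sum(1 for m in merged if m.cra_carriers == n_individuals)
    print(f"{len(records)} deletion records from {n_individuals} individuals")
    print(f"  PASS <DEL> records  : {len(kept)}")
    print(f"  CRA events (novel)  : {len(merged)}")
    print(f"  common (freq > 5%)  : {n_common}")
    print(f"  carried by everyone : {n_all}")


if __name__ == "__main__":
    main()
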