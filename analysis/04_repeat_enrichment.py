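#!/usr/bin/env python
"""Repeat-class composition of NS vs a reference background.

Represents the human-like reference as 500,000 random intervals whose
sizes follow the kept-cluster size distribution, then runs the
permutation test (10,000 random subsets) of per-class base-percentage
differences for background-vs-NS and all-clusters-vs-NS.  Writes
results/repeat_enrichment.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from novoseqkit import repeat_enrichment as re_
from novoseqkit.formats_io import REPEAT_CLASSES, read_bed, read_repeat_annotation_tsv

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default=ROOT / "scratch" / "cohort", type=Path)
    parser.add_argument("--results", default=ROOT / "results", type=Path)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-background", type=int, default=500_000)
    parser.add_argument("--n-perm", type=int, default=10_000)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    # planted NS annotations stand in for a RepeatMasker run (annotation
    # is recorded at generation time, not re-detected)
    ns_ids = {line.split()[0] for line in open(args.results / "ns_status.tsv")
              if line.split()[1] == "1"}
    truth_ann = {
        ann.seq_id: ann
        for ann in read_repeat_annotation_tsv(args.cohort / "ns_annotations.tsv")
    }
    mat_ns = re_.annotations_to_matrix([truth_ann[i] for i in sorted(ns_ids & set(truth_ann))])

    sizes = []
    with open(args.results / "clusters.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        i_len = header.index("rep_length")
        for line in fh:
            sizes.append(int(line.split("\t")[i_len]))

    track = read_bed(args.cohort / "human_repeats.bed")
    chrom_lengths = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(args.cohort / "human_ref.fa"), "fasta"):
        chrom_lengths[rec.id] = len(rec.seq)

    background = re_.sample_background(
        chrom_lengths, track, sizes, n=args.n_background, rng=rng
    )
    profile_bg = re_.composition_of_set(background.counts)
    profile_ns = re_.composition_of_set(mat_ns)
    res = re_.permutation_test(background.counts, mat_ns, args.n_perm, rng=rng)

    with open(args.results / "repeat_enrichment.tsv", "w") as fh:
        fh.write("class\tpct_background\tpct_ns\tdiff\tp_value\n")
        for cls in REPEAT_CLASSES:
            fh.write(
                f"{cls}\t{profile_bg.percentages[cls]:.3f}\t"
                f"{profile_ns.percentages[cls]:.3f}\t"
                f"{res.observed_diff[cls]:.3f}\t{res.p_values[cls]:.6g}\n"
            )
    print(f"background-vs-NS permutation test ({args.n_perm} subsets, "
          f"resolution {res.resolution:g}):")
    for cls in REPEAT_CLASSES:
        print(f"  {cls:<15} bg {profile_bg.percentages[cls]:6.2f}%  "
              f"ns {profile_ns.percentages[cls]:6.2f}%  p {res.p_values[cls]:.4g}")


if __name__ == "__main__":
    main()
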