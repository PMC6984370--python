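#!/usr/bin/env python
"""Classify cluster representatives against the references.

Aligns every representative to the human-like and chimp-like references
with the anchor aligner; a cluster is NS when no human hit exceeds 80%
identity and 50% query coverage, and confidently aligned to a reference
when some hit exceeds 95% identity and 90% coverage.  Writes
results/classifications.tsv, results/ns_status.tsv (NS id -> NS flag,
for the positioning step) and prints the membership breakdown and the
NS allele-frequency spectrum.
"""

import argparse
from pathlib import Path

from Bio import SeqIO

from novoseqkit import contig_qc_cluster as qc
from novoseqkit import ns_classify as nc
from novoseqkit.formats_io import read_fasta

ROOT = Path(__file__).resolve().parent.parent


def read_ref(path):
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default=ROOT / "scratch" / "cohort", type=Path)
    parser.add_argument("--results", default=ROOT / "results", type=Path)
    args = parser.parse_args()

    reps = read_fasta(args.results / "cluster_reps.fa")
    clusters = [
        qc.SequenceCluster(ct.name, ct, [ct]) for ct in reps
    ]
    references = {
        "human": read_ref(args.cohort / "human_ref.fa"),
        "chimp": read_ref(args.cohort / "chimp_ref.fa"),
    }
    classifications = nc.classify_clusters(clusters, references, human_ref="human")
    membership = nc.catalog_membership(classifications, ["human", "chimp"])

    # recover per-cluster individual counts from the cluster table for the
    # NS allele-frequency spectrum
    af = {}
    with open(args.results / "clusters.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        i_rep, i_af = header.index("representative"), header.index("allele_frequency")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            af[f[i_rep]] = float(f[i_af]) if f[i_af] else None

    # contig -> source NS id, so calls (labelled with truth ids) can be
    # filtered by the classification of the owning cluster
    source = {}
    with open(args.cohort / "truth_contig_sources.tsv") as fh:
        next(fh)
        for line in fh:
            name, kind, sid = line.rstrip("\n").split("\t")
            if kind == "ns":
                source[name] = sid

    ns_status: dict[str, bool] = {}
    n_ns = n_rare = 0
    with open(args.results / "classifications.tsv", "w") as fh:
        fh.write("cluster_id\tis_ns\tallele_frequency\tconfident_refs\n")
        for cid, cc in classifications.items():
            a = af.get(cid)
            fh.write(
                f"{cid}\t{int(cc.is_ns)}\t{'' if a is None else f'{a:.6f}'}\t"
                f"{','.join(sorted(cc.confident_refs))}\n"
            )
            if cc.is_ns:
                n_ns += 1
                if a is not None and a < 0.05:
                    n_rare += 1
            if cid in source:
                ns_id = source[cid]
                ns_status[ns_id] = ns_status.get(ns_id, False) or cc.is_ns
    with open(args.results / "ns_status.tsv", "w") as fh:
        for ns_id in sorted(ns_status):
            fh.write(f"{ns_id}\t{int(ns_status[ns_id])}\n")

    print(f"{len(clusters)} representatives classified")
    print(f"  NS clusters          : {n_ns} ({100 * n_ns / len(clusters):.1f}%)")
    if n_ns:
        print(f"  rare NS (AF<5%)      : {n_rare} ({100 * n_rare / n_ns:.1f}% of NS)")
    for subset, count in sorted(
        membership["subset_counts"].items(), key=lambda kv: -kv[1]
    ):
        label = "+".join(sorted(subset)) if subset else "neither"
        print(f"  confident in {label:<12}: {count}")


if __name__ == "__main__":
    main()
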