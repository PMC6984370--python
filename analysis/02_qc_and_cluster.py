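#!/usr/bin/env python
"""QC and cluster the cohort's contigs.

Greedy identity/coverage clustering (c=0.95, aS=aL=0.90) of all
per-individual contigs, removal of contaminant clusters (significant
non-primate BLAST-like hit, no primate hit, E < 1e-40) and of clusters
represented by sequences under 301 bp, then allele-frequency estimation.
Writes results/clusters.tsv and a representative FASTA for the
classification step.
"""

import argparse
from pathlib import Path

from novoseqkit import contig_qc_cluster as qc
from novoseqkit.formats_io import read_fasta, write_fasta

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default=ROOT / "scratch" / "cohort", type=Path)
    parser.add_argument("--results", default=ROOT / "results", type=Path)
    args = parser.parse_args()
    args.results.mkdir(exist_ok=True)

    contigs = []
    fastas = sorted((args.cohort / "contigs").glob("*.fa"))
    for fa in fastas:
        contigs.extend(read_fasta(fa))
    n_individuals = len(fastas)

    clusters = qc.greedy_cluster(contigs)
    hits = qc.read_blast_hits_tsv(args.cohort / "blast_hits.tsv")
    clean, contaminant = qc.classify_contaminants(clusters, hits)
    kept, small = qc.filter_clusters_by_size(clean)
    summary = qc.allele_frequencies(kept, n_individuals)

    qc.write_clusters(kept, args.results / "clusters.tsv",
                      args.results / "clusters.clstr")
    write_fasta([cl.representative for cl in kept],
                args.results / "cluster_reps.fa")

    print(f"{len(contigs)} contigs from {n_individuals} individuals")
    print(f"  clusters             : {len(clusters)}")
    print(f"  contaminant clusters : {len(contaminant)} removed")
    print(f"  sub-301 bp clusters  : {len(small)} removed")
    print(f"  kept clusters        : {len(kept)}")
    print(f"  fraction rare (AF<5%): {summary['fraction_rare']:.3f}")


if __name__ == "__main__":
    main()
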