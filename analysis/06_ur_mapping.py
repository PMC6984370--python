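#!/usr/bin/env python
"""Unmapped-read mapping fractions and population statistics.

Counts reads with the secondary/supplementary-excluding flag filters,
computes per-individual mapped fractions and allele-frequency depletion
curves (thresholds 0.5-10%), and tests for population differences with
one-way ANOVA plus Tukey HSD at every threshold.  Writes
results/ur_fractions.tsv, results/ur_curves.tsv and
results/ur_anova.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from novoseqkit import ur_mapping as ur
from novoseqkit.formats_io import read_sam_flag_stream

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default=ROOT / "scratch" / "cohort", type=Path)
    parser.add_argument("--results", default=ROOT / "results", type=Path)
    args = parser.parse_args()

    populations = {}
    with open(args.cohort / "sample_sheet.tsv") as fh:
        next(fh)
        for line in fh:
            ind, pop = line.split()
            populations[ind] = pop

    # cluster AF per NS id: planted truth AFs (the catalog the reads were
    # aligned to is the truth catalog)
    cluster_af = {}
    with open(args.cohort / "truth_ns.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        i_id, i_af = header.index("ns_id"), header.index("true_af")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            cluster_af[f[i_id]] = float(f[i_af])

    fractions, curves = [], []
    for sam in sorted((args.cohort / "urs").glob("*.sam")):
        records = list(read_sam_flag_stream(sam))
        fractions.append(
            ur.mapping_fraction(records, sam.stem, populations[sam.stem])
        )
        curves.append(
            ur.depletion_curve(ur.primary_assignments(records), cluster_af,
                               individual_id=sam.stem)
        )

    with open(args.results / "ur_fractions.tsv", "w") as fh:
        fh.write("individual_id\tpopulation\tn_total\tn_mapped\tfraction\n")
        for mf in fractions:
            fh.write(f"{mf.individual_id}\t{mf.population}\t{mf.n_total}\t"
                     f"{mf.n_mapped}\t{mf.fraction:.6f}\n")
    thresholds = sorted(curves[0].remaining_fraction)
    with open(args.results / "ur_curves.tsv", "w") as fh:
        fh.write("individual_id\t" + "\t".join(str(t) for t in thresholds) + "\n")
        for c in curves:
            fh.write(c.individual_id + "\t" + "\t".join(
                f"{c.remaining_fraction[t]:.6f}" for t in thresholds) + "\n")

    by_pop = {}
    for mf in fractions:
        by_pop.setdefault(mf.population, []).append(mf.fraction)
    res = ur.population_anova_tukey(by_pop)
    with open(args.results / "ur_anova.tsv", "w") as fh:
        fh.write(f"min_af\tF\tp_value\n")
        fh.write(f"overall\t{res['F']:.4f}\t{res['p_value']:.4g}\n")
        ind_pop = {c.individual_id: populations[c.individual_id] for c in curves}
        for t in thresholds:
            if t == 0.0:
                continue
            groups = {}
            for c in curves:
                v = c.remaining_fraction[t]
                if not np.isnan(v):
                    groups.setdefault(ind_pop[c.individual_id], []).append(v)
            r = ur.population_anova_tukey(groups)
            fh.write(f"{t}\t{r['F']:.4f}\t{r['p_value']:.4g}\n")

    mean_pct = 100 * np.nanmean([mf.fraction for mf in fractions])
    rem05 = 100 * np.nanmean([c.remaining_fraction[0.05] for c in curves])
    print(f"{len(fractions)} individuals")
    print(f"  mean UR mapped fraction : {mean_pct:.2f}%")
    print(f"  UR on common NS (AF>=5%): {rem05:.1f}% of mapped UR")
    print(f"  population ANOVA        : F={res['F']:.3f}, p={res['p_value']:.3f}")


if __name__ == "__main__":
    main()
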