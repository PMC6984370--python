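#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emits a population of 100 individuals carrying 300 planted novel
sequences (NS) with a skewed allele-frequency spectrum, plus decoy,
sub-size and contaminant contigs, insertion breakpoint calls, deletion
VCFs against the chimp-like reference, and unmapped-read SAM files.
All files land under scratch/cohort/; downstream scripts read from
there.
"""

import argparse
from pathlib import Path

from novoseqkit.synthetic_cohort import SimConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parent.parent


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--outdir", default=ROOT / "scratch" / "cohort", type=Path)
    args = parser.parse_args()

    config = SimConfig(seed=args.seed)
    cohort = simulate_cohort(config)
    write_cohort(cohort, args.outdir)

    truth = cohort.truth
    n_contigs = sum(len(v) for v in cohort.contigs.values())
    n_rare = sum(1 for t in truth.ns.values() if t.true_af < 0.05)
    print(f"cohort written to {args.outdir}")
    print(f"  individuals          : {config.n_individuals}")
    print(f"  planted NS           : {config.n_ns} "
          f"({n_rare} rare, {sum(t.is_ancestral for t in truth.ns.values())} ancestral)")
    print(f"  contigs emitted      : {n_contigs}")
    print(f"  deleted regions (chimp coords): {len(truth.deleted_regions)}")


if __name__ == "__main__":
    main()
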