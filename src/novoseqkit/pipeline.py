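"""End-to-end orchestration: simulate -> qc -> cluster -> classify ->
repeats -> position -> enrich -> urmap -> deletions.

Every stage is a plain function over in-memory objects so tests and
analysis drivers can run them individually; :func:`run_all` chains them
and produces a machine-readable report.  Stage parameters default to the
published analysis settings (301 bp size filter, E < 1e-40, c=0.95 /
aS=aL=0.90 clustering, 95/90 and 80/50 classification thresholds,
DBSCAN eps=150 minPts=3 with the 5-individual filter, 10,000
permutations and simulation iterations, reciprocal overlap 0.7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import ancestral_deletions as ad
from . import contig_qc_cluster as qc
from . import ns_classify as nc
from . import positioning_enrichment as pe
from . import repeat_enrichment as re_
from . import ur_mapping as ur
from .formats_io import RepeatAnnotation
from .synthetic_cohort import Cohort, CohortTruth, SimConfig, simulate_cohort, write_cohort

__all__ = ["RunConfig", "run_all", "annotation_for_contig"]


@dataclass
class RunConfig:
    """All pipeline knobs with the published defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_contig_len: int = 301
    e_threshold: float = 1e-40
    cluster_c: float = 0.95
    cluster_aS: float = 0.90
    cluster_aL: float = 0.90
    thresholds: nc.ClassificationThresholds = field(
        default_factory=nc.ClassificationThresholds
    )
    n_background: int = 500_000
    n_permutations: int = 10_000
    dbscan_eps: int = 150
    dbscan_min_neighbors: int = 3
    min_individuals: int = 5
    enrich_iterations: int = 10_000
    enrich_region_size: int = 1_000
    af_thresholds: tuple[float, ...] = ur.DEFAULT_AF_THRESHOLDS
    reciprocal_overlap: float = 0.7

    @property
    def seed(self) -> int:
        return self.sim.seed

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, sim=replace(self.sim, seed=seed))


def annotation_for_contig(truth: CohortTruth, name: str) -> RepeatAnnotation | None:
    """Recorded repeat annotation for a contig: the owning NS's planted
    annotation, a repeat-track lookup for decoys, fully unmasked for
    contaminants; None when the contig is unknown."""
    src = truth.contig_sources.get(name)
    if src is None:
        return None
    kind = src[0]
    if kind == "ns":
        return truth.ns[src[1]].annotation
    if kind == "decoy":
        _, chrom, start, end = src
        intervals = []
        for iv in truth.human_repeat_track:
            if iv.chrom == chrom and iv.start < end and start < iv.end:
                intervals.append(
                    (max(iv.start, start) - start, min(iv.end, end) - start, iv.label)
                )
        return RepeatAnnotation(name, end - start, sorted(intervals))
    if kind in ("contaminant", "small"):
        length = (
            len(truth.contaminants[src[1]].sequence)
            if kind == "contaminant"
            else None
        )
        return None if length is None else RepeatAnnotation(name, length, [])
    return None


def _stage_qc_cluster(cohort: Cohort, config: RunConfig) -> dict:
    truth = cohort.truth
    contigs = [c for contigs in cohort.contigs.values() for c in contigs]
    clusters = qc.greedy_cluster(
        contigs, c=config.cluster_c, aS=config.cluster_aS, aL=config.cluster_aL
    )
    hits = [qc.BlastLikeHit(n, g, e) for n, g, e in cohort.blast_hits]
    clean, contaminant = qc.classify_contaminants(clusters, hits, config.e_threshold)
    kept, small = qc.filter_clusters_by_size(clean, config.min_contig_len)
    af_summary = qc.allele_frequencies(kept, truth.config.n_individuals)
    return {
        "contigs": contigs,
        "clusters_all": clusters,
        "clusters": kept,
        "contaminant_clusters": contaminant,
        "small_clusters": small,
        "af_summary": af_summary,
    }


def _stage_classify(cohort: Cohort, config: RunConfig, clusters) -> dict:
    truth = cohort.truth
    references = {"human": truth.human_ref, "chimp": truth.chimp_ref}
    classifications = nc.classify_clusters(
        clusters, references, human_ref="human", thresholds=config.thresholds
    )
    ns_clusters = [cl for cl in clusters if classifications[cl.cluster_id].is_ns]
    ns_af = qc.allele_frequencies(ns_clusters, truth.config.n_individuals) if ns_clusters else None
    membership = nc.catalog_membership(classifications, ["human", "chimp"])
    return {
        "classifications": classifications,
        "ns_clusters": ns_clusters,
        "ns_af_summary": ns_af,
        "membership": membership,
    }


def _stage_repeats(cohort: Cohort, config: RunConfig, clusters, ns_clusters, rng) -> dict:
    truth = cohort.truth
    def matrix_for(cluster_list):
        anns = []
        for cl in cluster_list:
            ann = annotation_for_contig(truth, cl.representative.name)
            if ann is not None:
                anns.append(ann)
        return re_.annotations_to_matrix(anns)

    mat_uc = matrix_for(clusters)
    mat_ns = matrix_for(ns_clusters)
    sizes = [cl.representative.length for cl in clusters]
    chrom_lengths = {c: len(s) for c, s in truth.human_ref.items()}
    background = re_.sample_background(
        chrom_lengths, truth.human_repeat_track, sizes,
        n=config.n_background, rng=rng,
    )
    results = {}
    if len(mat_ns) and len(background.counts) >= 2 * len(mat_ns):
        results["background_vs_ns"] = re_.permutation_test(
            background.counts, mat_ns, config.n_permutations, rng=rng
        )
    if len(mat_ns) and len(mat_uc) >= 2 * len(mat_ns):
        results["uc_vs_ns"] = re_.permutation_test(
            mat_uc, mat_ns, config.n_permutations, rng=rng
        )
    return {
        "profile_uc": re_.composition_of_set(mat_uc) if len(mat_uc) else None,
        "profile_ns": re_.composition_of_set(mat_ns) if len(mat_ns) else None,
        "tests": results,
    }


def _ns_status_map(cohort: Cohort, clusters, classifications) -> dict[str, bool]:
    """ns_id -> is the sequence NS (does not match the human reference),
    taken from the classification of the cluster owning each NS."""
    truth = cohort.truth
    status: dict[str, bool] = {}
    for cl in clusters:
        src = truth.contig_sources.get(cl.representative.name)
        if src and src[0] == "ns":
            cc = classifications[cl.cluster_id]
            status[src[1]] = status.get(src[1], False) or cc.is_ns
    for ns_id in truth.ns:
        status.setdefault(ns_id, True)
    return status


def _stage_position_enrich(cohort: Cohort, config: RunConfig, ns_status, rng) -> dict:
    truth = cohort.truth
    calls = [c for lst in cohort.insertion_calls.values() for c in lst]
    merged = pe.merge_insertions(
        calls, ns_status, eps=config.dbscan_eps,
        min_neighbors=config.dbscan_min_neighbors,
        min_individuals=config.min_individuals,
    )
    events = [m.interval() for m in merged]
    chrom_lengths = {c: len(s) for c, s in truth.human_ref.items()}
    tracks = {"genes": truth.gene_track, "repeats": truth.human_repeat_track}
    rows = pe.enrichment_table(
        events, tracks, chrom_lengths,
        region_size=config.enrich_region_size,
        iterations=config.enrich_iterations, rng=rng,
    ) if events else []
    return {"merged_insertions": merged, "enrichment": rows}


def _stage_urmap(cohort: Cohort, config: RunConfig, clusters) -> dict:
    truth = cohort.truth
    # recovered cluster AF per NS id (fall back to planted AF)
    ns_af = {t.ns_id: t.true_af for t in truth.ns.values()}
    for cl in clusters:
        src = truth.contig_sources.get(cl.representative.name)
        if src and src[0] == "ns" and cl.allele_frequency is not None:
            ns_af[src[1]] = max(ns_af.get(src[1], 0.0), cl.allele_frequency)

    fractions, curves = [], []
    for ind in truth.individuals:
        records = [rec for rec, _seq in cohort.ur_records[ind]]
        mf = ur.mapping_fraction(records, ind, truth.populations[ind])
        fractions.append(mf)
        curves.append(
            ur.depletion_curve(
                ur.primary_assignments(records), ns_af,
                thresholds=config.af_thresholds, individual_id=ind,
            )
        )
    by_pop: dict[str, list[float]] = {}
    for mf in fractions:
        by_pop.setdefault(mf.population, []).append(mf.fraction)
    anova = ur.population_anova_tukey(by_pop) if len(by_pop) >= 2 else None
    # Table-5-style: ANOVA of remaining fraction at each threshold
    per_threshold = {}
    pops = {mf.individual_id: mf.population for mf in fractions}
    for t in config.af_thresholds:
        groups: dict[str, list[float]] = {}
        for curve in curves:
            groups.setdefault(pops[curve.individual_id], []).append(
                curve.remaining_fraction[float(t)]
            )
        per_threshold[float(t)] = ur.population_anova_tukey(groups)
    return {
        "fractions": fractions,
        "curves": curves,
        "anova": anova,
        "per_threshold_anova": per_threshold,
    }


def _stage_deletions(cohort: Cohort, config: RunConfig) -> dict:
    truth = cohort.truth
    records = [r for lst in cohort.deletion_records.values() for r in lst]
    kept = ad.filter_deletions(records)
    merged = ad.merge_by_reciprocal_overlap(kept, config.reciprocal_overlap)
    merged = ad.intersect_with_ns(merged, truth.deleted_regions)
    merged = [m for m in merged if m.overlapping_ns_ids]
    status = [
        (iv, "deleted_in_new" if truth.ns[iv.label].novel_vs_human else "lifts_over")
        for iv in truth.deleted_regions
    ]
    merged = ad.check_novelty(merged, status)
    merged = [m for m in merged if m.novel_vs_human]
    n = truth.config.n_individuals
    for m in merged:
        ad.cra_frequency(m, n)
    return {
        "n_records": len(records),
        "n_pass_del": len(kept),
        "merged_deletions": merged,
        "n_common": sum(1 for m in merged if m.common),
        "n_all_carrier": sum(1 for m in merged if m.cra_carriers == n),
    }


def run_all(config: RunConfig, outdir: str | None = None) -> dict:
    """Run every stage in dependency order; returns the report dict and,
    when ``outdir`` is given, writes cohort emissions and report.json."""
    cohort = simulate_cohort(config.sim)
    if outdir:
        write_cohort(cohort, outdir)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(100,))
    )
    s_qc = _stage_qc_cluster(cohort, config)
    s_cls = _stage_classify(cohort, config, s_qc["clusters"])
    s_rep = _stage_repeats(
        cohort, config, s_qc["clusters"], s_cls["ns_clusters"], rng
    )
    ns_status = _ns_status_map(cohort, s_qc["clusters"], s_cls["classifications"])
    s_pos = _stage_position_enrich(cohort, config, ns_status, rng)
    s_ur = _stage_urmap(cohort, config, s_qc["clusters"])
    s_del = _stage_deletions(cohort, config)

    mean_fraction = float(
        np.nanmean([mf.fraction for mf in s_ur["fractions"]])
    )
    curves = s_ur["curves"]
    mean_remaining_05 = float(
        np.nanmean([c.remaining_fraction[0.05] for c in curves])
    )
    report = {
        "seed": config.seed,
        "n_individuals": config.sim.n_individuals,
        "n_contigs": len(s_qc["contigs"]),
        "n_clusters_total": len(s_qc["clusters_all"]),
        "n_contaminant_clusters": len(s_qc["contaminant_clusters"]),
        "n_small_clusters": len(s_qc["small_clusters"]),
        "n_clusters": len(s_qc["clusters"]),
        "fraction_rare_uc": s_qc["af_summary"]["fraction_rare"],
        "n_ns_clusters": len(s_cls["ns_clusters"]),
        "fraction_rare_ns": (
            s_cls["ns_af_summary"]["fraction_rare"]
            if s_cls["ns_af_summary"]
            else float("nan")
        ),
        "repeat_p_values": {
            name: res.p_values for name, res in s_rep["tests"].items()
        },
        "n_merged_insertions": len(s_pos["merged_insertions"]),
        "enrichment": [
            {
                "feature": r.feature_name,
                "unique_ns": r.unique_ns,
                "observed_events": r.observed_events,
                "observed_pct": r.observed_pct,
                "simulated_pct": r.simulated_pct,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in s_pos["enrichment"]
        ],
        "mean_ur_mapped_fraction_pct": 100.0 * mean_fraction,
        "mean_remaining_fraction_af05": mean_remaining_05,
        "ur_anova_p": s_ur["anova"]["p_value"] if s_ur["anova"] else float("nan"),
        "n_cra_events": len(s_del["merged_deletions"]),
        "n_cra_common": s_del["n_common"],
        "n_cra_all_carrier": s_del["n_all_carrier"],
    }
    stages = {
        "cohort": cohort,
        "qc": s_qc,
        "classify": s_cls,
        "repeats": s_rep,
        "position": s_pos,
        "urmap": s_ur,
        "deletions": s_del,
    }
    if outdir:
        with open(Path(outdir) / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return {"report": report, "stages": stages}
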