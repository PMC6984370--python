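"""Generator correctness: reference construction, carrier bookkeeping,
emission statistics and seed determinism."""

import filecmp
import math

import numpy as np
import pytest

from novoseqkit import synthetic_cohort as sc
from novoseqkit.ur_mapping import count_reads

from conftest import small_sim_config


class TestReferences:
    def test_no_ancestral_ns_means_identical_references(self):
        cfg = small_sim_config(ancestral_fraction=0.0)
        human, chimp, table = sc.build_references(cfg)
        assert chimp == human
        assert table == []

    def test_insertion_length_conservation(self):
        cfg = small_sim_config()
        truth = sc.generate_truth(cfg)
        extra = sum(len(s) for s in truth.chimp_ref.values()) - sum(
            len(s) for s in truth.human_ref.values()
        )
        planted = sum(
            t.length for t in truth.ns.values() if t.is_ancestral
        )
        assert extra == planted

    def test_deleted_region_slices_equal_ns_sequences(self):
        truth = sc.generate_truth(small_sim_config())
        assert truth.deleted_regions
        for iv in truth.deleted_regions:
            assert truth.chimp_ref[iv.chrom][iv.start : iv.end] == truth.ns[iv.label].sequence

    def test_repeat_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            small_sim_config(repeat_mix={"Unmasked": 0.5, "LINE": 0.4})


class TestCarriers:
    def test_rounding_rule(self):
        assert sc.carrier_count(0.5, 10) == 5
        assert sc.carrier_count(0.001, 100) == 1  # at least one carrier
        assert sc.carrier_count(1.0, 7) == 7

    def test_carrier_sets_match_af(self):
        truth = sc.generate_truth(small_sim_config())
        n = truth.config.n_individuals
        for t in truth.ns.values():
            assert abs(len(t.carriers) - round(t.true_af * n)) <= 1
            assert 1 <= len(t.carriers) <= n


class TestIndividuals:
    def test_exact_copies_without_mutation_or_fragmentation(self):
        cfg = small_sim_config(
            mutation_rate=0.0, fragmentation_prob=0.0, revcomp_prob=0.0
        )
        truth = sc.generate_truth(cfg)
        contigs = sc.simulate_individuals(cfg, truth)
        for ind, lst in contigs.items():
            for c in lst:
                src = truth.contig_sources[c.name]
                if src[0] == "ns":
                    assert c.sequence == truth.ns[src[1]].sequence

    def test_contig_accounting(self):
        cfg = small_sim_config(fragmentation_prob=0.0)
        truth = sc.generate_truth(cfg)
        contigs = sc.simulate_individuals(cfg, truth)
        for ind, lst in contigs.items():
            carried = sum(1 for t in truth.ns.values() if ind in t.carriers)
            contaminants = sum(
                1 for ct in truth.contaminants.values() if ind in ct.carriers
            )
            expected = (
                carried
                + contaminants
                + cfg.n_decoys_per_individual
                + cfg.n_small_per_individual
            )
            assert len(lst) == expected

    def test_base_conservation_per_ns(self):
        """With mutation and fragmentation off, every carrier contributes
        exactly the planted sequence length."""
        cfg = small_sim_config(mutation_rate=0.0, fragmentation_prob=0.0)
        truth = sc.generate_truth(cfg)
        contigs = sc.simulate_individuals(cfg, truth)
        by_ns: dict[str, int] = {}
        for lst in contigs.values():
            for c in lst:
                src = truth.contig_sources[c.name]
                if src[0] == "ns":
                    by_ns[src[1]] = by_ns.get(src[1], 0) + c.length
        for ns_id, total in by_ns.items():
            t = truth.ns[ns_id]
            assert total == t.length * len(t.carriers)

    def test_fragments_at_least_min_size(self):
        cfg = small_sim_config(fragmentation_prob=1.0)
        truth = sc.generate_truth(cfg)
        contigs = sc.simulate_individuals(cfg, truth)
        for lst in contigs.values():
            for c in lst:
                if truth.contig_sources[c.name][0] == "ns":
                    assert c.length >= 301


class TestInsertionCalls:
    def test_zero_jitter_reproduces_sites(self):
        cfg = small_sim_config(breakpoint_jitter_sd=0.0, false_call_rate=0.0)
        truth = sc.generate_truth(cfg)
        calls = sc.emit_insertion_calls(truth, cfg)
        sites = {t.ns_id: t.site for t in truth.ns.values() if t.site}
        n_calls = 0
        for lst in calls.values():
            for c in lst:
                n_calls += 1
                assert (c.chrom, c.position) == sites[c.ns_cluster_id]
        assert n_calls == sum(
            len(t.carriers) for t in truth.ns.values() if t.site
        )

    def test_zero_false_rate_means_all_calls_true(self):
        cfg = small_sim_config(false_call_rate=0.0)
        truth = sc.generate_truth(cfg)
        calls = sc.emit_insertion_calls(truth, cfg)
        for ind, lst in calls.items():
            for c in lst:
                assert ind in truth.ns[c.ns_cluster_id].carriers

    def test_jitter_sd_recovered(self):
        cfg = small_sim_config(
            n_individuals=60, n_ns=60, positioned_fraction=1.0,
            ref_length=1_000_000, rare_fraction=0.0,
            common_af_range=(0.3, 0.6),
            false_call_rate=0.0, hybrid_fraction=0.0,
        )
        truth = sc.generate_truth(cfg)
        calls = sc.emit_insertion_calls(truth, cfg)
        sites = {t.ns_id: t.site[1] for t in truth.ns.values() if t.site}
        jitters = np.array(
            [c.position - sites[c.ns_cluster_id] for lst in calls.values() for c in lst],
            dtype=float,
        )
        assert len(jitters) >= 1000
        sd = jitters.std(ddof=1)
        se_sd = cfg.breakpoint_jitter_sd / math.sqrt(2 * len(jitters))
        assert abs(sd - cfg.breakpoint_jitter_sd) < 3 * se_sd + 0.5  # +0.5 rounding


class TestDeletionEmission:
    def test_all_carrier_ns_yields_no_records(self):
        cfg = small_sim_config(
            ancestral_fraction=1.0, positioned_fraction=1.0,
            rare_fraction=0.0, common_af_range=(0.999, 0.9999),
            background_del_rate=0.0, background_dup_rate=0.0,
            lowqual_fraction=0.0,
        )
        truth = sc.generate_truth(cfg)
        dels = sc.emit_deletion_vcfs(truth, cfg)
        # every individual carries every NS; hom-deletion records can only
        # come from single-copy carriers (het), never hom_alt
        for lst in dels.values():
            for rec in lst:
                assert rec.genotype == "het"

    def test_padded_interval_contains_truth(self):
        """Any deletion record overlapping a planted deleted region must
        contain it fully (padding only widens)."""
        cfg = small_sim_config()
        truth = sc.generate_truth(cfg)
        dels = sc.emit_deletion_vcfs(truth, cfg)
        checked = 0
        for lst in dels.values():
            for rec in lst:
                if rec.svtype != "DEL":
                    continue
                for iv in truth.deleted_regions:
                    if iv.chrom == rec.chrom and rec.start < iv.end and iv.start < rec.end:
                        assert rec.start <= iv.start and rec.end >= iv.end
                        checked += 1
        assert checked > 0

    def test_genotype_proportions_match_diploid_model(self):
        cfg = small_sim_config(
            n_individuals=100, n_ns=80, ancestral_fraction=1.0,
            positioned_fraction=1.0, ref_length=1_200_000,
            background_del_rate=0.0, background_dup_rate=0.0,
            lowqual_fraction=0.0,
        )
        truth = sc.generate_truth(cfg)
        sc.emit_deletion_vcfs(truth, cfg)
        n_het = exp_het = var_het = 0.0
        for ns_id, copies in truth.ancestral_copies.items():
            t = truth.ns[ns_id]
            p = 1.0 - math.sqrt(1.0 - t.true_af)
            p_two = p / (2.0 - p)
            k = len(t.carriers)
            n_het += sum(1 for c in copies.values() if c == 1)
            exp_het += k * (1 - p_two)
            var_het += k * p_two * (1 - p_two)
        assert abs(n_het - exp_het) < 3 * math.sqrt(var_het)


class TestUnmappedReads:
    def test_mapped_fraction_recovered(self, small_cohort):
        cfg = small_cohort.truth.config
        totals = mapped = 0
        for recs in small_cohort.ur_records.values():
            t, m = count_reads(r for r, _ in recs)
            totals += t
            mapped += m
        p = cfg.ur_mapped_fraction
        se = math.sqrt(totals * p * (1 - p))
        assert abs(mapped - totals * p) < 3 * se

    def test_duplicate_records_never_change_counts(self, small_cohort):
        for recs in small_cohort.ur_records.values():
            primary = [r for r, _ in recs if not (r.flag & 0x900)]
            assert count_reads(r for r, _ in recs) == count_reads(primary)

    def test_all_ns_reads_when_no_random_reads(self):
        cfg = small_sim_config(ur_mapped_fraction=1.0)
        truth = sc.generate_truth(cfg)
        reads = sc.emit_unmapped_reads(truth, cfg)
        for ind, recs in reads.items():
            t, m = count_reads(r for r, _ in recs)
            if any(ind in x.carriers for x in truth.ns.values()):
                assert m == t


class TestDeterminism:
    def test_same_seed_byte_identical_emissions(self, tmp_path):
        cfg = small_sim_config(seed=99)
        for d in ("a", "b"):
            sc.write_cohort(sc.simulate_cohort(cfg), tmp_path / d)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")

        def assert_equal(c):
            assert not c.diff_files and not c.left_only and not c.right_only
            for sub in c.subdirs.values():
                assert_equal(sub)

        assert_equal(cmp)
        # and they genuinely compare content, not just names
        files = list((tmp_path / "a").rglob("*"))
        assert any(f.is_file() for f in files)
        for f in files:
            if f.is_file():
                rel = f.relative_to(tmp_path / "a")
                assert f.read_bytes() == (tmp_path / "b" / rel).read_bytes()
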