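"""QC filters, pairwise identity/coverage, and greedy clustering against a
brute-force oracle."""

import numpy as np
import pytest

from novoseqkit import contig_qc_cluster as qc
from novoseqkit.formats_io import Contig
from novoseqkit.synthetic_cohort import mutate, revcomp

from conftest import random_dna


def make_contig(ind, local, seq):
    return Contig(ind, str(local), seq)


def oracle_greedy(contigs, c=0.95, aS=0.90, aL=0.90):
    """Brute-force first-fit greedy clustering with the same join rule
    (no length-window shortcut): the independent reference partition."""
    ordered = sorted(contigs, key=lambda x: (-x.length, x.name))
    clusters: list[list[Contig]] = []
    for ct in ordered:
        for cl in clusters:
            if qc.satisfies_join(ct, cl[0], c, aS, aL):
                cl.append(ct)
                break
        else:
            clusters.append([ct])
    return [frozenset(m.name for m in cl) for cl in clusters]


def partition(clusters):
    return [frozenset(m.name for m in cl.members) for cl in clusters]


# ---------------------------------------------------------------------------
# size filter
# ---------------------------------------------------------------------------


class TestSizeFilter:
    def test_boundary_301(self, rng):
        contigs = [
            make_contig("A", i, random_dna(rng, n)) for i, n in enumerate([300, 301, 5000])
        ]
        kept, removed = qc.filter_by_size(contigs)
        assert [c.length for c in kept] == [301, 5000]
        assert [c.length for c in removed] == [300]

    def test_empty_input(self):
        assert qc.filter_by_size([]) == ([], [])

    def test_partition_is_exact(self, rng):
        contigs = [
            make_contig("A", i, random_dna(rng, int(n)))
            for i, n in enumerate(rng.integers(100, 600, 50))
        ]
        kept, removed = qc.filter_by_size(contigs)
        assert sorted(c.name for c in kept + removed) == sorted(c.name for c in contigs)
        assert not removed or max(c.length for c in removed) < 301


# ---------------------------------------------------------------------------
# contaminant filter
# ---------------------------------------------------------------------------


class TestContaminants:
    def _cluster(self, name, rng):
        ct = make_contig(*name.rsplit("_", 1), random_dna(rng, 400))
        return qc.SequenceCluster(name, ct, [ct])

    def test_rules(self, rng):
        clusters = [self._cluster(f"C_{i}", rng) for i in range(4)]
        hits = [
            qc.BlastLikeHit(clusters[0].representative.name, "non_primate", 1e-50),
            qc.BlastLikeHit(clusters[1].representative.name, "non_primate", 1e-50),
            qc.BlastLikeHit(clusters[1].representative.name, "primate", 1e-45),
            qc.BlastLikeHit(clusters[2].representative.name, "non_primate", 1e-30),
        ]
        clean, contaminant = qc.classify_contaminants(clusters, hits)
        assert [cl.cluster_id for cl in contaminant] == ["C_0"]
        # significant non-primate + significant primate -> clean;
        # non-significant non-primate -> clean; no hits at all -> clean
        assert [cl.cluster_id for cl in clean] == ["C_1", "C_2", "C_3"]

    def test_evalue_must_be_positive(self):
        with pytest.raises(ValueError):
            qc.BlastLikeHit("x", "primate", 0.0)


# ---------------------------------------------------------------------------
# pairwise identity / coverage
# ---------------------------------------------------------------------------


class TestPairwise:
    def test_identical(self, rng):
        s = random_dna(rng, 500)
        assert qc.pairwise_identity_coverage(s, s) == (1.0, 1.0, 1.0)

    def test_single_mismatch_in_100(self, rng):
        a = random_dna(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        ident, cov_s, cov_l = qc.pairwise_identity_coverage(a, b)
        assert ident == pytest.approx(0.99)
        assert cov_s == cov_l == 1.0

    def test_reverse_complement(self, rng):
        a = random_dna(rng, 300)
        assert qc.pairwise_identity_coverage(a, revcomp(a)) == (1.0, 1.0, 1.0)

    def test_fragment_coverage(self, rng):
        a = random_dna(rng, 1000)
        ident, cov_s, cov_l = qc.pairwise_identity_coverage(a[:600], a)
        assert ident == 1.0
        assert cov_s == 1.0
        assert cov_l == pytest.approx(0.6)

    def test_random_pair_far_below_threshold(self, rng):
        a, b = random_dna(rng, 1000), random_dna(rng, 1000)
        ident, cov_s, cov_l = qc.pairwise_identity_coverage(a, b)
        assert ident < 0.95 or cov_s < 0.9 or cov_l < 0.9
        assert not qc.satisfies_join(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            qc.pairwise_identity_coverage("", "ACGT")


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------


class TestGreedyCluster:
    def test_three_identical_contigs_one_cluster(self, rng):
        s = random_dna(rng, 800)
        contigs = [make_contig(f"I{i}", 1, s) for i in range(3)]
        clusters = qc.greedy_cluster(contigs)
        assert len(clusters) == 1
        assert len(clusters[0].individuals) == 3
        summary = qc.allele_frequencies(clusters, 10)
        assert clusters[0].allele_frequency == pytest.approx(0.3)
        assert summary["n_clusters"] == 1

    def test_unrelated_sequences_stay_apart(self, rng):
        contigs = [make_contig("A", 1, random_dna(rng, 1000)),
                   make_contig("B", 1, random_dna(rng, 1000))]
        assert len(qc.greedy_cluster(contigs)) == 2

    def test_representative_is_longest_member(self, rng):
        s = random_dna(rng, 1000)
        contigs = [
            make_contig("A", 1, s),
            make_contig("B", 1, mutate(s, 0.005, np.random.default_rng(0))[:950]),
        ]
        (cl,) = qc.greedy_cluster(contigs)
        assert cl.representative.length == max(m.length for m in cl.members)

    def test_planted_mixture_matches_bruteforce_oracle(self, rng):
        # families of mutated copies + unrelated singletons + fragments
        contigs = []
        for f in range(12):
            base = random_dna(rng, int(rng.integers(400, 1500)))
            for i in range(int(rng.integers(1, 5))):
                seq = mutate(base, 0.01, rng)
                if rng.random() < 0.3:
                    seq = revcomp(seq)
                if rng.random() < 0.2 and len(seq) > 700:
                    seq = seq[: int(rng.integers(310, len(seq) - 310))]
                contigs.append(make_contig(f"I{i}", f * 10 + i, seq))
        for j in range(15):
            contigs.append(make_contig("X", j, random_dna(rng, int(rng.integers(301, 2000)))))
        assert partition(qc.greedy_cluster(contigs)) == oracle_greedy(contigs)

    def test_input_order_invariance(self, rng):
        contigs = []
        for f in range(8):
            base = random_dna(rng, 600)
            for i in range(3):
                contigs.append(make_contig(f"I{i}", f * 10 + i, mutate(base, 0.01, rng)))
        p1 = partition(qc.greedy_cluster(contigs))
        p2 = partition(qc.greedy_cluster(list(reversed(contigs))))
        assert p1 == p2


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


class TestAlleleFrequencies:
    def _clusters(self, member_inds, rng):
        s = random_dna(rng, 400)
        out = []
        for i, inds in enumerate(member_inds):
            members = [make_contig(ind, f"{i}{j}", s) for j, ind in enumerate(inds)]
            out.append(qc.SequenceCluster(f"c{i}", members[0], members))
        return out

    def test_distinct_individuals_counted_once(self, rng):
        clusters = self._clusters([["A", "B", "A"]], rng)
        summary = qc.allele_frequencies(clusters, 100)
        assert clusters[0].allele_frequency == pytest.approx(0.02)
        assert summary["fraction_rare"] == 1.0

    def test_full_cohort_af_one(self, rng):
        clusters = self._clusters([[f"I{i}" for i in range(10)]], rng)
        qc.allele_frequencies(clusters, 10)
        assert clusters[0].allele_frequency == 1.0

    def test_too_many_individuals_rejected(self, rng):
        clusters = self._clusters([["A", "B", "C"]], rng)
        with pytest.raises(ValueError):
            qc.allele_frequencies(clusters, 2)
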