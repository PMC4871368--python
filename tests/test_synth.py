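"""Ground-truth properties of the synthetic two-taxon generator."""

import numpy as np
import pytest

from hybridtest.config import ConfigurationError, SimulationConfig
from hybridtest.synth import (
    containment_relations,
    derive_maternal,
    emit_consensus_transcripts,
    emit_redundant_contigs,
    make_hybrid,
    simulate_parent,
    simulate_reads,
)
from hybridtest._util import revcomp


def _flat_config(**kw):
    defaults = dict(n_loci=5, locus_length_mean=600, locus_length_sd=0, seed=11)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateParent:
    def test_zero_heterozygosity_gives_identical_haplotypes(self):
        loci = simulate_parent(_flat_config(parent_heterozygosity=0.0))
        for locus in loci:
            assert locus.haplotypes[0] == locus.haplotypes[1]
            assert locus.truth_table == []

    def test_heterozygous_site_count_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            n_loci=100, locus_length_mean=1000, locus_length_sd=0,
            parent_heterozygosity=0.002, seed=3,
        )
        loci = simulate_parent(cfg)
        total = sum(len(l.truth_table) for l in loci)
        n = 100 * 1000
        expected = n * 0.002
        sd = np.sqrt(n * 0.002 * 0.998)
        assert abs(total - expected) <= 3 * sd

    def test_truth_table_fraction_is_half_for_diploid(self):
        loci = simulate_parent(_flat_config(parent_heterozygosity=0.05))
        sites = [s for l in loci for s in l.truth_table]
        assert sites and all(s.expected_fraction == 0.5 for s in sites)

    def test_same_seed_reproduces_identical_haplotypes(self):
        cfg = _flat_config(parent_heterozygosity=0.01)
        a, b = simulate_parent(cfg), simulate_parent(cfg)
        assert [l.haplotypes for l in a] == [l.haplotypes for l in b]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_loci=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(parent_heterozygosity=0.7)
        with pytest.raises(ConfigurationError):
            SimulationConfig(hybrid_composition=(1, 0))


class TestDeriveMaternal:
    def test_zero_divergence_is_identity(self):
        loci = simulate_parent(_flat_config())
        maternal = derive_maternal(loci, 0.0, seed=1)
        for locus in loci:
            assert maternal[locus.locus_id] == locus.haplotypes[0]

    def test_divergent_site_count_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            n_loci=1, locus_length_mean=2500, locus_length_sd=0,
            parent_heterozygosity=0.0, seed=5,
        )
        loci = simulate_parent(cfg)
        maternal = derive_maternal(loci, 0.02, seed=5)
        diffs = sum(
            a != b for a, b in zip(loci[0].haplotypes[0], maternal[loci[0].locus_id])
        )
        expected, sd = 2500 * 0.02, np.sqrt(2500 * 0.02 * 0.98)
        assert abs(diffs - expected) <= 3 * sd

    def test_substitutions_never_restore_original_base(self):
        loci = simulate_parent(_flat_config(parent_heterozygosity=0.0))
        maternal = derive_maternal(loci, 0.3, seed=2)
        for locus in loci:
            pat, mat = locus.haplotypes[0], maternal[locus.locus_id]
            # every recorded difference really differs (substitution is a change)
            assert sum(a == b for a, b in zip(pat, mat)) < len(pat)

    def test_out_of_range_divergence_rejected(self):
        loci = simulate_parent(_flat_config())
        with pytest.raises(ConfigurationError):
            derive_maternal(loci, 0.9, seed=1)


class TestMakeHybrid:
    def _parent_and_maternal(self, h=0.01, d=0.05):
        cfg = _flat_config(parent_heterozygosity=h)
        loci = simulate_parent(cfg)
        return loci, derive_maternal(loci, d, seed=9)

    def test_one_two_composition_gives_one_third_minor_fraction(self):
        loci, maternal = self._parent_and_maternal(h=0.0)
        hyb = make_hybrid(loci[0], maternal[loci[0].locus_id], (1, 2))
        assert hyb.truth_table
        for site in hyb.truth_table:
            assert site.expected_fraction == pytest.approx(1 / 3)
            assert site.minor_copies == (0,)  # the paternal copy is minor

    def test_autopolyploid_varies_only_at_parental_het_sites(self):
        loci, maternal = self._parent_and_maternal(h=0.02, d=0.05)
        locus = loci[0]
        hyb = make_hybrid(locus, maternal[locus.locus_id], (3, 0))
        het_positions = {s.position for s in locus.truth_table}
        assert {s.position for s in hyb.truth_table} == het_positions
        for site in hyb.truth_table:
            assert site.expected_fraction == pytest.approx(1 / 3)

    def test_two_one_composition_minor_allele_is_maternal(self):
        loci, maternal = self._parent_and_maternal(h=0.0)
        locus = loci[0]
        hyb = make_hybrid(locus, maternal[locus.locus_id], (2, 1))
        for site in hyb.truth_table:
            assert site.expected_fraction == pytest.approx(1 / 3)
            assert site.minor_copies == (2,)  # the single maternal copy

    def test_composition_below_diploid_rejected(self):
        loci, maternal = self._parent_and_maternal()
        with pytest.raises(ConfigurationError):
            make_hybrid(loci[0], maternal[loci[0].locus_id], (1, 0))


class TestConsensus:
    def test_diploid_het_tie_resolves_to_paternal_base(self):
        loci = simulate_parent(_flat_config(parent_heterozygosity=0.05))
        consensus = emit_consensus_transcripts(loci)
        for locus in loci:
            cons = consensus[locus.locus_id]
            assert len(cons) == locus.length
            for site in locus.truth_table:
                assert cons[site.position - 1] == locus.haplotypes[0][site.position - 1]

    def test_triploid_difference_site_written_with_majority_maternal_base(self):
        loci = simulate_parent(_flat_config(parent_heterozygosity=0.0))
        maternal = derive_maternal(loci, 0.05, seed=4)
        hyb = [make_hybrid(l, maternal[l.locus_id], (1, 2)) for l in loci]
        consensus = emit_consensus_transcripts(hyb)
        for locus in hyb:
            cons = consensus[locus.locus_id]
            for site in locus.truth_table:
                assert cons[site.position - 1] == site.major_base
                assert site.major_base == locus.haplotypes[1][site.position - 1]

    def test_homozygous_sites_pass_through(self):
        loci = simulate_parent(_flat_config(parent_heterozygosity=0.0))
        consensus = emit_consensus_transcripts(loci)
        for locus in loci:
            assert consensus[locus.locus_id] == locus.haplotypes[0]


class TestRedundantContigs:
    def test_single_fragment_equals_consensus(self):
        loci = simulate_parent(_flat_config())
        frags, _ = emit_redundant_contigs(loci, n_fragments=1, seed=1)
        consensus = emit_consensus_transcripts(loci)
        assert set(frags.values()) == set(consensus.values())

    def test_recorded_containments_verified_by_substring_oracle(self):
        loci = simulate_parent(_flat_config())
        frags, rels = emit_redundant_contigs(loci, n_fragments=6, seed=1)
        for inner, outer in rels:
            s, o = frags[inner], frags[outer]
            assert s in o or revcomp(s) in o
        # brute-force: no relation missed
        assert rels == containment_relations(frags)

    def test_guaranteed_contained_and_overlapping_pairs_per_locus(self):
        loci = simulate_parent(_flat_config())
        frags, rels = emit_redundant_contigs(loci, n_fragments=4, seed=2)
        for locus in loci:
            mine = {k: v for k, v in frags.items() if k.startswith(locus.locus_id)}
            ids = sorted(mine)
            contained = {(a, b) for a, b in rels if a in mine}
            assert contained, f"{locus.locus_id} has no contained pair"
            overlapping_not_contained = [
                (a, b)
                for i, a in enumerate(ids)
                for b in ids[i + 1 :]
                if (a, b) not in contained and (b, a) not in contained
                and _overlap(mine[a], mine[b])
            ]
            assert overlapping_not_contained

    def test_same_seed_identical_fragments(self):
        loci = simulate_parent(_flat_config())
        a, _ = emit_redundant_contigs(loci, n_fragments=5, seed=3)
        b, _ = emit_redundant_contigs(loci, n_fragments=5, seed=3)
        assert a == b


def _overlap(a: str, b: str, k: int = 30) -> bool:
    return any(a[i : i + k] in b for i in range(0, len(a) - k + 1, k))


class TestSimulateReads:
    def test_error_free_reads_are_exact_haplotype_substrings(self):
        cfg = _flat_config(error_rate=0.0, coverage=5.0, parent_heterozygosity=0.01)
        loci = simulate_parent(cfg)
        by_id = {l.locus_id: l for l in loci}
        reads = simulate_reads(loci, cfg)
        assert reads
        for read in reads:
            locus = by_id[read.read_id.split(":")[0]]
            assert any(
                read.sequence in h or revcomp(read.sequence) in h
                for h in locus.haplotypes
            )

    def test_read_count_matches_poisson_expectation(self):
        cfg = SimulationConfig(
            n_loci=1, locus_length_mean=2500, locus_length_sd=0,
            coverage=600, read_length=100, seed=13,
        )
        loci = simulate_parent(cfg)
        reads = simulate_reads(loci, cfg)
        expected = 600 * 2500 / 100
        assert abs(len(reads) - expected) <= 3 * np.sqrt(expected)

    def test_dosage_maps_to_read_fraction_at_deep_coverage(self):
        cfg = SimulationConfig(
            n_loci=1, locus_length_mean=600, locus_length_sd=0,
            parent_heterozygosity=0.0, maternal_divergence=0.02,
            coverage=2000, error_rate=0.0, seed=21,
        )
        loci = simulate_parent(cfg)
        maternal = derive_maternal(loci, cfg.maternal_divergence, cfg.seed)
        hyb = [make_hybrid(l, maternal[l.locus_id], (1, 2)) for l in loci]
        reads = simulate_reads(hyb, cfg)
        locus = hyb[0]
        for site in locus.truth_table[:10]:
            pos0 = site.position - 1
            spanning = minor = 0
            for read in reads:
                _, copy, start, *_ = read.read_id.split(":")
                start = int(start[1:])
                if start <= pos0 < start + cfg.read_length:
                    spanning += 1
                    if int(copy[1:]) in site.minor_copies:
                        minor += 1
            p = site.expected_fraction
            sd = np.sqrt(p * (1 - p) / spanning)
            assert abs(minor / spanning - p) <= 3 * sd

    def test_quality_string_encodes_error_rate(self):
        cfg = _flat_config(error_rate=0.002, coverage=1.0)
        loci = simulate_parent(cfg)
        reads = simulate_reads(loci, cfg)
        q = ord(reads[0].quality[0]) - 33
        assert 10 ** (-q / 10) == pytest.approx(0.002, rel=0.2)

    def test_byte_identical_fastq_under_same_seed(self, tmp_path):
        from hybridtest.io import write_fastq

        cfg = _flat_config(coverage=2.0)
        paths = []
        for name in ("a.fq", "b.fq"):
            loci = simulate_parent(cfg)
            reads = simulate_reads(loci, cfg)
            p = tmp_path / name
            write_fastq(reads, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
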