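"""Generator tests: determinism, class structure, and closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from herivome.simulate import (SimulationConfig, eve_identity_truth,
                               random_split_times, simulate_codiverging_loci,
                               simulate_eve, simulate_small_rna_library,
                               simulate_virus_genome)


class TestConfigValidation:
    def test_probabilities_must_be_in_unit_interval(self):
        with pytest.raises(ValueError, match="u1_prob"):
            SimulationConfig(u1_prob=1.2)

    def test_pirna_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(pirna_length_weights={24: 0.5, 25: 0.4})

    def test_motif_overlapping_duplication_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            SimulationConfig(eve_duplication=(100, 300),
                             conserved_motifs=[(150, 31)])

    def test_divergence_bounded(self):
        with pytest.raises(ValueError, match="eve_divergence"):
            SimulationConfig(eve_divergence=0.9)


class TestVirusGenome:
    def test_deterministic_given_seed(self, small_config):
        assert simulate_virus_genome(small_config) == \
            simulate_virus_genome(small_config)

    def test_segment_count_and_length(self):
        cfg = SimulationConfig(seed=1, n_segments=3, genome_length=1000)
        contigs = simulate_virus_genome(cfg)
        assert len(contigs) == 3
        assert all(len(s) == 1000 for s in contigs.values())

    def test_short_genome_rejected(self):
        cfg = SimulationConfig(seed=1)
        cfg.genome_length = 0  # bypass __post_init__ to exercise the op check
        with pytest.raises(ValueError, match="genome_length"):
            simulate_virus_genome(cfg)


class TestEve:
    def test_zero_divergence_no_duplication_is_identity(self, small_config, rng):
        cfg = small_config.replace(eve_divergence=0.0, eve_duplication=None)
        virus = simulate_virus_genome(cfg)["virus_seg1"]
        eve, truth = simulate_eve(virus, cfg, rng)
        assert eve == virus
        identity, _ = eve_identity_truth(virus, eve, truth)
        assert identity == 100.0

    def test_duplication_extends_length_by_interval(self, small_config, rng):
        virus = simulate_virus_genome(small_config)["virus_seg1"]
        eve, truth = simulate_eve(virus, small_config, rng)
        d0, d1 = small_config.eve_duplication
        assert len(eve) == len(virus) + (d1 - d0)
        assert truth.duplication_eve == (d1, d1 + (d1 - d0))
        # tandem copy is byte-identical to its source in the EVE
        assert eve[d0:d1] == eve[d1:d1 + (d1 - d0)]

    def test_realized_identity_matches_divergence_and_motifs_conserved(self, rng):
        cfg = SimulationConfig(seed=3, genome_length=2000, eve_divergence=0.22,
                               eve_duplication=None,
                               conserved_motifs=[(100, 35)])
        virus = simulate_virus_genome(cfg)["virus_seg1"]
        eve, truth = simulate_eve(virus, cfg, rng)
        # position-wise oracle: identity outside motifs ~ 78%
        outside = [i for i in range(2000) if not 100 <= i < 135]
        mism = sum(virus[i] != eve[i] for i in outside)
        p_hat = mism / len(outside)
        assert abs(p_hat - 0.22) < 3 * np.sqrt(0.22 * 0.78 / len(outside))
        assert virus[100:135] == eve[100:135]

    def test_motif_outside_contig_rejected(self, small_config, rng):
        cfg = small_config.replace(conserved_motifs=[(990, 39)],
                                   eve_duplication=None)
        virus = simulate_virus_genome(cfg)["virus_seg1"]
        with pytest.raises(ValueError, match="motif"):
            simulate_eve(virus, cfg, rng)


class TestSmallRnaLibrary:
    def test_sirna_only_library_is_all_21mers(self, small_config):
        cfg = small_config.replace(sirna_fraction_21=1.0)
        contigs = simulate_virus_genome(cfg)
        reads, truth = simulate_small_rna_library(contigs, cfg)
        assert all(len(seq) == 21 for _, seq in reads)
        assert set(truth.cls) == {"siRNA"}

    def test_u1_prob_one_forces_antisense_u1(self, small_config):
        cfg = small_config.replace(sirna_fraction_21=0.0, u1_prob=1.0)
        contigs = simulate_virus_genome(cfg)
        reads, truth = simulate_small_rna_library(contigs, cfg)
        seqs = dict(reads)
        anti = truth[truth.strand == "antisense"]
        assert len(anti) > 0
        assert all(seqs[r].startswith("T") for r in anti.read_id)

    def test_u1_frequency_within_binomial_ci(self):
        cfg = SimulationConfig(seed=5, n_segments=1, genome_length=1000,
                               reads_per_contig=10000, sirna_fraction_21=0.0,
                               u1_prob=0.8)
        contigs = simulate_virus_genome(cfg)
        reads, truth = simulate_small_rna_library(contigs, cfg)
        seqs = dict(reads)
        anti = truth[truth.strand == "antisense"].read_id
        freq = np.mean([seqs[r][0] == "T" for r in anti])
        assert abs(freq - 0.8) < 3 * np.sqrt(0.8 * 0.2 / len(anti))

    def test_truth_table_conserves_reads(self, small_config):
        contigs = simulate_virus_genome(small_config)
        reads, truth = simulate_small_rna_library(contigs, small_config)
        assert len(truth) == len(reads)
        assert sorted(truth.read_id) == sorted(r for r, _ in reads)
        assert truth.read_id.is_unique

    def test_pirna_lengths_follow_configured_weights(self):
        cfg = SimulationConfig(seed=6, n_segments=1, genome_length=1000,
                               reads_per_contig=50000, sirna_fraction_21=0.0)
        contigs = simulate_virus_genome(cfg)
        _, truth = simulate_small_rna_library(contigs, cfg)
        observed = truth.length.value_counts().sort_index()
        lengths = sorted(cfg.pirna_length_weights)
        expected = np.array([cfg.pirna_length_weights[k] for k in lengths]) * len(truth)
        chi = stats.chisquare(observed.reindex(lengths, fill_value=0), expected)
        assert chi.pvalue > 0.001

    def test_empty_contig_set_rejected(self, small_config):
        with pytest.raises(ValueError, match="empty"):
            simulate_small_rna_library({}, small_config)

    def test_same_seed_reproduces_library(self, small_config):
        contigs = simulate_virus_genome(small_config)
        first = simulate_small_rna_library(contigs, small_config)
        second = simulate_small_rna_library(contigs, small_config)
        assert first[0] == second[0]
        assert first[1].equals(second[1])


class TestCodivergingLoci:
    def test_divergence_matches_clock_expectation(self):
        # two populations split 0.407 My at 3.54%/My: expected p-distance
        # 2 x 0.407 x 0.0354 ~ 2.88% on a 10 kb locus
        cfg = SimulationConfig(seed=8, n_populations=2,
                               split_times={("pop1", "pop2"): 0.407},
                               host_locus_length=10000)
        codiv = simulate_codiverging_loci(cfg)
        a, b = codiv.host_alignment["pop1"], codiv.host_alignment["pop2"]
        p_hat = np.mean([x != y for x, y in zip(a, b)])
        expected = 2 * 0.407 * 0.0354
        assert abs(p_hat - expected) < 3 * np.sqrt(expected * (1 - expected) / 10000)

    def test_zero_split_time_gives_identical_sequences(self):
        cfg = SimulationConfig(seed=9, n_populations=2,
                               split_times={("pop1", "pop2"): 0.0})
        codiv = simulate_codiverging_loci(cfg)
        assert codiv.host_alignment["pop1"] == codiv.host_alignment["pop2"]

    def test_same_seed_reproduces_alignments(self, small_config):
        first = simulate_codiverging_loci(small_config)
        second = simulate_codiverging_loci(small_config)
        assert first.host_alignment == second.host_alignment
        assert first.tree_newick == second.tree_newick

    def test_inconsistent_split_times_rejected(self):
        times = {("pop1", "pop2"): 0.1, ("pop1", "pop3"): 0.5,
                 ("pop2", "pop3"): 0.3}  # violates ultrametric three-point rule
        cfg = SimulationConfig(seed=1, n_populations=3, split_times=times)
        with pytest.raises(ValueError, match="inconsistent"):
            simulate_codiverging_loci(cfg)

    def test_random_split_times_are_ultrametric(self, rng):
        pops = [f"pop{i}" for i in range(1, 7)]
        times = random_split_times(pops, 0.8, rng)
        cfg = SimulationConfig(seed=2, n_populations=6, split_times=times)
        codiv = simulate_codiverging_loci(cfg)  # builds without inconsistency
        assert set(codiv.host_alignment) == set(pops)
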