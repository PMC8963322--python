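"""Distance matrices, neighbor joining, congruence, clock dating, and
prevalence arithmetic."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from herivome.phylo import (DistanceMatrix, clock_date, congruence, nj_tree,
                            p_distance_matrix, prevalence)
from herivome.simulate import (SimulationConfig, random_split_times,
                               simulate_codiverging_loci)


class TestPDistance:
    def test_identical_pair_zero(self):
        dm = p_distance_matrix({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        assert dm.get("a", "b") == 0.0

    def test_three_of_ten_differ(self):
        dm = p_distance_matrix({"a": "AAAAAAAAAA", "b": "CCCAAAAAAA"})
        assert dm.get("a", "b") == pytest.approx(0.3)

    def test_gaps_and_n_excluded_pairwise(self):
        dm = p_distance_matrix({"a": "ACGT-CGTAN", "b": "ACGTACGTAA"})
        # comparable columns: 8 (gap and N dropped), 0 mismatches
        assert dm.get("a", "b") == 0.0

    def test_no_comparable_columns_flagged(self):
        dm = p_distance_matrix({"a": "----", "b": "ACGT", "c": "ACGT"})
        assert np.isnan(dm.get("a", "b"))
        assert dm.has_missing

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            p_distance_matrix({"a": "ACGT", "b": "ACGTAC"})

    @given(st.integers(0, 5000))
    def test_triangle_inequality_on_gap_free_triples(self, seed):
        rng = np.random.default_rng(seed)
        seqs = {t: "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
                for t in "abc"}
        dm = p_distance_matrix(seqs)
        assert dm.get("a", "c") <= dm.get("a", "b") + dm.get("b", "c") + 1e-12


def random_binary_tree(taxa, rng):
    """Random topology with positive branch lengths; returns (newick, dm)."""
    nodes = [(t, 0.0, {t: 0.0}) for t in taxa]  # (newick, _, leaf depths)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (na, _, da), (nb, _, db) = nodes[i], nodes[j]
        ba, bb = rng.uniform(0.05, 1.0, 2)
        merged_depths = {t: d + ba for t, d in da.items()}
        merged_depths.update({t: d + bb for t, d in db.items()})
        merged = (f"({na}:{ba:.6f},{nb}:{bb:.6f})", 0.0, merged_depths)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = pdm.patristic_distance(lookup[taxa[a]], lookup[taxa[b]])
            values[a, b] = values[b, a] = d
    return newick, DistanceMatrix(list(taxa), values)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered(self):
        # additive distances from ((a:2,b:3):1,(c:4,d:5)) with internal 1
        taxa = ["a", "b", "c", "d"]
        values = np.array([[0, 5, 7, 8],
                           [5, 0, 8, 9],
                           [7, 8, 0, 9],
                           [8, 9, 0, 0]], dtype=float)
        values[2, 3] = values[3, 2] = 9.0
        nwk = nj_tree(DistanceMatrix(taxa, values))
        res = congruence(nwk, "((a:2,b:3):1,(c:4,d:5):0);", n_permutations=10)
        assert res.rf == 0

    def test_roundtrip_random_binary_trees(self):
        rng = np.random.default_rng(1234)
        for n_taxa in (5, 8, 12):
            taxa = [f"t{i}" for i in range(n_taxa)]
            newick, dm = random_binary_tree(taxa, rng)
            res = congruence(nj_tree(dm), newick, n_permutations=10)
            assert res.rf == 0

    def test_three_taxa_closed_form_branch_lengths(self):
        values = np.array([[0.0, 0.3, 0.5],
                           [0.3, 0.0, 0.6],
                           [0.5, 0.6, 0.0]])
        nwk = nj_tree(DistanceMatrix(["a", "b", "c"], values))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        edge = {leaf.taxon.label: leaf.edge.length
                for leaf in tree.leaf_node_iter()}
        # x = (d_ab + d_ac - d_bc)/2 etc.
        assert edge["a"] == pytest.approx(0.1, abs=1e-9)
        assert edge["b"] == pytest.approx(0.2, abs=1e-9)
        assert edge["c"] == pytest.approx(0.4, abs=1e-9)

    def test_missing_entries_rejected(self):
        values = np.array([[0, np.nan, 1.0],
                           [np.nan, 0, 1.0],
                           [1.0, 1.0, 0]])
        with pytest.raises(ValueError, match="missing"):
            nj_tree(DistanceMatrix(["a", "b", "c"], values))


class TestCongruence:
    def test_identical_trees(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1);"
        res = congruence(nwk, nwk, n_permutations=99)
        assert res.rf == 0 and res.normalized_rf == 0.0

    def test_conflicting_four_taxon_split(self):
        res = congruence("((a:1,b:1):1,(c:1,d:1):1);",
                         "((a:1,c:1):1,(b:1,d:1):1);", n_permutations=99)
        assert res.normalized_rf == 1.0

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            congruence("((a:1,b:1):1,c:1);", "((a:1,b:1):1,d:1);")

    def test_cospeciation_vs_independent_evolution(self):
        pops = [f"pop{i + 1}" for i in range(8)]
        rng = np.random.default_rng(55)
        times = random_split_times(pops, 0.8, rng)
        cfg = SimulationConfig(seed=56, n_populations=8, split_times=times,
                               host_locus_length=4000, virus_locus_length=4000)
        codiv = simulate_codiverging_loci(cfg)
        hdm = p_distance_matrix(codiv.host_alignment)
        vdm = p_distance_matrix(codiv.virus_alignment)
        res = congruence(nj_tree(hdm), nj_tree(vdm), host_dm=hdm,
                         virus_dm=vdm, n_permutations=999, seed=5)
        assert res.rf == 0
        assert res.p_value <= 0.01

        # independent virus tree: topology decoupled from the host
        other = random_split_times(pops, 0.8, np.random.default_rng(77))
        indep = simulate_codiverging_loci(cfg, virus_split_times=other)
        idm = p_distance_matrix(indep.virus_alignment)
        res2 = congruence(nj_tree(hdm), nj_tree(idm), host_dm=hdm,
                          virus_dm=idm, n_permutations=999, seed=5)
        assert res2.normalized_rf > 0


class TestClock:
    def test_published_continental_anchor(self):
        est = clock_date(0.0288, 0.0354)
        assert est.tmrca_years == pytest.approx(813559.32, abs=1.0)
        assert est.tmrca_rounded == 800000

    def test_zero_divergence(self):
        assert clock_date(0.0, 0.0354).tmrca_years == 0.0

    def test_rate_equal_divergence_is_one_my(self):
        assert clock_date(0.0354, 0.0354).tmrca_years == pytest.approx(1e6)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            clock_date(0.03, 0.0)

    def test_linearity_over_grid(self):
        for d in (0.01, 0.02, 0.04):
            for r in (0.01, 0.035, 0.08):
                est = clock_date(d, r)
                assert est.tmrca_years == pytest.approx(d / r * 1e6)


class TestPrevalence:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["population", "n_screened",
                                           "n_positive"])

    def test_overall_arithmetic(self):
        res = prevalence(self._table([("x", 10, 2), ("y", 10, 1)]))
        assert res.overall_pct == 15.0

    def test_continental_bracketing(self):
        assert prevalence(self._table([("all", 353, 39)])).overall_pct == 11.0
        assert prevalence(self._table([("all", 353, 40)])).overall_pct == 11.3

    def test_zero_positive_exact_ci(self):
        res = prevalence(self._table([("x", 100, 0)]))
        row = res.per_population.iloc[0]
        assert row.pct == 0.0
        assert row.ci_low_pct == 0.0
        assert row.ci_high_pct == pytest.approx(3.6, abs=0.05)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="n_positive"):
            prevalence(self._table([("x", 10, 11)]))
        with pytest.raises(ValueError, match="n_screened"):
            prevalence(self._table([("x", 0, 0)]))
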