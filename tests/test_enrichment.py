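"""Pooling, Hamming clustering and enrichment estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagescreen import (
    CountTable,
    HammingDBSCAN,
    SamplePair,
    assign_enrichment,
    cluster_peptides,
    compare_cluster_vs_direct,
    compare_replicates,
    enrich_pair,
    hamming_distance,
    pool_replicates,
)
from phagescreen.enrichment import PeptideCluster, cluster_enrichment, odr_line

from conftest import make_pair, make_table


class TestPooling:
    def test_pool_with_self_doubles(self):
        t = make_table({"AA": 3, "CC": 5})
        pooled = pool_replicates([t, t])
        assert pooled.counts == {"AA": 6, "CC": 10}
        assert pooled.total_reads_in == 2 * t.total_reads_in
        assert pooled.replicate == "pooled"

    def test_pool_with_empty_is_identity(self):
        t = make_table({"AA": 3})
        empty = make_table({})
        assert pool_replicates([t, empty]).counts == t.counts

    def test_pooled_frequency_between_replicates(self):
        t1 = make_table({"AA": 10, "CC": 90})
        t2 = make_table({"AA": 40, "CC": 60})
        pooled = pool_replicates([t1, t2])
        f1, f2 = 0.10, 0.40
        f = pooled.frequencies()["AA"]
        assert min(f1, f2) <= f <= max(f1, f2)

    def test_mixed_condition_errors(self):
        t1 = make_table({"AA": 1}, condition="competitor")
        t2 = make_table({"AA": 1}, condition="non-competitor")
        with pytest.raises(ValueError, match="mixed"):
            pool_replicates([t1, t2])


class TestHammingDistance:
    def test_basic_cases(self):
        assert hamming_distance("ACDE", "ACDE") == 0
        assert hamming_distance("ACDE", "ACDF") == 1
        with pytest.raises(ValueError):
            hamming_distance("ACDE", "ACD")

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(200):
            a = "".join(rng.choice(letters, 12))
            b = "".join(rng.choice(letters, 12))
            expected = sum(1 for x, y in zip(a, b) if x != y)
            assert hamming_distance(a, b) == expected

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_metric_properties(self, data):
        seqs = st.text(alphabet="ACDE", min_size=6, max_size=6)
        a, b = data.draw(seqs), data.draw(seqs)
        assert hamming_distance(a, b) == hamming_distance(b, a)
        assert (hamming_distance(a, b) == 0) == (a == b)


class TestClustering:
    def test_chain_is_one_cluster(self):
        # d(A,B)=d(B,C)=1 but d(A,C)=2: density-reachable through B
        peptides = ["AAAA", "AAAC", "AACC"]
        clusters = cluster_peptides(peptides, eps=1)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(peptides)

    def test_isolated_peptide_is_singleton(self):
        clusters = cluster_peptides(["AAAA", "CCCC"], eps=1)
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def _components_oracle(self, peptides, eps):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(peptides)
        for i, a in enumerate(peptides):
            for b in peptides[i + 1:]:
                if hamming_distance(a, b) <= eps:
                    g.add_edge(a, b)
        return {frozenset(c) for c in nx.connected_components(g)}

    @pytest.mark.parametrize("eps", [1, 2])
    def test_partition_equals_graph_components(self, eps):
        rng = np.random.default_rng(42)
        letters = np.array(list("ACDE"))
        peptides = sorted({"".join(rng.choice(letters, 6)) for _ in range(150)})
        clusters = cluster_peptides(peptides, eps=eps, min_pts=2)
        assert {frozenset(c.members) for c in clusters} == self._components_oracle(
            peptides, eps
        )

    def test_labels_align_with_input_order(self):
        peptides = ["CCCC", "AAAA", "AAAC"]
        model = HammingDBSCAN().fit(peptides)
        assert model.labels_[1] == model.labels_[2] != model.labels_[0]

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="duplicate"):
            HammingDBSCAN().fit(["AAAA", "AAAA"])
        with pytest.raises(ValueError, match="equal length"):
            cluster_peptides(["AAAA", "AAA"])


class TestClusterEnrichment:
    def test_direct_arithmetic(self):
        """Equal depths, summed counts 15 vs 5 -> E = ln(1/3)."""
        pair = make_pair(
            noncomp={"AAAA": 15, "WWWW": 85},
            comp={"AAAA": 5, "WWWW": 95},
        )
        cl = PeptideCluster(id=0, members=frozenset({"AAAA"}))
        e = cluster_enrichment(cl, pair, pseudocount=0.0)
        assert e == pytest.approx(math.log(1 / 3))

    def test_equal_frequencies_zero(self):
        pair = make_pair({"AAAA": 10, "CCCC": 90}, {"AAAA": 10, "CCCC": 90})
        cl = PeptideCluster(id=0, members=frozenset({"AAAA"}))
        assert cluster_enrichment(cl, pair, pseudocount=0.0) == pytest.approx(0.0)

    def test_competitor_zero_is_negative_finite(self):
        pair = make_pair({"AAAA": 50, "CCCC": 50}, {"CCCC": 100})
        cl = PeptideCluster(id=0, members=frozenset({"AAAA"}))
        e = cluster_enrichment(cl, pair, pseudocount=0.5)
        assert e < -3 and np.isfinite(e)

    def test_unobserved_cluster_errors(self):
        pair = make_pair({"CCCC": 10}, {"CCCC": 10})
        cl = PeptideCluster(id=0, members=frozenset({"AAAA"}))
        with pytest.raises(ValueError, match="not observed"):
            cluster_enrichment(cl, pair)


class TestAssignEnrichment:
    def test_members_inherit_and_cover_union(self):
        pair = make_pair(
            {"AAAA": 30, "AAAC": 10, "GGGG": 20},
            {"AAAA": 5, "GGGG": 40, "WWWW": 15},
        )
        table = enrich_pair(pair)
        assert set(table["peptide"]) == set(pair.peptides)
        fam = table[table["peptide"].isin(["AAAA", "AAAC"])]
        assert fam["E"].nunique() == 1 and fam["cluster"].nunique() == 1

    def test_singleton_equals_direct_ratio(self):
        pair = make_pair({"AAAA": 20, "WWWW": 80}, {"AAAA": 10, "WWWW": 90})
        table = enrich_pair(pair, pseudocount=0.0)
        expected = math.log(10 / 100) - math.log(20 / 100)
        got = table.loc[table["peptide"] == "AAAA", "E"].iloc[0]
        assert got == pytest.approx(expected)


class TestClusterVsDirect:
    def test_all_singletons_identity(self):
        rng = np.random.default_rng(3)
        # mutually distant peptides -> every cluster is a singleton
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peps = ["".join(rng.choice(letters, 12)) for _ in range(30)]
        nc = {p: int(c) for p, c in zip(peps, rng.integers(10, 100, 30))}
        cc = {p: int(c) for p, c in zip(peps, rng.integers(10, 100, 30))}
        pair = make_pair(nc, cc)
        table = enrich_pair(pair, pseudocount=0.0)
        result = compare_cluster_vs_direct(pair, table, pseudocount=0.0)
        assert result["slope"] == pytest.approx(1.0)
        assert result["r2"] == pytest.approx(1.0)

    def test_planted_families_high_agreement(self, planted_pooled_pair):
        """Cluster-estimated E explains nearly all direct-E variation."""
        table = enrich_pair(planted_pooled_pair)
        result = compare_cluster_vs_direct(planted_pooled_pair, table)
        assert result["r2"] > 0.9
        assert result["n"] > 1000

    def test_too_few_peptides_errors(self):
        pair = make_pair({"AAAA": 10}, {"AAAA": 10})
        table = enrich_pair(pair)
        with pytest.raises(ValueError, match="at least 3"):
            compare_cluster_vs_direct(pair, table)


class TestCompareReplicates:
    def _table(self, peptides, e_values):
        import pandas as pd

        return pd.DataFrame({"peptide": peptides, "E": e_values})

    def test_identical_replicates_perfect(self):
        peps = [f"p{i}" for i in range(50)]
        e = np.linspace(-6, 1, 50)
        result = compare_replicates(self._table(peps, e), self._table(peps, e),
                                    region_cutoff=-1.5)
        assert result["slope"] == pytest.approx(1.0)
        assert result["r2_region"] == pytest.approx(1.0)

    def test_axis_exchange_inverts_slope(self):
        rng = np.random.default_rng(7)
        peps = [f"p{i}" for i in range(200)]
        base = rng.normal(-4, 1.5, 200)
        t1 = self._table(peps, base + rng.normal(0, 0.3, 200))
        t2 = self._table(peps, 0.8 * base + rng.normal(0, 0.3, 200))
        a = compare_replicates(t1, t2, region_cutoff=-1.5)
        b = compare_replicates(t2, t1, region_cutoff=-1.5)
        assert a["slope"] == pytest.approx(1 / b["slope"], rel=1e-9)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(8)
        peps = [f"p{i}" for i in range(4000)]
        t1 = self._table(peps, rng.normal(-2, 0.6, 4000))
        t2 = self._table(peps, rng.normal(-2, 0.6, 4000))
        result = compare_replicates(t1, t2, region_cutoff=-1.5)
        assert result["n_region"] > 1000
        assert result["r2_region"] < 0.1

    def test_odr_slope_is_principal_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept = odr_line(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)


class TestEstimatorErrorShrinksWithDepth:
    def test_error_spread_decreases_with_depth(self):
        """Assigned E approaches planted family E as sequencing deepens.

        Renormalizing the competitor frequencies shifts every E by one
        global constant, so the estimator-noise measure is the spread of
        the residuals about their median, not the raw absolute error.
        """
        from phagescreen import assign_truth, generate_library, simulate_counts

        library = generate_library(300, 2, seed=50)
        truth = assign_truth(library, (0.3, -2.0, 1.5), seed=51)
        truth_e = truth.set_index("peptide")["true_E"]
        spreads = []
        for depth in (10**4, 10**5, 10**6):
            tables = simulate_counts(truth, depth, n_replicates=1, seed=52)
            pair = SamplePair(
                noncomp=tables["non-competitor"][0], comp=tables["competitor"][0]
            )
            table = enrich_pair(pair)
            merged = table.set_index("peptide").join(truth_e, how="inner")
            resid = merged["E"] - merged["true_E"]
            spreads.append((resid - resid.median()).abs().median())
        assert spreads[0] > spreads[1] > spreads[2]
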