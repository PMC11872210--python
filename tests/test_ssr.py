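"""Genotype calling, Table-style frequency arithmetic, dissimilarity and
minimum spanning networks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from traitscape import (bin_alleles, call_multilocus_genotypes,
                        dissimilarity_matrix, frequency_table,
                        minimum_spanning_network)
from traitscape.ssr import locus_columns, round_half_up


def _ssr_frame(rows, loci=("L1", "L2")):
    """rows: list of (sample_id, cytotype, {locus: iterable of sizes})."""
    records = []
    for sid, cyto, sets in rows:
        rec = {"sample_id": sid, "cytotype": cyto, "origin": ""}
        for locus in loci:
            rec[locus] = "/".join(str(a) for a in sorted(sets.get(locus, ())))
        records.append(rec)
    return pd.DataFrame.from_records(records)


class TestBinning:
    def test_close_sizes_collapse_to_one_allele(self):
        df = _ssr_frame([("a", "hybrid", {"L1": [249.6]}),
                         ("b", "hybrid", {"L1": [250.2]})], loci=("L1",))
        out = bin_alleles(df, bin_width=1)
        assert set(out["L1"]) == {"250"}

    def test_exclusions_removed_everywhere(self):
        df = _ssr_frame([("a", "hybrid", {"L1": [242, 250]}),
                         ("b", "hybrid", {"L1": [242]})], loci=("L1",))
        out = bin_alleles(df, exclusions=[("L1", 242)])
        assert list(out["L1"]) == ["250", ""]

    def test_integer_sizes_identity(self, reference_population):
        out = bin_alleles(reference_population, bin_width=1)
        for locus in locus_columns(reference_population):
            assert list(out[locus]) == list(reference_population[locus])

    def test_negative_sizes_rejected(self):
        df = _ssr_frame([("a", "hybrid", {"L1": [-5]})], loci=("L1",))
        with pytest.raises(ValueError):
            bin_alleles(df)


class TestGenotypeCalling:
    def test_matches_bruteforce_equality_partition(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            rows = []
            for i in range(5):
                sets = {locus: set(rng.choice([100, 104, 108], size=rng.integers(1, 3),
                                              replace=False).tolist())
                        for locus in ("L1", "L2")}
                rows.append((f"s{i}", "hybrid", sets))
            df = _ssr_frame(rows)
            gt = call_multilocus_genotypes(df)
            # oracle: all-pairs equality of the parsed allele sets
            parsed = [{locus: frozenset(sets[locus]) for locus in ("L1", "L2")}
                      for _, _, sets in rows]
            for i, j in itertools.combinations(range(5), 2):
                same = parsed[i] == parsed[j]
                assert (gt.assignments.iloc[i] == gt.assignments.iloc[j]) == same

    def test_all_identical_single_label(self):
        df = _ssr_frame([(f"s{i}", "hybrid", {"L1": [100], "L2": [200]})
                         for i in range(4)])
        gt = call_multilocus_genotypes(df)
        assert gt.n_genotypes == 1
        assert gt.summary.loc["A", "frequency"] == 100.0

    def test_labels_stable_under_row_permutation(self, modal_population):
        gt1 = call_multilocus_genotypes(modal_population)
        shuffled = modal_population.sample(frac=1.0, random_state=3)
        gt2 = call_multilocus_genotypes(shuffled)
        merged = gt1.assignments.to_frame("a").join(gt2.assignments.to_frame("b"))
        assert (merged["a"] == merged["b"]).all()

    def test_modal_frequencies(self, modal_population):
        gt = call_multilocus_genotypes(modal_population)
        row = gt.summary.loc["A"]
        assert row["count"] == 44
        assert row["frequency"] == 55.7
        assert row["hybrid_frequency"] == 42.9
        assert row["allopolyploid_frequency"] == 56.9

    def test_reports_both_allele_counts(self, modal_population):
        gt = call_multilocus_genotypes(modal_population)
        assert gt.modal_allele_count == 16
        assert gt.n_distinct_alleles > gt.modal_allele_count


class TestFrequencyTable:
    def test_unknown_locus_rejected(self, reference_population):
        with pytest.raises(KeyError):
            frequency_table(reference_population, "MS99")

    def test_monomorphic_locus_is_100_percent(self, reference_population):
        ft = frequency_table(reference_population, "MS16")
        assert len(ft) == 1
        assert ft.iloc[0]["total_pct"] == 100.0

    def test_stratum_columns_sum_to_100(self, reference_population):
        for locus in locus_columns(reference_population):
            ft = frequency_table(reference_population, locus)
            for col in ("hybrid_pct", "allopolyploid_pct", "total_pct"):
                assert ft[col].sum() == pytest.approx(100.0, abs=0.1)

    def test_round_half_up_ties_away_from_zero(self):
        assert round_half_up(87.55) == 87.6
        assert round_half_up(2.25, 1) == 2.3


class TestDissimilarity:
    def test_identical_samples_zero(self):
        df = _ssr_frame([("a", "hybrid", {"L1": [1, 2], "L2": [5]}),
                         ("b", "hybrid", {"L1": [1, 2], "L2": [5]})])
        d = dissimilarity_matrix(df)
        assert d.loc["a", "b"] == 0

    def test_symmetric_difference_count(self):
        df = _ssr_frame([("a", "hybrid", {"L1": [1, 2, 3]}),
                         ("b", "hybrid", {"L1": [1, 2, 4]})], loci=("L1",))
        assert dissimilarity_matrix(df).loc["a", "b"] == 2

    def test_superset_distance_equals_extra_alleles(self, modal_population):
        gt = call_multilocus_genotypes(modal_population)
        base = gt.to_frame().iloc[[0]].copy()
        extra = base.copy()
        extra["sample_id"] = "X"
        extra["MS15"] = extra["MS15"] + "/300/301/302"
        d = dissimilarity_matrix(pd.concat([base, extra], ignore_index=True))
        assert d.iloc[0, 1] == 3

    def test_empty_locus_contributes_zero(self):
        df = _ssr_frame([("a", "hybrid", {"L1": [1, 2], "L2": [5]}),
                         ("b", "hybrid", {"L1": [], "L2": [6]})])
        # L1 missing in b -> only L2's symmetric difference counts
        assert dissimilarity_matrix(df).loc["a", "b"] == 2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.frozensets(st.integers(100, 112), min_size=1, max_size=6),
                    min_size=3, max_size=3))
    def test_metric_on_nonempty_presence_sets(self, sets):
        df = _ssr_frame([(f"s{i}", "hybrid", {"L1": s}) for i, s in enumerate(sets)],
                        loci=("L1",))
        d = dissimilarity_matrix(df).to_numpy()
        assert (d >= 0).all()
        assert np.allclose(d, d.T)
        for i, j, k in itertools.permutations(range(3), 3):
            assert d[i, k] <= d[i, j] + d[j, k]


def enumerate_mst_weight(W: np.ndarray) -> float:
    """Exhaustive minimum over all labelled spanning trees (Pruefer)."""
    n = W.shape[0]
    if n == 2:
        return float(W[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        T = nx.from_prufer_sequence(list(seq))
        w = sum(W[u, v] for u, v in T.edges())
        best = min(best, w)
    return float(best)


class TestMinimumSpanningNetwork:
    def test_unique_mst(self):
        W = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        net = minimum_spanning_network(W)
        msn = {frozenset(e) for e in net.msn_subgraph().edges()}
        assert msn == {frozenset({0, 1}), frozenset({1, 2})}
        assert net.tree_weight == 3

    def test_full_tie_cycle_retained(self):
        W = np.ones((3, 3)) - np.eye(3)
        net = minimum_spanning_network(W)
        assert net.msn_subgraph().number_of_edges() == 3

    def test_tree_weight_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 6
            W = rng.integers(1, 6, size=(n, n)).astype(float)
            W = np.triu(W, 1)
            W = W + W.T
            net = minimum_spanning_network(W)
            assert net.tree_weight == enumerate_mst_weight(W)

    def test_retained_ties_equal_replaceable_tree_edges(self):
        rng = np.random.default_rng(8)
        W = rng.integers(1, 4, size=(7, 7)).astype(float)
        W = np.triu(W, 1)
        W = W + W.T
        net = minimum_spanning_network(W)
        G = net.graph
        msn = net.msn_subgraph()
        assert nx.is_connected(msn)
        # every retained non-tree edge ties the max-weight edge on some
        # tree path: swapping it in gives another tree of equal weight
        tree_edges = {frozenset(e) for e in
                      nx.minimum_spanning_tree(G, algorithm="kruskal").edges()}
        for u, v, d in msn.edges(data=True):
            if frozenset({u, v}) not in tree_edges:
                T = nx.minimum_spanning_tree(G, algorithm="kruskal")
                path = nx.shortest_path(T, u, v)
                max_w = max(T[a][b]["weight"] for a, b in zip(path, path[1:]))
                assert d["weight"] == max_w

    def test_nan_weights_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = np.nan
        with pytest.raises(ValueError):
            minimum_spanning_network(W)

    def test_node_sizes_carried(self, modal_population):
        gt = call_multilocus_genotypes(modal_population)
        d = dissimilarity_matrix(gt.to_frame())
        net = minimum_spanning_network(d, node_sizes=gt.summary["count"].to_dict())
        assert net.graph.nodes["A"]["size"] == 44
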