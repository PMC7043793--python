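import numpy as np
import pandas as pd
import pytest

from _oracles import all_simple_paths_distance
from quantkit.network_connectivity import (
    ThresholdParams,
    build_network,
    connectivity_report,
    read_edge_list,
    sample_connectivity_null,
    set_connectivity_profile,
    shortest_distance,
)


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def random_edges(rng, n_nodes, p=0.5):
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                rows.append((f"N{i}", f"N{j}", float(rng.uniform(0.5, 5.0))))
    return rows


def complete_graph(n, w):
    return edge_frame(
        [(f"N{i}", f"N{j}", w) for i in range(n) for j in range(i + 1, n)]
    )


class TestBuildNetwork:
    def test_min_weight_is_strict(self):
        edges = edge_frame(
            [("A", "B", 1.5), ("B", "C", 2.0), ("C", "D", 2.5), ("D", "E", 3.0)]
        )
        net = build_network(edges, ThresholdParams(mode="min_weight", min_weight=2.0))
        assert net.n_edges == 2  # 2.0 itself excluded

    def test_top_fraction_keeps_ceil(self, rng):
        edges = edge_frame(
            [(f"A{i}", f"B{i}", float(w)) for i, w in enumerate(rng.uniform(0, 1, 1000))]
        )
        net = build_network(edges, ThresholdParams(mode="top_fraction", top_fraction=0.005))
        assert net.n_edges == 5

    def test_duplicate_pair_collapses_to_max(self):
        edges = edge_frame([("A", "B", 2.5), ("B", "A", 3.0)])
        net = build_network(edges, ThresholdParams(min_weight=2.0))
        assert net.n_edges == 1
        assert net.graph["A"]["B"]["weight"] == 3.0

    def test_modes_agree_at_realized_cutoff(self, rng):
        edges = edge_frame(
            [(f"A{i}", f"B{i}", float(w)) for i, w in enumerate(rng.uniform(1, 9, 200))]
        )
        top = build_network(edges, ThresholdParams(mode="top_fraction", top_fraction=0.1))
        cutoff = min(d["weight"] for _, _, d in top.graph.edges(data=True))
        again = build_network(
            edges, ThresholdParams(mode="min_weight", min_weight=cutoff - 1e-9)
        )
        assert set(map(frozenset, top.graph.edges)) == set(map(frozenset, again.graph.edges))

    def test_empty_result_and_bad_weight_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            build_network(edge_frame([("A", "B", 1.0)]), ThresholdParams(min_weight=2.0))
        with pytest.raises(ValueError, match="record 1"):
            build_network(edge_frame([("A", "B", 3.0), ("B", "C", "oops")]))


class TestShortestDistance:
    def test_self_distance_zero(self):
        net = build_network(edge_frame([("A", "B", 4.0)]), ThresholdParams(min_weight=0.0))
        assert shortest_distance(net, "A", "A") == ("ok", 0.0)

    def test_single_edge_reciprocal_transform(self):
        net = build_network(edge_frame([("A", "B", 4.0)]), ThresholdParams(min_weight=0.0))
        assert shortest_distance(net, "A", "B") == ("ok", 0.25)

    def test_absent_and_disconnected_statuses(self):
        net = build_network(
            edge_frame([("A", "B", 1.0), ("C", "D", 1.0)]), ThresholdParams(min_weight=0.0)
        )
        assert shortest_distance(net, "A", "Z") == ("absent", None)
        assert shortest_distance(net, "A", "C") == ("disconnected", None)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_simple_path_enumeration(self, seed):
        r = np.random.default_rng(seed)
        rows = random_edges(r, 6)
        if not rows:
            return
        net = build_network(edge_frame(rows), ThresholdParams(min_weight=0.0))
        oracle_edges = {frozenset((a, b)): w for a, b, w in rows}
        nodes = sorted({g for a, b, _ in rows for g in (a, b)})
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                status, d = shortest_distance(net, a, b)
                ref = all_simple_paths_distance(oracle_edges, a, b)
                if status == "ok":
                    assert d == pytest.approx(ref, abs=1e-12)
                else:
                    assert ref is None

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_axioms_on_components(self, seed):
        r = np.random.default_rng(100 + seed)
        net = build_network(edge_frame(random_edges(r, 7, p=0.6)),
                            ThresholdParams(min_weight=0.0))
        nodes = net.nodes
        d = {}
        for a in nodes:
            for b in nodes:
                s, v = shortest_distance(net, a, b)
                if s == "ok":
                    d[a, b] = v
        for (a, b), v in d.items():
            assert v >= 0
            assert d[b, a] == pytest.approx(v, abs=1e-12)
            for c in nodes:
                if (a, c) in d and (c, b) in d:
                    assert v <= d[a, c] + d[c, b] + 1e-9

    def test_raising_a_weight_never_increases_distances(self, rng):
        rows = random_edges(rng, 8, p=0.5)
        net0 = build_network(edge_frame(rows), ThresholdParams(min_weight=0.0))
        i = int(rng.integers(len(rows)))
        boosted = [
            (a, b, w * 3.0 if j == i else w) for j, (a, b, w) in enumerate(rows)
        ]
        net1 = build_network(edge_frame(boosted), ThresholdParams(min_weight=0.0))
        for a in net0.nodes:
            for b in net0.nodes:
                s0, d0 = shortest_distance(net0, a, b)
                s1, d1 = shortest_distance(net1, a, b)
                if s0 == "ok":
                    assert s1 == "ok" and d1 <= d0 + 1e-12


class TestConnectivityProfile:
    def test_triangle_all_means_equal_reciprocal_weight(self):
        net = build_network(complete_graph(3, 4.0), ThresholdParams(min_weight=0.0))
        prof = set_connectivity_profile(net, ["N0", "N1", "N2"])
        assert prof.table["mean_distance"].to_numpy() == pytest.approx([0.25] * 3)

    def test_absent_genes_reported_not_scored(self):
        net = build_network(complete_graph(15, 2.5), ThresholdParams(min_weight=0.0))
        query = [f"N{i}" for i in range(15)] + [f"X{i}" for i in range(6)]
        prof = set_connectivity_profile(net, query)
        assert len(prof.table) == 15
        assert sorted(prof.absent) == sorted(f"X{i}" for i in range(6))

    def test_disconnected_member_flagged_and_excluded(self):
        edges = edge_frame(
            [("A", "B", 2.0), ("B", "C", 2.0), ("A", "C", 2.0), ("D", "E", 2.0)]
        )
        net = build_network(edges, ThresholdParams(min_weight=0.0))
        prof = set_connectivity_profile(net, ["A", "B", "C", "D"])
        row = prof.table.set_index("gene").loc["D"]
        assert row["n_reached"] == 0 and row["n_unreachable"] == 3
        assert np.isnan(row["mean_distance"])
        assert len(prof.per_gene_means) == 3

    def test_too_few_present_genes_rejected(self):
        net = build_network(complete_graph(4, 1.0), ThresholdParams(min_weight=0.0))
        with pytest.raises(ValueError):
            set_connectivity_profile(net, ["N0", "ZZ"])


class TestNullSampling:
    def test_complete_graph_null_is_degenerate(self):
        net = build_network(complete_graph(30, 5.0), ThresholdParams(min_weight=0.0))
        null = sample_connectivity_null(net, n_anchor_genes=10, n_replicates=5,
                                        partner_set_size=4, seed=0)
        assert null.values == pytest.approx(np.full(50, 0.2))
        assert null.n_empty == 0

    def test_seed_reproducibility(self, rng):
        net = build_network(edge_frame(random_edges(rng, 40, p=0.2)),
                            ThresholdParams(min_weight=0.0))
        a = sample_connectivity_null(net, 10, 5, 5, seed=3)
        b = sample_connectivity_null(net, 10, 5, 5, seed=3)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.raw_distances, b.raw_distances)

    def test_edge_insertion_order_irrelevant(self, rng):
        rows = random_edges(rng, 30, p=0.3)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        n1 = sample_connectivity_null(
            build_network(edge_frame(rows), ThresholdParams(min_weight=0.0)),
            8, 4, 5, seed=9)
        n2 = sample_connectivity_null(
            build_network(edge_frame(shuffled), ThresholdParams(min_weight=0.0)),
            8, 4, 5, seed=9)
        assert np.allclose(n1.values, n2.values)

    def test_too_small_network_rejected(self):
        net = build_network(complete_graph(5, 1.0), ThresholdParams(min_weight=0.0))
        with pytest.raises(ValueError):
            sample_connectivity_null(net, 3, 2, partner_set_size=10)


class TestConnectivityReport:
    def test_gene_below_entire_null_attains_minimal_exact_p(self):
        net = build_network(complete_graph(25, 1.0), ThresholdParams(min_weight=0.0))
        null = sample_connectivity_null(net, 10, 10, 5, seed=0)  # all values = 1.0
        strong = build_network(complete_graph(4, 100.0), ThresholdParams(min_weight=0.0))
        prof = set_connectivity_profile(strong, ["N0", "N1", "N2", "N3"])
        report = connectivity_report(prof, null)
        gene_rows = report[report["gene"] != "<set>"]
        m = null.values.size
        assert gene_rows["p"].to_numpy() == pytest.approx(np.full(4, 1 / (m + 1)))

    def test_q_dominates_p_and_flags_match_threshold(self, rng):
        net = build_network(edge_frame(random_edges(rng, 60, p=0.15)),
                            ThresholdParams(min_weight=0.0))
        genes = net.nodes[:8]
        prof = set_connectivity_profile(net, genes)
        null = sample_connectivity_null(net, 20, 10, 7, seed=1)
        report = connectivity_report(prof, null)
        assert (report["q"] >= report["p"] - 1e-12).all()
        assert (report["significant"] == (report["q"] < 0.05)).all()

    def test_empty_null_rejected(self):
        net = build_network(complete_graph(4, 1.0), ThresholdParams(min_weight=0.0))
        prof = set_connectivity_profile(net, ["N0", "N1"])
        from quantkit.network_connectivity import NullDistribution

        empty = NullDistribution(np.empty(0), np.empty(0), 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            connectivity_report(prof, empty)


class TestEdgeListIO:
    def test_reads_with_and_without_header(self, tmp_path):
        with_header = tmp_path / "a.tsv"
        with_header.write_text("gene_a\tgene_b\tweight\nA\tB\t2.5\n")
        bare = tmp_path / "b.tsv"
        bare.write_text("A\tB\t2.5\n")
        for path in (with_header, bare):
            df = read_edge_list(path)
            assert list(df.columns) == ["gene_a", "gene_b", "weight"]
            assert df.iloc[0]["weight"] == 2.5
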