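import itertools

import networkx as nx
import numpy as np
import pytest

import oracles
from rinmd.errors import ConfigurationError, TopologyInconsistencyError
from rinmd.fixtures import (
    PlantedInteraction,
    make_assembly,
    make_trajectory,
)
from rinmd.interactions import InteractionRecord, InteractionType as T, detect_all
from rinmd.rin import (
    ConsensusRIN,
    build_consensus,
    build_frame_graph,
    centralities,
    classify_edges,
    consensus_from_records,
    read_network,
    simple_projection,
    write_network,
)
from rinmd.structure_io import ResidueKey


def key(seq, chain="A", name="ALA"):
    return ResidueKey(chain_id=chain, residue_seq=seq, residue_name=name)


def rec(itype, a, b, frame=0, **desc):
    return InteractionRecord(itype, a, b, (), dict(desc) or {"distance": 1.0}, frame)


NODES = [key(i) for i in range(1, 6)]


class TestFrameGraph:
    def test_multigraph_collapses_multiplicity_to_count(self):
        a, b = NODES[0], NODES[1]
        records = [
            rec(T.HBOND, a, b, distance=2.8),
            rec(T.HBOND, a, b, distance=3.0),
            rec(T.SALT_BRIDGE, a, b, distance=4.0),
        ]
        g = build_frame_graph(records, 0, NODES)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 2  # one per type
        assert g[a][b]["HBOND"]["count"] == 2
        assert g[a][b]["HBOND"]["descriptors"]["distance"] == pytest.approx(2.9)
        assert g[a][b]["SALT_BRIDGE"]["count"] == 1

    def test_empty_records_keep_isolated_nodes(self):
        g = build_frame_graph([], 0, NODES)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 0

    def test_edge_multiset_matches_groupby_oracle(self, rng):
        records = []
        for _ in range(60):
            i, j = rng.choice(5, size=2, replace=False)
            t = T(int(rng.integers(1, 10)))
            records.append(rec(t, *sorted([NODES[i], NODES[j]]), distance=1.0))
        g = build_frame_graph(records, 0, NODES)
        expected = {}
        for r in records:
            expected[(r.pair(), r.type.name)] = expected.get((r.pair(), r.type.name), 0) + 1
        got = {
            ((u, v) if u <= v else (v, u), k): d["count"]
            for u, v, k, d in g.edges(keys=True, data=True)
        }
        assert got == expected

    def test_wrong_frame_rejected(self):
        with pytest.raises(TopologyInconsistencyError):
            build_frame_graph([rec(T.HBOND, NODES[0], NODES[1], frame=3)], 0, NODES)


class TestConsensus:
    def make_graphs(self, presence, itype=T.HBOND):
        graphs = []
        for f, present in enumerate(presence):
            records = [rec(itype, NODES[0], NODES[1], frame=f)] if present else []
            graphs.append(build_frame_graph(records, f, NODES))
        return graphs

    def test_eight_of_ten_kept_at_075(self):
        graphs = self.make_graphs([1] * 8 + [0] * 2)
        rin = build_consensus(graphs, persistence_min=0.75)
        edges = rin.edges()
        assert len(edges) == 1
        assert edges[0][3]["persistence"] == pytest.approx(0.8)
        assert edges[0][3]["frame_count"] == 8

    def test_seven_of_ten_dropped_at_075(self):
        rin = build_consensus(self.make_graphs([1] * 7 + [0] * 3), persistence_min=0.75)
        assert rin.edges() == []

    def test_exact_boundary_nine_of_twelve(self):
        rin = build_consensus(self.make_graphs([1] * 9 + [0] * 3), persistence_min=0.75)
        assert len(rin.edges()) == 1
        assert rin.edges()[0][3]["persistence"] == pytest.approx(0.75)

    def test_zero_cutoff_gives_union(self):
        graphs = self.make_graphs([1, 0, 0, 0])
        rin = build_consensus(graphs, persistence_min=0.0)
        assert len(rin.edges()) == 1

    def test_monotone_in_persistence_min(self):
        rng = np.random.default_rng(5)
        graphs = []
        for f in range(20):
            records = []
            for i, j in itertools.combinations(range(5), 2):
                if rng.random() < 0.5:
                    records.append(rec(T.CALPHA, NODES[i], NODES[j], frame=f))
            graphs.append(build_frame_graph(records, f, NODES))
        sizes = []
        for pmin in (0.0, 0.25, 0.5, 0.75, 1.0):
            rin = build_consensus(graphs, pmin)
            edges = {(u, v, k) for u, v, k, _ in rin.edges()}
            sizes.append(edges)
        for small, large in zip(sizes[1:], sizes):
            assert small <= large

    def test_frame_order_invariance(self):
        graphs = self.make_graphs([1, 0, 1, 1, 0, 1])
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(graphs)))
        a = build_consensus(graphs, 0.5)
        b = build_consensus([graphs[i] for i in perm], 0.5)
        ea = {(u, v, k, d["persistence"]) for u, v, k, d in a.edges()}
        eb = {(u, v, k, d["persistence"]) for u, v, k, d in b.edges()}
        assert ea == eb

    def test_single_frame_reproduces_frame_graph(self, dense_random_system):
        records = detect_all(dense_random_system)
        rin = consensus_from_records(
            [records], dense_random_system.residue_keys, persistence_min=1.0
        )
        g = build_frame_graph(records, 0, dense_random_system.residue_keys)
        assert {(u, v, k) for u, v, k in rin.graph.edges(keys=True)} == {
            (u, v, k) if u <= v else (v, u, k) for u, v, k in g.edges(keys=True)
        }
        for u, v, k, d in rin.edges():
            assert d["persistence"] == 1.0 and d["frame_count"] == 1

    def test_inconsistent_node_sets_rejected(self):
        g1 = build_frame_graph([], 0, NODES)
        g2 = build_frame_graph([], 1, NODES[:-1])
        with pytest.raises(TopologyInconsistencyError):
            build_consensus([g1, g2])

    def test_descriptor_stats_over_present_frames(self):
        graphs = []
        for f, d in enumerate([2.0, 4.0, None, 6.0]):
            records = [] if d is None else [rec(T.CALPHA, NODES[0], NODES[1], frame=f, distance=d)]
            graphs.append(build_frame_graph(records, f, NODES))
        rin = build_consensus(graphs, 0.5)
        d = rin.edges()[0][3]
        assert d["distance_mean"] == pytest.approx(4.0)
        assert d["distance_min"] == pytest.approx(2.0)
        assert d["distance_max"] == pytest.approx(6.0)
        assert d["persistence"] == pytest.approx(0.75)


class TestClassification:
    def test_three_classes(self):
        amap = {"A": 1, "B": 1, "G": 2}
        graphs = [
            build_frame_graph(
                [
                    rec(T.HBOND, key(1, "A"), key(5, "A")),
                    rec(T.HBOND, key(1, "A"), key(1, "B")),
                    rec(T.SALT_BRIDGE, key(2, "A"), key(2, "G")),
                ],
                0,
                [key(1, "A"), key(2, "A"), key(5, "A"), key(1, "B"), key(2, "G")],
            )
        ]
        rin = build_consensus(graphs, 1.0)
        table = classify_edges(rin, amap)
        assert table.loc["HBOND", "INTRA_CHAIN"] == 1
        assert table.loc["HBOND", "INTER_CHAIN"] == 1
        assert table.loc["SALT_BRIDGE", "INTER_ASSEMBLY"] == 1
        # conservation: row totals equal per-type edge counts
        assert int(table.loc["HBOND"].sum()) == 2
        assert int(table.sum().sum()) == rin.graph.number_of_edges()

    def test_missing_chain_raises(self):
        graphs = [
            build_frame_graph(
                [rec(T.HBOND, key(1, "A"), key(1, "B"))],
                0,
                [key(1, "A"), key(1, "B")],
            )
        ]
        rin = build_consensus(graphs, 1.0)
        with pytest.raises(ConfigurationError, match="B"):
            classify_edges(rin, {"A": 1})

    def test_planted_assembly_counts(self):
        system, amap = make_assembly(
            4, 2, inter_chain_planted=[("A", "B")], inter_assembly_planted=[("A", "C")]
        )
        records = detect_all(system, enabled_types={T.HBOND})
        rin = consensus_from_records([records], system.residue_keys, 0.75)
        table = classify_edges(rin, amap)
        assert table.loc["HBOND", "INTER_ASSEMBLY"] == 1
        assert table.loc["HBOND", "INTER_CHAIN"] == 1
        assert table.loc["HBOND", "INTRA_CHAIN"] == 4

    def test_no_inter_chain_plants_means_zero_column(self):
        system, amap = make_assembly(3, 1)
        records = detect_all(system, enabled_types={T.HBOND})
        rin = consensus_from_records([records], system.residue_keys, 0.75)
        table = classify_edges(rin, amap)
        assert table["INTER_CHAIN"].sum() == 0
        assert table["INTER_ASSEMBLY"].sum() == 0

    def test_chain_label_permutation_invariance(self):
        counts = []
        for chains in (("A", "B"), ("B", "A")):
            system, amap = make_assembly(2, 2, inter_assembly_planted=[chains])
            records = detect_all(system, enabled_types={T.HBOND})
            rin = consensus_from_records([records], system.residue_keys, 0.75)
            table = classify_edges(rin, amap)
            counts.append(table.values.tolist())
        assert counts[0] == counts[1]


class TestCentralities:
    @staticmethod
    def rin_from_graph(g):
        nodes = {n: key(n + 1) for n in g.nodes}
        mg = nx.MultiGraph()
        for n in g.nodes:
            mg.add_node(nodes[n], resname="ALA", chain="A")
        for u, v in g.edges:
            mg.add_edge(nodes[u], nodes[v], key="CALPHA", type="CALPHA", persistence=1.0)
        return ConsensusRIN(graph=mg, n_frames=1), nodes

    def test_path_graph_betweenness(self):
        rin, nodes = self.rin_from_graph(nx.path_graph(3))
        c = centralities(rin)
        assert c[nodes[1]]["betweenness"] == pytest.approx(1.0)
        assert c[nodes[0]]["betweenness"] == pytest.approx(0.0)

    def test_complete_graph_symmetry(self):
        rin, nodes = self.rin_from_graph(nx.complete_graph(4))
        c = centralities(rin)
        assert all(c[n]["degree"] == pytest.approx(1.0) for n in nodes.values())
        assert all(c[n]["betweenness"] == pytest.approx(0.0) for n in nodes.values())

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_graph_matches_textbook_formulas(self, seed):
        g = nx.gnp_random_graph(15, 0.3, seed=seed)
        rin, nodes = self.rin_from_graph(g)
        got = centralities(rin)
        adj = [sorted(g.neighbors(v)) for v in range(15)]
        deg, btw, clo = oracles.textbook_centralities(adj)
        for v in range(15):
            assert got[nodes[v]]["degree"] == pytest.approx(deg[v], abs=1e-9)
            assert got[nodes[v]]["betweenness"] == pytest.approx(btw[v], abs=1e-9)
            assert got[nodes[v]]["closeness"] == pytest.approx(clo[v], abs=1e-9)

    def test_eigenvector_matches_power_iteration(self):
        g = nx.gnp_random_graph(12, 0.4, seed=7)
        # keep only the largest connected component for a well-defined vector
        giant = max(nx.connected_components(g), key=len)
        g = g.subgraph(giant).copy()
        g = nx.convert_node_labels_to_integers(g)
        rin, nodes = self.rin_from_graph(g)
        got = centralities(rin)
        a = nx.to_numpy_array(g)
        v = np.ones(len(g))
        for _ in range(2000):
            v = a @ v
            v /= np.linalg.norm(v)
        for i in range(len(g)):
            assert got[nodes[i]]["eigenvector"] == pytest.approx(abs(v[i]), abs=1e-6)

    def test_weighted_degree_counts_distinct_types(self):
        mg = nx.MultiGraph()
        a, b = key(1), key(2)
        mg.add_node(a), mg.add_node(b)
        mg.add_edge(a, b, key="HBOND", type="HBOND")
        mg.add_edge(a, b, key="SALT_BRIDGE", type="SALT_BRIDGE")
        rin = ConsensusRIN(graph=mg, n_frames=1)
        c = centralities(rin)
        assert c[a]["weighted_degree"] == 2.0
        assert simple_projection(rin).number_of_edges() == 1


class TestNetworkIO:
    @pytest.fixture
    def sample_rin(self):
        graphs = [
            build_frame_graph(
                [
                    rec(T.HBOND, key(1), key(5), frame=f, distance=2.8, angle=150.0),
                    rec(T.CALPHA, key(1), key(3), frame=f, distance=6.0),
                ],
                f,
                NODES,
            )
            for f in range(4)
        ]
        return build_consensus(graphs, 0.5)

    def test_graphml_roundtrip(self, sample_rin, tmp_path):
        written = write_network(sample_rin, tmp_path, prefix="x")
        back = read_network(written["global"])
        assert set(back.graph.nodes) == set(sample_rin.graph.nodes)
        assert back.n_frames == sample_rin.n_frames
        for u, v, k, d in sample_rin.edges():
            assert back.graph.has_edge(u, v, key=k)
            for attr, val in d.items():
                if isinstance(val, float):
                    assert back.graph[u][v][k][attr] == pytest.approx(val)
                else:
                    assert back.graph[u][v][k][attr] == val

    def test_per_type_files_partition_edges(self, sample_rin, tmp_path):
        written = write_network(sample_rin, tmp_path, prefix="x")
        assert set(written) == {"global", "HBOND", "CALPHA", "nodes", "edges"}
        hb = read_network(written["HBOND"])
        assert {k for _, _, k in hb.graph.edges(keys=True)} == {"HBOND"}

    def test_empty_rin_writes_valid_files(self, tmp_path):
        rin = build_consensus([build_frame_graph([], 0, NODES)], 0.5)
        written = write_network(rin, tmp_path, prefix="empty")
        back = read_network(written["global"])
        assert back.graph.number_of_edges() == 0
        assert set(back.graph.nodes) == set(NODES)
        header = (tmp_path / "empty_nodes.tsv").read_text().splitlines()[0]
        assert header.startswith("node\t")


def test_trajectory_consensus_matches_planted_persistence():
    presence = np.array([1, 1, 1, 0, 0, 1, 1, 1, 1, 0, 1, 1], dtype=bool)  # 9/12
    plants = [PlantedInteraction(T.HBOND, {}, presence)]
    traj = make_trajectory(plants, 12, noise=0.02, seed=8)
    per_frame = [detect_all(traj.system, f, None, (T.HBOND,)) for f in range(12)]
    rin = consensus_from_records(per_frame, traj.system.residue_keys, 0.75)
    edges = rin.edges()
    assert len(edges) == 1
    assert edges[0][3]["persistence"] == pytest.approx(0.75)
    assert edges[0][3]["frame_count"] == 9
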