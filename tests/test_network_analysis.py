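import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tempomics import (
    analyse_network,
    betweenness,
    build_graph,
    connected_components,
    degree_normalized,
)


def matrix(entries, mols):
    n = len(mols)
    mat = np.eye(n)
    for (a, b), v in entries.items():
        i, j = mols.index(a), mols.index(b)
        mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=mols, columns=mols)


def brute_force_betweenness(g, n_norm):
    """Exhaustive geodesic enumeration via BFS path counting."""
    nodes = list(g.nodes)
    acc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # enumerate all shortest s-t paths explicitly
        try:
            length = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [
            p for p in nx.all_simple_paths(g, s, t, cutoff=length)
            if len(p) - 1 == length
        ]
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            acc[v] += through / len(paths)
    scale = 2.0 / ((n_norm - 1) * (n_norm - 2)) if n_norm > 2 else 0.0
    return {v: acc[v] * scale for v in nodes}


class TestBuildGraph:
    def test_all_below_threshold_no_edges(self):
        mols = ["A", "B", "C"]
        mg = build_graph(matrix({("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5}, mols))
        assert mg.graph.number_of_edges() == 0

    def test_exactly_at_threshold_excluded(self):
        mg = build_graph(matrix({("A", "B"): 0.6}, ["A", "B"]))
        assert mg.graph.number_of_edges() == 0

    def test_toy_edge_enumeration_with_signs(self):
        mols = ["A", "B", "C", "D"]
        entries = {
            ("A", "B"): 0.9,
            ("A", "C"): -0.7,
            ("A", "D"): 0.2,
            ("B", "C"): 0.1,
            ("B", "D"): -0.3,
            ("C", "D"): 0.61,
        }
        mg = build_graph(matrix(entries, mols))
        got = {tuple(sorted(e)) for e in mg.graph.edges}
        assert got == {("A", "B"), ("A", "C"), ("C", "D")}
        assert mg.graph.edges["A", "C"]["tpsm"] == -0.7
        assert mg.graph.edges["A", "C"]["abs_tpsm"] == 0.7

    def test_asymmetric_matrix_rejected(self):
        mat = matrix({("A", "B"): 0.9}, ["A", "B"])
        mat.iloc[0, 1] = 0.8
        with pytest.raises(ValueError, match="symmetric"):
            build_graph(mat)


class TestComponents:
    def test_edgeless_graph_all_isolated(self):
        mg = build_graph(matrix({}, ["A", "B", "C"]))
        connected_components(mg)
        assert mg.components == {}
        assert sorted(mg.isolated) == ["A", "B", "C"]

    def test_two_disjoint_triangles(self):
        mols = list("ABCDEF")
        entries = {(a, b): 0.9 for a, b in [("A", "B"), ("B", "C"), ("A", "C"),
                                            ("D", "E"), ("E", "F"), ("D", "F")]}
        mg = connected_components(build_graph(matrix(entries, mols)))
        comp_sizes = {}
        for cid in mg.components.values():
            comp_sizes[cid] = comp_sizes.get(cid, 0) + 1
        assert sorted(comp_sizes.values()) == [3, 3]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(33)
        mols = [f"N{i}" for i in range(12)]
        mat = np.eye(12)
        for i in range(12):
            for j in range(i + 1, 12):
                mat[i, j] = mat[j, i] = rng.uniform(-1, 1)
        df = pd.DataFrame(mat, index=mols, columns=mols)
        mg = connected_components(build_graph(df))

        parent = list(range(12))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(12):
            for j in range(i + 1, 12):
                if abs(mat[i, j]) > 0.6:
                    parent[find(i)] = find(j)
        oracle = {}
        for i, m in enumerate(mols):
            if any(abs(mat[i, j]) > 0.6 for j in range(12) if j != i):
                oracle.setdefault(find(i), set()).add(m)
        got = {}
        for m, cid in mg.components.items():
            got.setdefault(cid, set()).add(m)
        assert set(map(frozenset, oracle.values())) == set(map(frozenset, got.values()))


class TestBetweenness:
    def test_path_graph_centre(self):
        mg = build_graph(matrix({("A", "B"): 0.9, ("B", "C"): 0.9}, ["A", "B", "C"]))
        betweenness(mg)
        assert mg.betweenness["B"] == pytest.approx(1.0)
        assert mg.betweenness["A"] == 0.0

    def test_complete_graph_all_zero(self):
        mols = list("ABCD")
        entries = {(a, b): 0.9 for a, b in itertools.combinations(mols, 2)}
        mg = betweenness(build_graph(matrix(entries, mols)))
        assert all(v == 0.0 for v in mg.betweenness.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        mols = [f"N{i}" for i in range(8)]
        mat = np.eye(8)
        for i in range(8):
            for j in range(i + 1, 8):
                mat[i, j] = mat[j, i] = rng.uniform(-1, 1)
        mg = betweenness(build_graph(pd.DataFrame(mat, index=mols, columns=mols)))
        g = mg.graph
        connected = [n for n in g.nodes if g.degree(n) > 0]
        oracle = brute_force_betweenness(g.subgraph(connected), len(connected))
        for node in connected:
            assert mg.betweenness[node] == pytest.approx(oracle[node], abs=1e-12)


class TestDegreeNormalized:
    def test_direct_arithmetic(self):
        mols = [f"G{i}" for i in range(8)]
        entries = {("G0", m): 0.9 for m in mols[1:5]}  # G0 has degree 4
        mg = build_graph(matrix(entries, mols), groups={m: "amino acid" for m in mols})
        degree_normalized(mg)
        assert mg.deg_normalized["G0"] == pytest.approx(0.5)  # 4 / 8

    def test_isolated_node_zero(self):
        mg = build_graph(matrix({}, ["A", "B"]), groups={"A": "ion", "B": "ion"})
        degree_normalized(mg)
        assert mg.deg_normalized == {"A": 0.0, "B": 0.0}

    def test_single_group_loop_oracle(self):
        rng = np.random.default_rng(5)
        mols = [f"N{i}" for i in range(6)]
        mat = np.eye(6)
        for i in range(6):
            for j in range(i + 1, 6):
                mat[i, j] = mat[j, i] = rng.uniform(0, 1)
        mg = build_graph(pd.DataFrame(mat, index=mols, columns=mols),
                         groups={m: "lipid" for m in mols})
        degree_normalized(mg)
        for m in mols:
            assert mg.deg_normalized[m] == pytest.approx(mg.graph.degree(m) / 6)

    def test_missing_group_rejected(self):
        mg = build_graph(matrix({("A", "B"): 0.9}, ["A", "B"]))
        with pytest.raises(ValueError):
            degree_normalized(mg, groups={"A": "ion", "B": ""})


class TestThresholdMonotonicity:
    def test_raising_threshold_never_adds_structure(self):
        rng = np.random.default_rng(44)
        mols = [f"N{i}" for i in range(15)]
        mat = np.eye(15)
        for i in range(15):
            for j in range(i + 1, 15):
                mat[i, j] = mat[j, i] = rng.uniform(-1, 1)
        df = pd.DataFrame(mat, index=mols, columns=mols)
        groups = {m: "other" for m in mols}
        prev = None
        for thr in (0.4, 0.6, 0.8):
            mg = analyse_network(df, groups, threshold=thr)
            stats = (
                mg.graph.number_of_edges(),
                len(mg.components),
                max((mg.graph.degree(n) for n in mg.graph.nodes), default=0),
            )
            if prev is not None:
                assert stats[0] <= prev[0]
                assert stats[1] <= prev[1]
                assert stats[2] <= prev[2]
            prev = stats


def test_graphml_export_round_trips_node_statistics(tmp_path):
    from tempomics import analyse_network, write_graphml

    mols = list("ABCD")
    entries = {("A", "B"): 0.9, ("B", "C"): 0.7, ("C", "D"): -0.65}
    mat = matrix(entries, mols)
    mg = analyse_network(mat, {m: "lipid" for m in mols})
    path = tmp_path / "net.graphml"
    write_graphml(mg, path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == set(mols)
    assert back.nodes["B"]["betweenness"] == pytest.approx(mg.betweenness["B"])
    assert back.edges["C", "D"]["tpsm"] == pytest.approx(-0.65)


def test_bridge_molecule_attains_maximum_betweenness():
    """A molecule built as a mixture of two group templates bridges the two
    cliques of the similarity network and tops the betweenness ranking."""
    import tempomics as tm

    arch_a = tm.ArchetypeSpec("sustained_decrease", peak_time=120,
                              peak_amplitude=1.0, return_fraction=0.85)
    arch_b = tm.ArchetypeSpec("transient_decrease", peak_time=90,
                              peak_amplitude=1.0, return_fraction=0.0)
    wins = 0
    for seed in range(5):
        spec = tm.GeneratorSpec(
            n_subjects=20,
            groups=[("amino acid", 6, arch_a), ("lipid", 6, arch_b)],
            shape_noise_sd=0.08,
            within_group_corr=0.3,
            baseline_cv=0.2,
            bridge=("amino acid", "lipid"),
            seed=seed,
        )
        ds, _ = tm.generate_dataset(spec)
        mat, _ = tm.tpsm(tm.difference_from_fasting(ds))
        mg = analyse_network(mat, ds.groups)
        top = max(mg.betweenness, key=mg.betweenness.get)
        if top.startswith("bridge"):
            wins += 1
    assert wins >= 4
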