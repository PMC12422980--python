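"""SWC parsing, key nodes, region assignment and connectivity maps."""

import numpy as np
import pandas as pd
import pytest

from stereoatlas import neuron_mapper as nm
from stereoatlas import phantom


def swc_text(rows):
    return "# test neuron\n" + "\n".join(" ".join(str(v) for v in r) for r in rows) + "\n"


def write(tmp_path, rows, name="n.swc"):
    path = tmp_path / name
    path.write_text(swc_text(rows))
    return path


class TestReadSwc:
    def test_minimal_three_node_path(self, tmp_path):
        path = write(tmp_path, [
            (1, 1, 0, 0, 0, 5, -1),
            (2, 2, 10, 0, 0, 1, 1),
            (3, 2, 20, 0, 0, 1, 2),
        ])
        neuron = nm.read_swc(path)
        assert len(neuron.nodes) == 3
        assert neuron.root_id == 1
        assert int(neuron.nodes.iloc[0]["type"]) == 1

    def test_phantom_neuron_round_trip(self, world, neurons_and_truth, tmp_path):
        neurons, _ = neurons_and_truth
        original = neurons[0]
        path = tmp_path / "round.swc"
        nm.write_swc(path, original)
        loaded = nm.read_swc(path, neuron_id=original.neuron_id)
        assert len(loaded.nodes) == len(original.nodes)
        assert loaded.nodes["parent"].tolist() == original.nodes["parent"].tolist()
        assert np.allclose(loaded.nodes[["x", "y", "z"]], original.nodes[["x", "y", "z"]],
                           atol=1e-3)

    def test_dangling_parent_rejected(self, tmp_path):
        path = write(tmp_path, [
            (1, 1, 0, 0, 0, 5, -1),
            (5, 2, 10, 0, 0, 1, 99),
        ])
        with pytest.raises(nm.SwcParseError, match="99"):
            nm.read_swc(path)

    def test_multiple_roots_rejected(self, tmp_path):
        path = write(tmp_path, [
            (1, 1, 0, 0, 0, 5, -1),
            (2, 2, 1, 0, 0, 1, -1),
        ])
        with pytest.raises(nm.SwcParseError, match="one root"):
            nm.read_swc(path)

    def test_bad_column_count_reports_line(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\n2 2 0 0\n")
        with pytest.raises(nm.SwcParseError, match=":2:"):
            nm.read_swc(path)


class TestKeyNodes:
    def chain(self, n):
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
        for i in range(2, n + 1):
            rows.append((i, 2, float(i * 10), 0.0, 0.0, 1.0, i - 1))
        return nm.NeuronMorphology(
            nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="chain")

    def test_unbranched_cable(self):
        keys = nm.key_nodes(self.chain(10))
        assert keys.soma == 1
        assert keys.branch_points == []
        assert keys.terminals == [10]

    def test_perfect_binary_tree_counts_by_degree_enumeration(self):
        """Binary tree of depth 3 rooted at the soma: brute-force child
        degrees give the expected key-node partition (soma excluded from the
        branch points even though it has two children)."""
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
        next_id = 2
        frontier = [1]
        for _depth in range(3):
            new_frontier = []
            for parent in frontier:
                for _ in range(2):
                    rows.append((next_id, 2, float(next_id), 0.0, 0.0, 1.0, parent))
                    new_frontier.append(next_id)
                    next_id += 1
            frontier = new_frontier
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="tree")
        # independent oracle: count children per node directly
        children = {}
        for r in rows:
            children.setdefault(r[6], []).append(r[0])
        oracle_branch = sorted(i for r in rows for i in [r[0]]
                               if len(children.get(i, [])) >= 2 and i != 1)
        oracle_term = sorted(i for r in rows for i in [r[0]]
                             if not children.get(i) and i != 1)
        keys = nm.key_nodes(neuron)
        assert sorted(keys.branch_points) == oracle_branch
        assert sorted(keys.terminals) == oracle_term
        assert len(keys.terminals) == 8
        assert len(keys.branch_points) == 6  # internal non-soma nodes with 2 children

    def test_single_node_neuron(self):
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame([(1, 1, 0.0, 0.0, 0.0, 5.0, -1)],
                               columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="dot")
        keys = nm.key_nodes(neuron)
        assert keys.soma == 1 and keys.branch_points == [] and keys.terminals == []

    def test_soma_falls_back_to_root_without_type1(self):
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame([(4, 2, 0.0, 0.0, 0.0, 1.0, -1),
                                (5, 2, 1.0, 0.0, 0.0, 1.0, 4)],
                               columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="untyped")
        assert nm.key_nodes(neuron).soma == 4

    def test_terminal_leaf_accounting_random_trees(self, rng):
        """#terminals == #leaves − [soma is a leaf], on random parent trees."""
        for _ in range(10):
            n = int(rng.integers(2, 40))
            rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
            for i in range(2, n + 1):
                rows.append((i, 2, float(i), 0.0, 0.0, 1.0, int(rng.integers(1, i))))
            neuron = nm.NeuronMorphology(
                nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
                neuron_id="rand")
            keys = nm.key_nodes(neuron)
            parents = {r[6] for r in rows}
            leaves = [r[0] for r in rows if r[0] not in parents]
            assert len(keys.terminals) == len(leaves) - (1 in leaves)


class TestAssignRegions:
    def test_rows_match_generator_truth(self, world, neurons_and_truth, relation_tables):
        _neurons, truth = neurons_and_truth
        got = relation_tables[["neuron_id", "node_kind", "structure_id"]]
        key = ["neuron_id", "node_kind", "structure_id"]
        assert (got.sort_values(key).reset_index(drop=True)
                .equals(truth.sort_values(key).reset_index(drop=True)))

    def test_row_conservation(self, neurons_and_truth, relation_tables):
        neurons, _ = neurons_and_truth
        expected = 0
        for neuron in neurons:
            keys = nm.key_nodes(neuron)
            expected += 1 + len(keys.branch_points) + len(keys.terminals)
        assert len(relation_tables) == expected

    def test_out_of_volume_terminal_labeled_outside(self, world, lookup):
        rows = [(1, 1, 1280.0, 905.0, 1505.0, 5.0, -1),
                (2, 2, -500.0, -500.0, -500.0, 1.0, 1)]
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="escapee")
        table = nm.assign_regions(lookup, world.ontology, neuron)
        terminal = table[table["node_kind"] == "terminal"].iloc[0]
        assert terminal["structure_id"] == 0 and terminal["acronym"] == "outside"

    def test_boundary_node_is_deterministic(self, world, lookup):
        """A node exactly on a voxel boundary resolves by the floor
        convention, identically across repeated runs."""
        rows = [(1, 1, 1280.0, 900.0, 1500.0, 5.0, -1)]  # exactly on boundaries
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="edge")
        sids = {nm.assign_regions(lookup, world.ontology, neuron)["structure_id"].iloc[0]
                for _ in range(3)}
        assert len(sids) == 1
        expected = int(world.annotation.data[128, 90, 150])
        assert sids == {expected}


class TestConnectivity:
    def test_multiplicity_counts_once_per_neuron(self, world, lookup):
        """Three terminals in the same target still count one neuron."""
        rows = [(1, 1, 1280.0, 905.0, 1505.0, 5.0, -1)]  # soma in NucA
        b = world.truth.structure_geometry["NucB"]["center"]
        for i, off in enumerate((-30.0, 0.0, 30.0), start=2):
            rows.append((i, 2, b[0] + off + 5.0, b[1] + 5.0, b[2] + 5.0, 1.0, 1))
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="multi")
        table = nm.assign_regions(lookup, world.ontology, neuron)
        ids = [world.ontology.id_of(a) for a in ("NucA", "NucB")]
        cmap = nm.connectivity_map(table, world.ontology, ids)
        assert cmap.count(ids[0], ids[1]) == 1
        weighted = nm.connectivity_map(table, world.ontology, ids, weighted=True)
        assert weighted.count(ids[0], ids[1]) == 3

    def test_full_matrix_matches_generator_tally(self, world, neurons_and_truth,
                                                 relation_tables):
        _, truth = neurons_and_truth
        ids = [world.ontology.id_of(a) for a in ("NucA", "NucB", "NucC")]
        cmap = nm.connectivity_map(relation_tables, world.ontology, ids)
        oracle = phantom.ground_truth_connectivity(truth, set(ids))
        assert cmap.counts == oracle

    def test_parent_level_rollup(self, world, relation_tables):
        """Counting directly at the parent level dominates every child pair
        and matches hierarchical membership."""
        onto = world.ontology
        deep = onto.id_of("Deep")
        leaf_ids = [onto.id_of(a) for a in ("NucA", "NucB", "NucC")]
        parent_map = nm.connectivity_map(relation_tables, onto, [deep])
        leaf_map = nm.connectivity_map(relation_tables, onto, leaf_ids)
        for (src, dst), n in leaf_map.counts.items():
            assert parent_map.count(deep, deep) >= n
        # neurons with soma and a terminal anywhere in Deep, counted directly
        somata = relation_tables[relation_tables["node_kind"] == "soma"]
        deep_members = onto.descendants(deep)
        direct = 0
        for neuron_id in somata["neuron_id"]:
            neuron_rows = relation_tables[relation_tables["neuron_id"] == neuron_id]
            soma_in = int(neuron_rows[neuron_rows["node_kind"] == "soma"]
                          ["structure_id"].iloc[0]) in deep_members
            term_in = any(int(s) in deep_members for s in
                          neuron_rows[neuron_rows["node_kind"] == "terminal"]["structure_id"])
            direct += int(soma_in and term_in)
        assert parent_map.count(deep, deep) == direct

    def test_unknown_structure_rejected(self, world, relation_tables):
        with pytest.raises(Exception, match="999"):
            nm.connectivity_map(relation_tables, world.ontology, [999])

    def test_determinism_byte_identical_tables(self, world, lookup, neurons_and_truth):
        neurons, _ = neurons_and_truth
        a = pd.concat([nm.assign_regions(lookup, world.ontology, n) for n in neurons])
        b = pd.concat([nm.assign_regions(lookup, world.ontology, n) for n in neurons])
        assert a.to_csv(index=False) == b.to_csv(index=False)


class TestQueries:
    def test_empty_region_has_no_connections(self, world, relation_tables):
        l1 = world.ontology.id_of("L1")  # no phantom neuron touches L1
        for direction in ("afferent", "efferent"):
            assert nm.query_connections(relation_tables, world.ontology, l1, direction).empty

    def test_afferent_efferent_partition(self, world, relation_tables):
        onto = world.ontology
        nucb = onto.id_of("NucB")
        efferents = nm.query_connections(relation_tables, onto, nucb, "efferent")
        afferents = nm.query_connections(relation_tables, onto, nucb, "afferent")
        # phantom recipes: n4, n5 have somata in NucB; n1, n2 target it from NucA
        assert set(efferents["neuron_id"]) == {"n4", "n5"}
        assert set(afferents["neuron_id"]) == {"n1", "n2"}

    def test_self_projection_is_efferent_not_afferent(self, world, lookup):
        a = world.truth.structure_geometry["NucA"]["center"]
        rows = [(1, 1, a[0] + 5, a[1] + 5, a[2] + 5, 5.0, -1),
                (2, 2, a[0] + 45, a[1] + 5, a[2] + 5, 1.0, 1)]
        neuron = nm.NeuronMorphology(
            nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]),
            neuron_id="selfie")
        table = nm.assign_regions(lookup, world.ontology, neuron)
        nuca = world.ontology.id_of("NucA")
        assert set(nm.query_connections(table, world.ontology, nuca, "efferent")["neuron_id"]) \
            == {"selfie"}
        assert nm.query_connections(table, world.ontology, nuca, "afferent").empty

    def test_bad_direction_rejected(self, world, relation_tables):
        with pytest.raises(ValueError, match="direction"):
            nm.query_connections(relation_tables, world.ontology,
                                 world.ontology.id_of("NucA"), "sideways")
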