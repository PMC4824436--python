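"""Tanimoto similarity, the two edge layers, styling and graph I/O."""

import numpy as np
import pytest

import metabodose as md
from metabodose.chem_network import Fingerprint, node_size
from metabodose.core_data import TableError
from metabodose.differential import DifferentialResult


def fp(bits, n_bits=16):
    return Fingerprint(bits=frozenset(bits), n_bits=n_bits)


class TestTanimoto:
    def test_identical_is_one(self):
        assert md.tanimoto(fp({1, 5, 9}), fp({1, 5, 9})) == 1.0

    def test_disjoint_is_zero(self):
        assert md.tanimoto(fp({1, 2}), fp({3, 4})) == 0.0

    def test_analytic_count(self):
        assert md.tanimoto(fp({1, 2, 3}), fp({2, 3, 4})) == 0.5

    def test_symmetric_and_bounded_on_random_fingerprints(self):
        rng = np.random.default_rng(50)
        fps = [
            fp(set(rng.choice(64, size=rng.integers(1, 20), replace=False)),
               n_bits=64)
            for _ in range(100)
        ]
        for i in range(0, 100, 7):
            for j in range(i + 1, 100, 11):
                s = md.tanimoto(fps[i], fps[j])
                assert s == md.tanimoto(fps[j], fps[i])
                assert 0.0 <= s <= 1.0

    def test_both_empty_is_error(self):
        with pytest.raises(TableError, match="empty"):
            md.tanimoto(fp(set()), fp(set()))

    def test_length_mismatch_is_error(self):
        with pytest.raises(TableError, match="length"):
            md.tanimoto(fp({1}, 16), fp({1}, 32))

    def test_matches_bit_array_oracle(self):
        """Set-based Tanimoto equals an independent packed-array route
        over all pairs of 100 random fingerprints."""
        rng = np.random.default_rng(51)
        arrays = rng.random((100, 128)) < 0.15
        arrays[arrays.sum(axis=1) == 0, 0] = True
        fps = [
            fp(set(np.flatnonzero(a)), n_bits=128) for a in arrays
        ]
        for i in range(100):
            for j in range(i + 1, 100):
                expected = (
                    np.logical_and(arrays[i], arrays[j]).sum()
                    / np.logical_or(arrays[i], arrays[j]).sum()
                )
                assert md.tanimoto(fps[i], fps[j]) == pytest.approx(
                    expected, abs=1e-12
                )


class TestHexRoundTrip:
    def test_hex_parse_and_emit(self):
        f = Fingerprint.from_hex("a1")  # 1010 0001
        assert f.bits == {0, 2, 7}
        assert f.to_hex() == "a1"

    def test_rdkit_smiles_path_self_similarity(self):
        f1 = Fingerprint.from_smiles("CSCCC(N)C(=O)O")   # methionine
        f2 = Fingerprint.from_smiles("CSCCC(N)C(=O)O")
        assert md.tanimoto(f1, f2) == 1.0
        assert f1.provenance == "computed-from-SMILES"
        assert f1.n_bits == 1024


class TestSimilarityLayer:
    def _toy_fps(self):
        return {
            "a": fp({1, 2, 3, 4}),
            "b": fp({1, 2, 3, 4}),
            "c": fp({1, 2, 3, 5}),
            "d": fp({9, 10}),
            "e": fp({1, 9}),
        }

    def test_threshold_one_only_identical(self):
        edges = md.build_similarity_layer(self._toy_fps(), 1.0)
        assert {(a, b) for a, b, _ in edges} == {("a", "b")}

    def test_equals_exhaustive_all_pairs(self):
        fps = self._toy_fps()
        threshold = 0.5
        expected = set()
        names = sorted(fps)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                s = md.tanimoto(fps[a], fps[b])
                if s >= threshold:
                    expected.add((a, b, s))
        assert md.build_similarity_layer(fps, threshold) == expected

    def test_threshold_zero_rejected(self):
        with pytest.raises(TableError, match="threshold"):
            md.build_similarity_layer(self._toy_fps(), 0.0)

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(52)
        fps = {
            f"m{i}": fp(
                set(rng.choice(32, size=rng.integers(2, 12), replace=False)),
                n_bits=32,
            )
            for i in range(20)
        }
        counts = [
            len(md.build_similarity_layer(fps, t))
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestReactionLayer:
    def test_pair_retained_dedup_and_drop(self, tmp_path):
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text(
            "Methionine\t5'-Methylthioadenosine\n"
            "5'-Methylthioadenosine\tMethionine\n"
            "Methionine\tAbsentine\n"
        )
        edges = md.build_reaction_layer(
            pairs, {"Methionine", "5'-Methylthioadenosine"}
        )
        assert edges == {("5'-Methylthioadenosine", "Methionine")}

    def test_malformed_line_reports_number(self, tmp_path):
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text("A\tB\nonly-one-field\n")
        with pytest.raises(TableError, match=":2"):
            md.build_reaction_layer(pairs, {"A", "B"})

    def test_packaged_fixture_loads(self):
        from metabodose.fixtures import demo_reaction_pairs_path

        cohort = {r.metabolite for r in md.load_table1()}
        edges = md.build_reaction_layer(demo_reaction_pairs_path(), cohort)
        assert ("5'-Deoxy-5'-methylthioadenosine", "Methionine") in edges
        # pairs with endpoints outside the printed panel are dropped
        assert all(a in cohort and b in cohort for a, b in edges)


class TestAssembleNetwork:
    def test_table1_styling(self):
        results = md.load_table1()
        graph = md.assemble_network(set(), set(), results)
        xa = graph.nodes["Xanthurenic acid"]
        assert xa["node_color"] == "red"
        sizes = {n: graph.nodes[n]["node_size"] for n in graph.nodes}
        assert max(sizes, key=sizes.get) == "Xanthurenic acid"
        met = graph.nodes["Methionine"]
        assert met["node_color"] == "blue"

    def test_insignificant_node_uncolored(self):
        results = [DifferentialResult("m", 0.2, 2.0, False)]
        graph = md.assemble_network(set(), set(), results)
        assert "node_color" not in graph.nodes["m"]

    def test_pair_in_both_layers_two_tagged_edges(self):
        results = [
            DifferentialResult("a", 0.01, 2.0, True),
            DifferentialResult("b", 0.01, 0.5, True),
        ]
        graph = md.assemble_network(
            {("a", "b", 0.8)}, {("a", "b")}, results
        )
        layers = {d["layer"] for _, _, d in graph.edges(data=True)}
        assert graph.number_of_edges("a", "b") == 2
        assert layers == {"similarity", "reaction_pair"}

    def test_unknown_endpoint_is_error(self):
        results = [DifferentialResult("a", 0.01, 2.0, True)]
        with pytest.raises(TableError, match="ghost"):
            md.assemble_network({("a", "ghost", 0.9)}, set(), results)

    def test_node_size_monotone(self):
        sizes = [node_size(x) for x in (0.0, 0.5, 1.0, 3.0, 10.0)]
        assert sizes == sorted(sizes)
        assert sizes[-1] <= 60.0


class TestGraphIO:
    def _network(self):
        results = md.load_table1()
        cohort = {r.metabolite for r in results}
        annotations = md.read_annotations(
            __import__("metabodose.fixtures", fromlist=["x"])
            .demo_annotations_path()
        )
        fps = md.fingerprints_from_annotations(
            {n: a for n, a in annotations.items() if n in cohort}
        )
        similarity = md.build_similarity_layer(fps, 0.7)
        from metabodose.fixtures import demo_reaction_pairs_path

        reaction = md.build_reaction_layer(demo_reaction_pairs_path(), cohort)
        return md.assemble_network(similarity, reaction, results)

    def test_sif_round_trip_preserves_topology(self, tmp_path):
        graph = self._network()
        path = tmp_path / "net.sif"
        md.write_sif(graph, path)
        back = md.read_sif(path)
        assert set(back.nodes) == set(graph.nodes)
        want = {(min(a, b), max(a, b), d["layer"])
                for a, b, d in graph.edges(data=True)}
        got = {(min(a, b), max(a, b), d["layer"])
               for a, b, d in back.edges(data=True)}
        assert want == got

    def test_graphml_round_trip_identical_attributes(self, tmp_path):
        graph = self._network()
        path = tmp_path / "net.graphml"
        md.write_graphml(graph, path)
        back = md.read_graphml(path)
        assert set(back.nodes) == set(graph.nodes)
        for node in graph.nodes:
            for key, value in graph.nodes[node].items():
                if isinstance(value, float):
                    assert back.nodes[node][key] == pytest.approx(value)
                else:
                    assert back.nodes[node][key] == value
        assert back.number_of_edges() == graph.number_of_edges()

    def test_similarity_edges_present_in_demo_cohort(self):
        """Structurally close pairs (e.g. the C18+ fatty acids) clear the
        0.7 Tanimoto cutoff with Morgan fingerprints."""
        graph = self._network()
        sim_pairs = {
            frozenset((a, b))
            for a, b, d in graph.edges(data=True)
            if d["layer"] == "similarity"
        }
        assert frozenset(("Stearic acid", "Arachidic acid")) in sim_pairs
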