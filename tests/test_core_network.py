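"""Network/annotation I/O, normalization and basic graph queries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdset.core_network import (
    ComplexCatalog,
    ParseError,
    ProteinNetwork,
    connected_components,
    network_summary,
    read_class_annotation,
    read_complex_catalog,
    read_edge_list,
    read_gene_set,
    write_class_annotation,
    write_complex_catalog,
    write_edge_list,
    write_gene_set,
)
from mdset.core_network import GeneSet

from conftest import flood_fill_components, random_network


class TestEdgeList:
    def test_normalization_drops_loops_and_duplicates(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\nC\tC\nA\tB\n")
        net = read_edge_list(p)
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B")}
        assert net.n_self_loops_dropped == 1
        assert net.n_duplicates_merged == 2

    def test_adjacency_is_symmetric(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tC\n")
        net = read_edge_list(p)
        assert net.neighbors("B") == {"A", "C"}
        for u, v in net.edges:
            assert u in net.neighbors(v) and v in net.neighbors(u)

    def test_sif_dialect_ignores_relation(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A\tpp\tB\nB\tpd\tC\n")
        net = read_edge_list(p, dialect="sif")
        assert net.edges == {("A", "B"), ("B", "C")}

    @pytest.mark.parametrize("content", ["A\n", "A\tB\tC\n"])
    def test_malformed_line_names_line_number(self, tmp_path, content):
        p = tmp_path / "bad.tsv"
        p.write_text("# header\n" + content)
        with pytest.raises(ParseError, match=":2"):
            read_edge_list(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(ParseError):
            read_edge_list(p)

    @pytest.mark.parametrize("dialect", ["tsv-2col", "sif"])
    def test_round_trip(self, tmp_path, rng, dialect):
        net = random_network(100, 0.04, rng)
        p = tmp_path / "rt"
        write_edge_list(net, p, dialect=dialect)
        back = read_edge_list(p, dialect=dialect)
        assert back.edges == net.edges
        # isolated nodes are not expressible in an edge list
        assert back.nodes == {v for v in net.nodes if net.degree(v) > 0}


class TestGeneSetAndCatalog:
    def test_gene_set_collapses_duplicates(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("g1\ng2\ng1\n")
        assert read_gene_set(p).members == {"g1", "g2"}

    def test_empty_gene_set_warns_not_raises(self, tmp_path, caplog):
        p = tmp_path / "none.txt"
        p.write_text("")
        with caplog.at_level("WARNING"):
            gs = read_gene_set(p)
        assert gs.members == frozenset()
        assert any("empty" in r.message for r in caplog.records)

    def test_gene_set_round_trip(self, tmp_path, rng):
        gs = GeneSet(frozenset(f"g{i}" for i in rng.integers(0, 500, size=80)))
        p = tmp_path / "genes.txt"
        write_gene_set(gs, p)
        assert read_gene_set(p).members == gs.members

    def test_long_dialect_preserves_overlap(self, tmp_path):
        p = tmp_path / "cx.tsv"
        p.write_text("c1\tA\nc1\tB\nc2\tB\n")
        cat = read_complex_catalog(p, dialect="long")
        assert cat.n_complexes == 2
        assert cat.membership()["B"] == {"c1", "c2"}

    def test_wide_dialect(self, tmp_path):
        p = tmp_path / "cx.tsv"
        p.write_text("c1\tA;B;C\n")
        cat = read_complex_catalog(p, dialect="wide")
        assert cat.complexes["c1"] == {"A", "B", "C"}

    def test_unknown_dialect_and_empty_complex(self, tmp_path):
        p = tmp_path / "cx.tsv"
        p.write_text("c1\t;\n")
        with pytest.raises(ValueError):
            read_complex_catalog(p, dialect="weird")
        with pytest.raises(ParseError):
            read_complex_catalog(p, dialect="wide")
        with pytest.raises(ValueError):
            ComplexCatalog({"c1": frozenset()})

    @pytest.mark.parametrize("dialect", ["long", "wide"])
    def test_catalog_round_trip(self, tmp_path, rng, dialect):
        cat = ComplexCatalog(
            {
                f"c{i}": frozenset(
                    f"p{j}" for j in rng.choice(200, size=rng.integers(2, 12), replace=False)
                )
                for i in range(25)
            }
        )
        p = tmp_path / "cat.tsv"
        write_complex_catalog(cat, p, dialect=dialect)
        assert read_complex_catalog(p, dialect=dialect).complexes == cat.complexes

    def test_annotation_round_trip(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("p1\tKLT\np2\tJ\n")
        ann = read_class_annotation(p)
        assert ann.assignments["p1"] == {"K", "L", "T"}
        q = tmp_path / "ann2.tsv"
        write_class_annotation(ann, q)
        assert read_class_annotation(q).assignments == ann.assignments


class TestGraphQueries:
    def test_mean_degree_of_printed_study_counts(self):
        # 1,203 proteins / 1,938 binary interactions -> <k> = 3.22
        assert 2 * 1938 / 1203 == pytest.approx(3.22, abs=0.005)

    def test_summary_formula(self):
        tri = ProteinNetwork([("a", "b"), ("b", "c"), ("a", "c")])
        assert network_summary(tri).mean_degree == pytest.approx(2.0)
        star = ProteinNetwork([("z", f"l{i}") for i in range(4)])
        assert network_summary(star).mean_degree == pytest.approx(1.6)

    def test_summary_rejects_empty(self):
        with pytest.raises(ValueError):
            network_summary(ProteinNetwork())

    def test_components_small_cases(self):
        two = ProteinNetwork([("A", "B"), ("C", "D")])
        assert len(connected_components(two)) == 2
        path_iso = ProteinNetwork([("A", "B"), ("B", "C")], nodes=["D"])
        comps = connected_components(path_iso)
        assert len(comps) == 2
        assert {"D"} in comps

    def test_components_match_flood_fill(self, rng):
        for _ in range(5):
            net = random_network(50, 0.03, rng)
            got = sorted(map(sorted, connected_components(net)))
            want = sorted(map(sorted, flood_fill_components(net)))
            assert got == want

    def test_component_sizes_sum_to_node_count(self, rng):
        for p in (0.01, 0.05, 0.2):
            net = random_network(60, p, rng)
            assert sum(len(c) for c in connected_components(net)) == net.n_nodes


@given(
    edges=st.lists(
        st.tuples(st.integers(0, 15), st.integers(0, 15)), max_size=60
    )
)
@settings(max_examples=60, derandomize=True)
def test_normalization_is_idempotent(edges):
    named = [(f"p{a}", f"p{b}") for a, b in edges]
    once = ProteinNetwork(named)
    twice = ProteinNetwork(list(once.edges), nodes=once.nodes)
    assert twice.nodes == once.nodes
    assert twice.edges == once.edges
    assert twice.n_self_loops_dropped == 0
    assert twice.n_duplicates_merged == 0
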