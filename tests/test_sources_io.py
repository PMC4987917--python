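"""Readers, writers and invariants of the four evidence-source formats."""

import numpy as np
import pytest

import priorank as pr
from priorank.errors import FormatError, ValidationError
from priorank.sources import (
    write_edge_list,
    write_gene_list,
    write_gmt,
    write_pair_scores,
    write_profile_tsv,
)


class TestGenome:
    def test_rejects_duplicates_and_empties(self):
        with pytest.raises(ValidationError):
            pr.Genome(["g1", "g1"])
        with pytest.raises(ValidationError):
            pr.Genome(["g1", ""])
        with pytest.raises(ValidationError):
            pr.Genome([])

    def test_iteration_order_is_insertion_order(self):
        g = pr.Genome(["b", "a", "c"])
        assert list(g) == ["b", "a", "c"]
        assert "a" in g and "z" not in g


class TestGeneList:
    def test_full_overlap(self, tmp_path, toy_genome):
        p = tmp_path / "seeds.txt"
        p.write_text("# comment\ng1\ng2\ng3\n")
        assert pr.read_gene_list(p, toy_genome) == {"g1", "g2", "g3"}

    def test_partial_overlap_warns(self, tmp_path, toy_genome, caplog):
        p = tmp_path / "seeds.txt"
        p.write_text("g1\ngX\n")
        with caplog.at_level("WARNING"):
            assert pr.read_gene_list(p, toy_genome) == {"g1"}
        assert "1 identifier(s)" in caplog.text

    def test_empty_intersection_raises_with_filename(self, tmp_path, toy_genome):
        p = tmp_path / "seeds.txt"
        p.write_text("gX\ngY\n")
        with pytest.raises(ValidationError, match="seeds.txt"):
            pr.read_gene_list(p, toy_genome)


class TestGMT:
    def test_basic(self, tmp_path, toy_genome):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tg1\tg2\n")
        src = pr.read_gmt(p, toy_genome)
        assert src.term_to_genes == {"T1": frozenset({"g1", "g2"})}
        assert src.term_descriptions["T1"] == "desc"

    def test_unknown_genes_drop_term(self, tmp_path, toy_genome, caplog):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tgX\n")
        with caplog.at_level("WARNING"):
            src = pr.read_gmt(p, toy_genome)
        assert src.term_to_genes == {}
        assert "dropped" in caplog.text

    def test_duplicate_term_raises(self, tmp_path, toy_genome):
        p = tmp_path / "a.gmt"
        p.write_text("T1\td\tg1\nT1\td\tg2\n")
        with pytest.raises(FormatError, match="duplicate term"):
            pr.read_gmt(p, toy_genome)

    def test_malformed_line_reports_line_number(self, tmp_path, toy_genome):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tg1\nT2-without-fields\n")
        with pytest.raises(FormatError, match=":2"):
            pr.read_gmt(p, toy_genome)


class TestProfile:
    def test_shape(self, tmp_path, toy_genome):
        p = tmp_path / "prof.tsv"
        p.write_text("gene\tc1\tc2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        src = pr.read_profile_tsv(p, toy_genome)
        assert src.matrix.shape == (3, 2)
        assert src.condition_labels == ("c1", "c2")
        assert np.allclose(src.row("g2"), [3, 4])

    def test_duplicate_gene_row_raises(self, tmp_path, toy_genome):
        p = tmp_path / "prof.tsv"
        p.write_text("gene\tc1\tc2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(FormatError, match="duplicate"):
            pr.read_profile_tsv(p, toy_genome)

    def test_non_numeric_cell_raises(self, tmp_path, toy_genome):
        p = tmp_path / "prof.tsv"
        p.write_text("gene\tc1\tc2\ng1\t1\toops\n")
        with pytest.raises(FormatError, match="non-numeric"):
            pr.read_profile_tsv(p, toy_genome)


class TestEdgeList:
    def test_self_loop_dropped_with_warning(self, tmp_path, toy_genome, caplog):
        p = tmp_path / "net.tsv"
        p.write_text("geneA\tgeneB\tweight\ng1\tg1\t1.0\ng1\tg2\t2.0\n")
        with caplog.at_level("WARNING"):
            src = pr.read_edge_list(p, toy_genome)
        assert "self-loop" in caplog.text
        assert src.graph.number_of_edges() == 1
        assert src.graph["g1"]["g2"]["weight"] == 2.0

    def test_duplicate_edges_collapse_by_summing(self, tmp_path, toy_genome):
        p = tmp_path / "net.tsv"
        p.write_text("geneA\tgeneB\tweight\ng1\tg2\t1.5\ng2\tg1\t2.5\n")
        src = pr.read_edge_list(p, toy_genome)
        assert src.graph["g1"]["g2"]["weight"] == pytest.approx(4.0)

    def test_default_weight_is_one(self, tmp_path, toy_genome):
        p = tmp_path / "net.tsv"
        p.write_text("geneA\tgeneB\ng1\tg2\n")
        src = pr.read_edge_list(p, toy_genome)
        assert src.graph["g1"]["g2"]["weight"] == 1.0


class TestPairScores:
    def test_asymmetric_duplicate_raises(self, tmp_path, toy_genome):
        p = tmp_path / "sim.tsv"
        p.write_text("geneA\tgeneB\tscore\ng1\tg2\t5\ng2\tg1\t7\n")
        with pytest.raises(ValidationError, match="asymmetric duplicate"):
            pr.read_pair_scores(p, toy_genome)

    def test_symmetric_duplicate_collapses(self, tmp_path, toy_genome):
        p = tmp_path / "sim.tsv"
        p.write_text("geneA\tgeneB\tscore\ng1\tg2\t5\ng2\tg1\t5\n")
        src = pr.read_pair_scores(p, toy_genome)
        assert src.pair_scores == {("g1", "g2"): 5.0}

    def test_negative_score_raises(self, tmp_path, toy_genome):
        p = tmp_path / "sim.tsv"
        p.write_text("geneA\tgeneB\tscore\ng1\tg2\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            pr.read_pair_scores(p, toy_genome)


@pytest.mark.parametrize("kind", ["annotation", "profile", "network", "similarity", "genelist"])
def test_round_trip(kind, tmp_path, default_dataset):
    """Write-then-read reproduces an identical in-memory structure."""
    ds = default_dataset
    genome = ds.genome
    if kind == "annotation":
        p = tmp_path / "a.gmt"
        write_gmt(p, ds.annotation)
        back = pr.read_gmt(p, genome, name=ds.annotation.name)
        assert back.term_to_genes == ds.annotation.term_to_genes
    elif kind == "profile":
        p = tmp_path / "p.tsv"
        write_profile_tsv(p, ds.profile)
        back = pr.read_profile_tsv(p, genome, name=ds.profile.name)
        assert back.genes == ds.profile.genes
        assert back.condition_labels == ds.profile.condition_labels
        assert np.allclose(back.matrix, ds.profile.matrix, rtol=1e-9)
    elif kind == "network":
        p = tmp_path / "n.tsv"
        write_edge_list(p, ds.network)
        back = pr.read_edge_list(p, genome, name=ds.network.name)
        assert set(back.graph.edges) == set(ds.network.graph.edges)
        for u, v, d in back.graph.edges(data=True):
            assert d["weight"] == pytest.approx(ds.network.graph[u][v]["weight"])
    elif kind == "similarity":
        p = tmp_path / "s.tsv"
        write_pair_scores(p, ds.similarity)
        back = pr.read_pair_scores(p, genome, name=ds.similarity.name)
        assert back.pair_scores.keys() == ds.similarity.pair_scores.keys()
        assert all(
            back.pair_scores[k] == pytest.approx(ds.similarity.pair_scores[k], rel=1e-9)
            for k in back.pair_scores
        )
    else:
        p = tmp_path / "g.txt"
        write_gene_list(p, ds.module_genes)
        assert pr.read_gene_list(p, genome) == set(ds.module_genes)


def test_loading_is_order_independent(tmp_path, toy_genome):
    """Permuting input lines yields identical sources."""
    lines = ["T1\td\tg1\tg2", "T2\td\tg3", "T3\td\tg4\tg5\tg6"]
    p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
    p1.write_text("\n".join(lines) + "\n")
    p2.write_text("\n".join(reversed(lines)) + "\n")
    s1 = pr.read_gmt(p1, toy_genome, name="x")
    s2 = pr.read_gmt(p2, toy_genome, name="x")
    assert s1.term_to_genes == s2.term_to_genes
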