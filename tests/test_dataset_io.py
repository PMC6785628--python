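"""Alignment/tree/table I/O, gene partitioning, translation, depth classes."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitosel.alignment import Alignment, AlignmentError
from mitosel.dataset_io import (GeneCoordinate, SpeciesRecord,
                                classify_deep_sea, partition_genes,
                                read_depth_table, translate_mt)
from mitosel.trees import PhyloTree, TreeError


class TestAlignmentIO:
    def test_fasta_parse_and_gap(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>b\nAC-T\n")
        aln = Alignment.read(p)
        assert aln.names == ["a", "b"]
        assert aln.data.shape == (2, 4)
        assert aln.data[1, 2] == "-"

    def test_lowercase_normalised(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nacgt\n")
        assert Alignment.read(p).sequence("a") == "ACGT"

    def test_round_trip(self, tmp_path, rng):
        data = rng.choice(list("ACGT-"), size=(3, 12))
        aln = Alignment(["t1", "t2", "t3"], data)
        aln.write(tmp_path / "rt.fasta")
        assert Alignment.read(tmp_path / "rt.fasta") == aln

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentError, match="ragged"):
            Alignment.from_records([("a", "ACGT"), ("b", "ACG")])

    def test_duplicate_names_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            Alignment.from_records([("a", "ACGT"), ("a", "ACGT")])

    def test_phylip_relaxed(self, tmp_path):
        p = tmp_path / "x.phy"
        p.write_text(" 2 4\nlongname_one  ACGT\nlongname_two  AC-T\n")
        aln = Alignment.read(p)
        assert aln.names == ["longname_one", "longname_two"]


class TestPartitionGenes:
    def _alignment(self):
        # reference 30 nt, one insertion column (ref gap) at alignment col 5
        ref = "AAAAA" + "-" + "A" * 25
        other = "CCCCC" + "G" + "C" * 25
        return Alignment.from_records([("ref", ref), ("q", other)])

    def test_interval_columns(self):
        aln = self._alignment()
        out = partition_genes(aln, [GeneCoordinate("G", 4, 12)], "ref",
                              trim_to_codon=False)
        sub = out["G"]
        assert sub.n_columns == 9
        assert list(sub.reference_map) == list(range(4, 13))

    def test_insertion_column_excluded(self):
        aln = self._alignment()
        out = partition_genes(aln, [GeneCoordinate("G", 1, 30)], "ref",
                              trim_to_codon=False)
        # 31 alignment columns, one is an insertion relative to the reference
        assert out["G"].n_columns == 30
        assert "G" not in out["G"].sequence("q")[:6]

    def test_adjacent_genes_disjoint_and_covering(self):
        aln = self._alignment()
        coords = [GeneCoordinate("G1", 1, 9), GeneCoordinate("G2", 10, 18)]
        out = partition_genes(aln, coords, "ref", trim_to_codon=False)
        maps = [set(out["G1"].reference_map), set(out["G2"].reference_map)]
        assert maps[0] & maps[1] == set()
        assert maps[0] | maps[1] == set(range(1, 19))

    def test_minus_strand_reverse_complemented(self):
        aln = Alignment.from_records([("ref", "ATGAAATTT"), ("q", "ATGAAATTT")])
        out = partition_genes(aln, [GeneCoordinate("G", 1, 9, "-")], "ref")
        assert out["G"].sequence("q") == "AAATTTCAT"

    def test_interval_past_reference_rejected(self):
        aln = self._alignment()
        with pytest.raises(ValueError, match="exceeds reference"):
            partition_genes(aln, [GeneCoordinate("G", 25, 40)], "ref")

    def test_trim_to_whole_codons(self):
        aln = self._alignment()
        out = partition_genes(aln, [GeneCoordinate("G", 1, 11)], "ref")
        assert out["G"].n_columns == 9


class TestTranslation:
    @pytest.mark.parametrize("codon,expected", [
        ("TGA", "W"),      # vertebrate-mito reassignment
        ("ATA", "M"),
        ("A-G", "X"),      # gap-containing codon -> missing
        ("ANG", "X"),
    ])
    def test_codon_rules(self, codon, expected):
        aln = Alignment.from_records([("a", codon)])
        assert translate_mt(aln).sequence("a") == expected

    def test_internal_stop_warns_and_is_missing(self):
        aln = Alignment.from_records([("a", "AGAAAA")])   # AGA = mito stop
        with pytest.warns(UserWarning, match="internal stop"):
            assert translate_mt(aln).sequence("a") == "XK"
        with pytest.raises(ValueError):
            translate_mt(aln, on_internal_stop="error")

    def test_terminal_stop_tolerated(self):
        aln = Alignment.from_records([("a", "AAATAA")])
        assert translate_mt(aln).sequence("a") == "KX"


class TestDeepSeaClassification:
    @pytest.mark.parametrize("dmax,expected", [
        (1500.0, "deep"), (500.0, "shallow"), (1000.0, "deep")])
    def test_threshold(self, dmax, expected):
        rec = SpeciesRecord("t", 0.0, dmax)
        assert classify_deep_sea([rec])["t"] == expected

    def test_missing_depth_excluded(self):
        rec = SpeciesRecord("t", 0.0, float("nan"))
        assert classify_deep_sea([rec]) == {}

    @given(st.floats(0, 8000), st.floats(0, 8000))
    def test_monotone_in_depth(self, d1, d2):
        lo, hi = sorted([d1, d2])
        out = classify_deep_sea([SpeciesRecord("a", 0, lo),
                                 SpeciesRecord("b", 0, hi)])
        assert not (out["a"] == "deep" and out["b"] == "shallow")

    def test_depth_table_round_trip(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("taxon_id\tdepth_min\tdepth_max\tgroup\n"
                     "s1\t10\t1200\tg1\ns2\t0\t300\tg1\n")
        recs = read_depth_table(p)
        assert [r.taxon_id for r in recs] == ["s1", "s2"]
        assert classify_deep_sea(recs) == {"s1": "deep", "s2": "shallow"}

    def test_inverted_depths_rejected(self):
        with pytest.raises(ValueError, match="depth_min"):
            SpeciesRecord("t", 100.0, 10.0)


class TestTrees:
    def test_parse_topology_and_length(self):
        t = PhyloTree.from_newick("((a:1,b:1):0.5,c:1);")
        assert sorted(t.leaf_labels) == ["a", "b", "c"]
        internal = [n for n in range(t.n_nodes)
                    if not t.is_leaf(n) and n != t.root]
        assert t.branch_length[internal[0]] == 0.5

    def test_foreground_tag(self):
        t = PhyloTree.from_newick("((a,b)#1,c);")
        (fg,) = t.foreground_nodes()
        assert sorted(t.labels[c] for c in t.children[fg]) == ["a", "b"]

    def test_round_trip_preserves_everything(self):
        s = "((a:0.1,b:0.2)#1:0.05,(c:0.3,d#1:0.15):0.2);"
        t1 = PhyloTree.from_newick(s)
        t2 = PhyloTree.from_newick(t1.to_newick())
        assert t1.to_newick() == t2.to_newick()
        assert sorted(t1.foreground_nodes()) == sorted(t2.foreground_nodes())
        assert np.allclose(sorted(t1.branch_length), sorted(t2.branch_length))

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(TreeError):
            PhyloTree.from_newick("((a,b),c;")

    def test_ancestry_queries(self):
        t = PhyloTree.from_newick("((a,b),(c,d));")
        a = t.node_of_label("a")
        c = t.node_of_label("c")
        assert t.on_same_path(t.root, a)
        assert not t.on_same_path(a, c)
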