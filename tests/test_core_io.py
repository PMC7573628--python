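import math

import numpy as np
import pytest

from plastburst.core_io import (
    AlignmentHit,
    FamilyCounts,
    NewickParseError,
    midpoint_root,
    parse_newick,
    read_blast_tab,
    read_codon_fasta,
    read_counts_table,
    read_annotations,
    resolve_polytomies,
    write_blast_tab,
    write_counts_table,
    write_newick,
)
from plastburst.synthetic import ANGIOSPERM_11_NEWICK, sim_family_tree_with_ks


class TestNewick:
    def test_two_leaf_tree_depths(self):
        tree = parse_newick("(A:1,B:1):0;")
        d = tree.depths()
        assert sorted(tree.leaf_names()) == ["A", "B"]
        assert all(abs(d[l] - 1.0) < 1e-12 for l in tree.leaves())

    def test_study_tree_is_ultrametric_with_11_leaves(self):
        tree = parse_newick(ANGIOSPERM_11_NEWICK)
        assert tree.n_leaves() == 11
        depths = tree.depths()
        leaf_depths = [depths[l] for l in tree.leaves()]
        assert max(leaf_depths) - min(leaf_depths) < 1e-9

    @pytest.mark.parametrize("bad", ["(A,(B,C);", "(A:1,A:1);", "((A,B)"])
    def test_malformed_or_duplicated_input_raises(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_preserves_lengths_and_topology(self, seed):
        tree, _, _ = sim_family_tree_with_ks(10, seed=seed)
        text = write_newick(tree)
        again = parse_newick(text)
        assert write_newick(again) == text
        d1, d2 = tree.leaf_distances(), again.leaf_distances()
        assert d1.keys() == d2.keys()
        assert all(abs(d1[k] - d2[k]) < 1e-9 for k in d1)


class TestMidpointRoot:
    def test_cherry_root_equidistant(self):
        rooted = midpoint_root(parse_newick("(A:1,B:1);"))
        d = rooted.depths()
        assert all(abs(d[l] - 1.0) < 1e-9 for l in rooted.leaves())

    def test_root_bisects_the_diameter_path(self):
        # diameter 6 realised by B..A? pairwise: A-B 5, A-C 3, B-C 6
        rooted = midpoint_root(parse_newick("((A:1,B:4):1,C:1);"))
        d = rooted.depths()
        by_name = {l.name: d[l] for l in rooted.leaves()}
        assert abs(by_name["B"] - 3.0) < 1e-9
        assert abs(by_name["C"] - 3.0) < 1e-9
        # total path lengths preserved
        dist = rooted.leaf_distances()
        assert abs(dist[("B", "C")] - 6.0) < 1e-9
        assert abs(dist[("A", "B")] - 5.0) < 1e-9

    def test_idempotent(self):
        once = midpoint_root(parse_newick("((A:1,B:4):1,C:1);"))
        twice = midpoint_root(once)
        d1 = once.leaf_distances()
        d2 = twice.leaf_distances()
        assert all(abs(d1[k] - d2[k]) < 1e-9 for k in d1)
        far1 = sorted(d1.values())[-1]
        far2 = sorted(d2.values())[-1]
        assert abs(far1 - far2) < 1e-9

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError):
            midpoint_root(parse_newick("((A,B),C);"))


class TestBlastTab:
    LINE = "cp\tscaf1\t98.5\t2000\t30\t0\t1\t2000\t5001\t7000\t0.0\t3600"

    def test_plus_strand_record(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE + "\n")
        (hit,) = read_blast_tab(p)
        assert hit.aln_length == 2000 and hit.strand == "+"
        assert (hit.sstart, hit.send) == (5001, 7000)

    def test_minus_strand_normalised(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("cp\tscaf1\t98.5\t2000\t30\t0\t1\t2000\t7000\t5001\t0.0\t3600\n")
        (hit,) = read_blast_tab(p)
        assert (hit.sstart, hit.send) == (5001, 7000)
        assert hit.strand == "-"

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE + "\n" + "\t".join(self.LINE.split("\t")[:11]) + "\n")
        with pytest.raises(ValueError, match=":2:"):
            read_blast_tab(p)

    def test_total_alignment_length_matches_line_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        lines = []
        for i in range(50):
            ln = int(rng.integers(50, 5000))
            s = int(rng.integers(1, 10**6))
            rev = rng.random() < 0.5
            a, b = (s + ln - 1, s) if rev else (s, s + ln - 1)
            lines.append(
                f"cp\tscaf{i % 7}\t{rng.uniform(70, 100):.2f}\t{ln}\t10\t0\t1\t{ln}\t{a}\t{b}\t1e-10\t{ln * 1.8:.1f}"
            )
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join(lines) + "\n")
        hits = read_blast_tab(p)
        oracle_total = sum(int(l.split("\t")[3]) for l in p.read_text().splitlines() if l)
        assert sum(h.aln_length for h in hits) == oracle_total
        # round trip
        q = tmp_path / "back.tsv"
        write_blast_tab(hits, q)
        assert [h.aln_length for h in read_blast_tab(q)] == [h.aln_length for h in hits]


class TestTables:
    def test_counts_roundtrip(self, tmp_path):
        fc = FamilyCounts(["f1", "f2"], ["A", "B", "C"], np.array([[1, 0, 2], [3, 1, 0]]))
        p = tmp_path / "counts.tsv"
        write_counts_table(fc, p)
        back = read_counts_table(p)
        assert back.shape == (2, 3)
        assert (back.counts == fc.counts).all()

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            FamilyCounts(["f1"], ["A"], np.array([[-1]]))

    def test_annotations_reader(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        ann = read_annotations(p)
        assert ann == {"g1": {"GO:1", "GO:2"}, "g2": {"GO:1"}}


class TestCodonFasta:
    def test_equal_in_frame_alignment(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\n" + "ATG" * 100 + "\n>b\n" + "ATA" * 100 + "\n")
        seqs = read_codon_fasta(p)
        assert {len(s) for s in seqs.values()} == {300}

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\n" + "A" * 300 + "\n>b\n" + "A" * 299 + "\n")
        with pytest.raises(ValueError, match="ragged"):
            read_codon_fasta(p)

    def test_frame_violation_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\n" + "A" * 301 + "\n>b\n" + "A" * 301 + "\n")
        with pytest.raises(ValueError, match="divisible by 3"):
            read_codon_fasta(p)


def test_resolve_polytomies_is_deterministic_and_binary():
    t1 = resolve_polytomies(parse_newick("(A:1,B:1,C:1,D:1);"))
    t2 = resolve_polytomies(parse_newick("(A:1,B:1,C:1,D:1);"))
    assert write_newick(t1) == write_newick(t2)
    assert all(len(n.children) in (0, 2) for n in t1.postorder())
    # inserted branches carry zero length: path lengths unchanged
    d = t1.leaf_distances()
    assert all(abs(v - 2.0) < 1e-12 for v in d.values())
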