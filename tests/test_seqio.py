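"""I/O layer: FASTA parsing, RNA normalization, structure interchange."""

import pytest
from hypothesis import given, settings, strategies as st

from acepamir import seqio
from acepamir.seqio import (
    PairTable,
    SequenceError,
    SequenceRecord,
    StructureError,
    normalize_to_rna,
    parse_dotbracket,
    read_fasta,
    write_fasta,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [("acgt", "ACGU"), ("ACGU", "ACGU"), ("AcGu", "ACGU"), ("TTTT", "UUUU")],
    )
    def test_uppercase_and_t_to_u(self, raw, expected):
        assert normalize_to_rna(raw) == expected

    def test_idempotent(self):
        once = normalize_to_rna("acgtnryk")
        assert normalize_to_rna(once) == once

    def test_ambiguity_preserved_and_flagged(self):
        rec = SequenceRecord(id="x", sequence="ANGT", source="EST")
        assert rec.sequence == "ANGU"
        assert rec.ambiguous

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            normalize_to_rna("")

    def test_bad_character_position_reported(self):
        with pytest.raises(SequenceError, match="position 3"):
            normalize_to_rna("AC!U")


class TestFasta:
    def test_read_normalizes_and_keeps_order(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a first\nAC\n>b\nGt\n")
        records = read_fasta(p)
        assert [r.id for r in records] == ["a", "b"]
        assert [r.sequence for r in records] == ["AC", "GU"]

    def test_single_record_t_to_u(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "ACGU"

    def test_duplicate_id_error_names_id(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACGU\n>a\nGGGG\n")
        with pytest.raises(SequenceError, match="'a'"):
            read_fasta(p)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(SequenceError):
            read_fasta(p)

    def test_roundtrip_identity(self, tmp_path):
        records = [
            SequenceRecord(id="long", sequence="AUGC" * 50, source="EST"),
            SequenceRecord(id="short", sequence="GGCC", source="EST", description="short desc"),
        ]
        p = tmp_path / "out.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in records]
        # wrapping at 70 columns
        longest = max(len(l) for l in p.read_text().splitlines())
        assert longest <= 71


class TestDotBracket:
    def test_simple_hairpin(self):
        pt = parse_dotbracket("(((...)))")
        assert pt.pairs() == [(1, 9), (2, 8), (3, 7)]
        assert all(pt[i] == 0 for i in (4, 5, 6))

    def test_all_unpaired(self):
        pt = parse_dotbracket(".........")
        assert pt.pairs() == []

    def test_unclosed_error_position(self):
        with pytest.raises(StructureError, match="position 1"):
            parse_dotbracket("(()")

    def test_unmatched_close_error(self):
        with pytest.raises(StructureError, match="position 1"):
            parse_dotbracket(")(")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_balanced_strings_roundtrip(self, seed):
        """PairTable invariants and roundtrip hold on random valid structures."""
        import random

        rng = random.Random(seed)
        # build a random balanced string
        out, stack = [], 0
        for _ in range(rng.randint(1, 60)):
            ch = rng.choice("(.)" if stack else "(.")
            if ch == "(":
                stack += 1
            elif ch == ")":
                stack -= 1
            out.append(ch)
        out.extend(")" * stack)
        s = "".join(out)
        pt = parse_dotbracket(s)
        # symmetry + no self pairs enforced by the constructor; roundtrip:
        assert pt.to_dotbracket() == s
        for i, j in pt.pairs():
            assert pt[j] == i and i != j


class TestCt:
    def test_ct_reader_matches_dotbracket(self, tmp_path):
        seq, struct = "GGGAAACCC", "(((...)))"
        pt = parse_dotbracket(struct)
        lines = [f"{len(seq)} synthetic"]
        for i, base in enumerate(seq, start=1):
            lines.append(f"{i} {base} {i-1} {i+1} {pt[i]} {i}")
        p = tmp_path / "x.ct"
        p.write_text("\n".join(lines) + "\n")
        got_seq, got_pt = seqio.read_ct(p)
        assert got_seq == seq
        assert got_pt.partner == pt.partner

    def test_truncated_ct_rejected(self, tmp_path):
        p = tmp_path / "bad.ct"
        p.write_text("5 broken\n1 G 0 2 0 1\n")
        with pytest.raises(StructureError):
            seqio.read_ct(p)


class TestDbn:
    def test_roundtrip_with_mfe(self, tmp_path):
        recs = [("h1", "GGGAAACCC", "(((...)))", -3.5), ("h2", "AAAA", "....", None)]
        p = tmp_path / "x.dbn"
        seqio.write_dotbracket(recs, p)
        back = seqio.read_dotbracket(p)
        assert back[0][:3] == recs[0][:3]
        assert back[0][3] == pytest.approx(-3.5)
        assert back[1][3] is None


class TestReports:
    def test_tsv_roundtrip(self, tmp_path):
        rows = [{"a": 1, "b": "x"}, {"a": 2, "b": "y"}]
        p = tmp_path / "r.tsv"
        seqio.write_tsv(rows, p)
        back = seqio.read_tsv(p)
        assert back == [{"a": "1", "b": "x"}, {"a": "2", "b": "y"}]

    def test_empty_report_header_only(self, tmp_path):
        p = tmp_path / "e.tsv"
        seqio.write_tsv([], p, columns=["a", "b"])
        assert p.read_text() == "a\tb\n"

    def test_newick_two_leaves(self):
        from acepamir.phylo import DistanceMatrix, nj_tree

        tree = nj_tree(DistanceMatrix(["A", "B"], [[0.0, 3.0], [3.0, 0.0]]))
        text = seqio.write_newick(tree)
        assert text == "(A:1.5,B:1.5):0;"

    def test_newick_roundtrip_topology(self, tmp_path):
        import dendropy

        from acepamir.phylo import DistanceMatrix, nj_tree

        labels = ["A", "B", "C", "D"]
        d = [
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ]
        tree = nj_tree(DistanceMatrix(labels, [[float(x) for x in r] for r in d]))
        p = tmp_path / "t.nwk"
        seqio.write_newick(tree, p)
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == labels
        # the A|B split survives the round trip
        clades = set()
        for node in parsed.preorder_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(leaves) < len(labels):
                clades.add(leaves)
        assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades
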