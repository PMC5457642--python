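"""Sequence parsing, random generation, bonding function, dot-bracket I/O."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nustile.nussinov import Structure
from nustile.sequence_io import (
    CrossingPairsError,
    FastaError,
    RNASequence,
    SequenceValidationError,
    bond_matrix,
    delta,
    dot_bracket,
    parse_dot_bracket,
    random_rna,
    read_fasta,
    read_structures,
    write_structure,
)

rna_text = st.text(alphabet="ACGU", min_size=1, max_size=40)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">s\nGCGC\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "s" and recs[0].residues == "GCGC" and recs[0].n == 4

    def test_multi_record_order_and_wrapping(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">a\nGCG\nC\n>b\nAU\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].residues == "GCGC"

    def test_lowercase_is_uppercased(self, tmp_path):
        p = tmp_path / "lc.fa"
        p.write_text(">s\ngcau\n")
        assert read_fasta(p)[0].residues == "GCAU"

    def test_invalid_symbol_names_record_and_position(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">rec1\nGCXG\n")
        with pytest.raises(SequenceValidationError, match=r"rec1.*position 2"):
            read_fasta(p)

    def test_dna_rejected_unless_flagged(self, tmp_path):
        p = tmp_path / "dna.fa"
        p.write_text(">d\nGCTA\n")
        with pytest.raises(SequenceValidationError):
            read_fasta(p)
        assert read_fasta(p, dna_ok=True)[0].residues == "GCUA"

    def test_malformed_file_names_line(self, tmp_path):
        p = tmp_path / "notfasta.fa"
        p.write_text("GCGC\n>late\nAU\n")
        with pytest.raises(FastaError, match="line 1"):
            read_fasta(p)


class TestRandomRNA:
    def test_reproducible_and_valid(self):
        a = random_rna(100, seed=3)
        b = random_rna(100, seed=3)
        assert a.residues == b.residues and a.n == 100
        assert set(a.residues) <= set("ACGU")

    def test_length_one(self):
        assert random_rna(1, seed=7).n == 1

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            random_rna(0, seed=1)

    def test_symbol_frequencies_uniform(self):
        # each residue frequency within 5 sigma of 1/4 (binomial)
        n = 100_000
        seq = random_rna(n, seed=11)
        sigma = (n * 0.25 * 0.75) ** 0.5
        for ch in "ACGU":
            assert abs(seq.residues.count(ch) - n / 4) < 5 * sigma


class TestDelta:
    @pytest.mark.parametrize(
        "residues,i,j,expected",
        [
            ("AU", 0, 1, 1),
            ("GU", 0, 1, 1),
            ("GC", 0, 1, 1),
            ("AG", 0, 1, 0),
            ("AU", 1, 0, 0),  # i < j required
            ("AA", 0, 1, 0),
        ],
    )
    def test_bonding_rules(self, residues, i, j, expected):
        assert delta(RNASequence("x", residues), i, j) == expected

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            delta(RNASequence("x", "AU"), 0, 2)

    def test_min_loop_excludes_adjacent(self):
        seq = RNASequence("x", "AU")
        assert delta(seq, 0, 1, min_loop=1) == 0

    @given(rna_text)
    def test_positional_antisymmetry(self, residues):
        # residue-symmetric but zero whenever i >= j
        seq = RNASequence("x", residues)
        n = seq.n
        for i in range(n):
            assert delta(seq, i, i) == 0
            for j in range(i):
                assert delta(seq, i, j) == 0

    def test_all_a_has_no_bonds(self):
        seq = RNASequence("x", "A" * 12)
        assert bond_matrix(seq).sum() == 0

    @given(rna_text)
    def test_bond_matrix_matches_delta(self, residues):
        seq = RNASequence("x", residues)
        m = bond_matrix(seq)
        for i in range(seq.n):
            for j in range(seq.n):
                assert m[i, j] == delta(seq, i, j)


class TestDotBracket:
    def test_single_pair(self):
        st_ = Structure(pairs=frozenset({(0, 1)}))
        assert dot_bracket(st_, 2) == "()"

    def test_unpaired(self):
        assert dot_bracket(Structure(pairs=frozenset()), 4) == "...."

    def test_crossing_pairs_refused(self):
        st_ = Structure(pairs=frozenset({(0, 2), (1, 3)}))
        with pytest.raises(CrossingPairsError):
            dot_bracket(st_, 4)

    def test_round_trip_file(self, tmp_path):
        seq = RNASequence("s", "GAAC")
        st_ = Structure(pairs=frozenset({(0, 3)}))
        p = tmp_path / "out.db"
        write_structure(seq, st_, p)
        [(seq2, pairs)] = read_structures(p)
        assert seq2.residues == seq.residues and pairs == {(0, 3)}

    def test_parse_rejects_unbalanced(self):
        with pytest.raises(ValueError):
            parse_dot_bracket("(()")
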