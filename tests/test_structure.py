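"""Pair tables, cleavage windows, complementary sequences, encoders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dicersite.errors import BoundaryError, EncodingError, ValidationError
from dicersite.structure import (
    CleavagePattern,
    PreMiRNA,
    complementary_sequence,
    decode_pattern,
    decode_structure,
    encode_pattern,
    encode_structure,
    extract_window,
    make_pattern,
    pair_table,
    terminal_loop_midpoint,
)

from conftest import (
    MIR4704_BOND5,
    MIR4704_COMP,
    MIR4704_DOT,
    MIR4704_DOTPAT,
    MIR4704_PAT,
    MIR4704_START,
)


# -- pair tables -----------------------------------------------------------


def brute_force_pairs(structure: str) -> list:
    """Independent oracle: repeatedly erase innermost '(.*)'-free pairs."""
    partner = [0] * (len(structure) + 1)
    chars = list(structure)
    changed = True
    while changed:
        changed = False
        open_pos = None
        for i, ch in enumerate(chars, 1):
            if ch == "(":
                open_pos = i
            elif ch == ")":
                assert open_pos is not None, "unbalanced"
                partner[i], partner[open_pos] = open_pos, i
                chars[i - 1] = chars[open_pos - 1] = "*"
                changed = True
                break
    assert "(" not in chars and ")" not in chars, "unbalanced"
    return partner


@st.composite
def balanced_dotbrackets(draw):
    """Random balanced dot-bracket strings (possibly nested/branched)."""
    def grow(depth):
        if depth > 4:
            return "." * draw(st.integers(0, 3))
        parts = []
        for _ in range(draw(st.integers(1, 3))):
            kind = draw(st.sampled_from(["dots", "pair"]))
            if kind == "dots":
                parts.append("." * draw(st.integers(0, 4)))
            else:
                parts.append("(" + grow(depth + 1) + ")")
        return "".join(parts)

    return grow(0)


class TestPairTable:
    def test_single_pair(self):
        assert pair_table("(...)").tolist() == [0, 5, 0, 0, 0, 1]

    def test_all_unpaired(self):
        assert pair_table(".....").tolist() == [0] * 6

    def test_published_structure(self):
        partner = pair_table(MIR4704_DOT)
        assert partner[25] == 51
        assert all(partner[i] == 0 for i in range(33, 39))

    @pytest.mark.parametrize("bad, pos", [(".).", 2), ("((.)", 1)])
    def test_unbalanced_reports_offending_index(self, bad, pos):
        with pytest.raises(ValidationError, match=str(pos)):
            pair_table(bad)

    @settings(max_examples=200, deadline=None)
    @given(balanced_dotbrackets())
    def test_agrees_with_brute_force_oracle(self, structure):
        assert pair_table(structure).tolist() == brute_force_pairs(structure)

    @settings(max_examples=100, deadline=None)
    @given(balanced_dotbrackets())
    def test_involution_and_count_invariants(self, structure):
        partner = pair_table(structure)
        for i in range(1, len(structure) + 1):
            if partner[i]:
                assert partner[partner[i]] == i
                assert partner[i] != i
        n_paired = int((partner[1:] > 0).sum())
        assert structure.count("(") == structure.count(")") == n_paired // 2


# -- windows and complementary sequences -----------------------------------


def _hairpin(seq, dot, b5=9, b3=None):
    return PreMiRNA("hp", seq, dot, b5, b3 if b3 else len(seq) - 7)


class TestWindows:
    def test_boundary_window_starts_at_position_one(self):
        pm = PreMiRNA("x", "ACGUACGUACGUACGUACGUA", "." * 21, 7, 14)
        start, pat, dotpat = extract_window(pm, 7)
        assert start == 1
        assert pat == pm.sequence[:14] and dotpat == pm.structure[:14]

    def test_published_window(self, mir4704):
        start, pat, dotpat = extract_window(mir4704, MIR4704_BOND5)
        assert start == MIR4704_START
        assert pat == MIR4704_PAT
        assert dotpat == MIR4704_DOTPAT

    def test_underflow_rejected(self, mir4704):
        with pytest.raises(BoundaryError):
            extract_window(mir4704, 6)
        with pytest.raises(BoundaryError):
            extract_window(mir4704, len(mir4704) - 6)

    def test_published_complementary_sequence(self, mir4704):
        assert complementary_sequence(mir4704, MIR4704_START) == MIR4704_COMP

    def test_fully_unpaired_window_is_all_O(self):
        pm = PreMiRNA("x", "ACGU" * 5, "." * 20, 7, 13)
        assert complementary_sequence(pm, 4) == "O" * 14

    def test_perfect_stem_window_pairs_each_base(self):
        seq5 = "ACGUGCAUCCGGAU"
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        seq = seq5 + "AAAA" + "".join(comp[c] for c in reversed(seq5))
        dot = "(" * 14 + "...." + ")" * 14
        pm = PreMiRNA("stem", seq, dot, 7, 25)
        out = complementary_sequence(pm, 1)
        assert out == "".join(comp[c] for c in seq5)

    def test_make_pattern_bundles_window_fields(self, mir4704):
        cp = make_pattern(mir4704, MIR4704_BOND5, arm=5, label=1)
        assert (cp.pat, cp.dotpat, cp.comp) == (
            MIR4704_PAT, MIR4704_DOTPAT, MIR4704_COMP
        )
        assert cp.start == MIR4704_START

    def test_terminal_loop_midpoint_of_symmetric_hairpin(self):
        dot = "(" * 10 + "." * 4 + ")" * 10
        # innermost pair is (10, 15); the enclosed loop midpoint is 12.5
        assert terminal_loop_midpoint(pair_table(dot)) == 12.5


# -- encoders --------------------------------------------------------------


class TestPatternEncoder:
    def test_published_entity_shape_and_round_trip(self):
        cp = CleavagePattern("id", 25, MIR4704_PAT, MIR4704_DOTPAT,
                             MIR4704_COMP, 5, 1)
        m = encode_pattern(cp)
        assert m.shape == (13, 14)
        assert np.all(m.sum(axis=0) == 3)  # one symbol per block per column
        assert decode_pattern(m) == (MIR4704_PAT, MIR4704_COMP, MIR4704_DOTPAT)

    def test_pattern_rows_never_use_O_channel(self):
        cp = CleavagePattern("id", 25, MIR4704_PAT, MIR4704_DOTPAT,
                             MIR4704_COMP, 5, 1)
        m = encode_pattern(cp)
        assert m[4].sum() == 0  # row 5 is the O channel of the Pat block

    def test_symbol_outside_alphabet_rejected(self):
        cp = CleavagePattern("id", 1, "ANGUACGUACGUAC", "." * 14, "O" * 14, 5, 0)
        with pytest.raises(EncodingError):
            encode_pattern(cp)

    def test_O_in_pattern_sequence_rejected(self):
        cp = CleavagePattern("id", 1, "AOGUACGUACGUAC", "." * 14, "O" * 14, 5, 0)
        with pytest.raises(EncodingError):
            encode_pattern(cp)


class TestStructureEncoder:
    def test_padding_layout(self):
        m = encode_structure("(.)")
        assert m.shape == (4, 200)
        assert np.all(m.sum(axis=0) == 1)
        assert m[3, :3].sum() == 0 and np.all(m[3, 3:] == 1)  # N channel

    def test_full_length_structure_has_no_padding(self):
        dot = "(" * 90 + "." * 20 + ")" * 90
        m = encode_structure(dot)
        assert m[3].sum() == 0

    def test_published_structure_padding_count(self):
        m = encode_structure(MIR4704_DOT)
        assert m[3].sum() == 200 - 75

    def test_overlong_structure_rejected(self):
        with pytest.raises(EncodingError, match="201"):
            encode_structure("." * 201)

    @settings(max_examples=50, deadline=None)
    @given(balanced_dotbrackets())
    def test_round_trip(self, structure):
        assert decode_structure(encode_structure(structure)) == structure
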