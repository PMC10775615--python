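"""Secondary-structure handling and one-hot encoders.

A dot-bracket string is turned into a *pair table* (1-based partner indices,
0 for unpaired). From a pre-miRNA and a cleavage bond we extract the 14-nt
*cleavage window*: the bond between nucleotides ``b`` and ``b+1`` sits
exactly between window positions 7 and 8, so the window spans nucleotides
``b-6 .. b+7``. The *complementary sequence* of a window lists, position by
position, the base paired with each window position, or ``O`` where the
position is unpaired.

Two encoders produce the model inputs:

* ``encode_pattern``: a 13 x 14 one-hot matrix per window — rows 1-5 the
  pattern over (A, C, G, U, O), rows 6-10 the complementary sequence over
  the same alphabet, rows 11-13 the local structure over ("(", ".", ")").
  Every column sums to exactly 3 (one symbol per block).
* ``encode_structure``: a 4 x 200 one-hot matrix of a full dot-bracket
  string over the rows ("(", ")", ".", "N"), where positions beyond the
  structure length carry the padding symbol N.

The channel (row) orders above are fixed and recorded in checkpoint
metadata; they are part of the trained-model contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundaryError, EncodingError, ValidationError

__all__ = [
    "PATTERN_ALPHABET",
    "PATTERN_STRUCT_ALPHABET",
    "STRUCTURE_ALPHABET",
    "WINDOW_LEN",
    "MAX_STRUCT_LEN",
    "PreMiRNA",
    "CleavagePattern",
    "pair_table",
    "extract_window",
    "complementary_sequence",
    "make_pattern",
    "encode_pattern",
    "decode_pattern",
    "encode_structure",
    "decode_structure",
    "terminal_loop_midpoint",
]

PATTERN_ALPHABET = "ACGUO"
PATTERN_STRUCT_ALPHABET = "(.)"
STRUCTURE_ALPHABET = "()" + ".N"  # rows: ( ) . N
WINDOW_LEN = 14
MAX_STRUCT_LEN = 200


def pair_table(structure: str) -> np.ndarray:
    """Partner indices for a dot-bracket string.

    Returns a 1-based int array ``partner`` of length L+1 (index 0 unused):
    ``partner[i]`` is the position paired with i, or 0 if i is unpaired.
    """
    partner = np.zeros(len(structure) + 1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure, 1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValidationError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif ch != ".":
            raise ValidationError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise ValidationError(f"unmatched '(' at position {stack[0]}")
    return partner


@dataclass
class PreMiRNA:
    """A pre-miRNA hairpin with its structure and two annotated cleavage bonds.

    ``bond5``/``bond3`` are 1-based bond indices: bond *b* is the
    phosphodiester bond between nucleotides *b* and *b+1*.
    """

    id: str
    sequence: str
    structure: str
    bond5: int
    bond3: int
    pairs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValidationError(
                f"{self.id}: sequence/structure length mismatch "
                f"({len(self.sequence)} vs {len(self.structure)})"
            )
        if self.pairs is None:
            self.pairs = pair_table(self.structure)
        L = len(self.sequence)
        for name, b in (("bond5", self.bond5), ("bond3", self.bond3)):
            if not (7 <= b <= L - 7):
                raise ValidationError(
                    f"{self.id}: {name}={b} leaves no room for a 14-nt window "
                    f"(need 7 <= bond <= {L - 7})"
                )
        if not self.bond5 < self.bond3:
            raise ValidationError(f"{self.id}: bond5 must precede bond3")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavagePattern:
    """A 14-nt window with its local structure and complementary sequence."""

    source_id: str
    start: int  # 1-based position of the first window nucleotide
    pat: str
    dotpat: str
    comp: str
    arm: int  # 5 or 3
    label: int  # 0 negative, 1 positive (5' in multi-class), 2 positive 3'


def extract_window(pm: PreMiRNA, bond: int) -> tuple[int, str, str]:
    """The 14-nt window centred on a bond: nucleotides ``bond-6 .. bond+7``.

    Returns ``(start, pat, dotpat)`` with 1-based ``start = bond - 6``; the
    bond lies between window positions 7 and 8.
    """
    start = bond - 6
    if start < 1 or bond + 7 > len(pm):
        raise BoundaryError(
            f"{pm.id}: window for bond {bond} falls outside sequence "
            f"of length {len(pm)}"
        )
    pat = pm.sequence[start - 1 : start + 13]
    dotpat = pm.structure[start - 1 : start + 13]
    return start, pat, dotpat


def complementary_sequence(pm: PreMiRNA, start: int) -> str:
    """Position-wise pairing partners of the window starting at ``start``.

    Output position i is the base paired with window position i, or ``O``
    if that position is unpaired.
    """
    if start < 1 or start + WINDOW_LEN - 1 > len(pm):
        raise BoundaryError(
            f"{pm.id}: window starting at {start} falls outside sequence"
        )
    out = []
    for pos in range(start, start + WINDOW_LEN):
        j = pm.pairs[pos]
        out.append(pm.sequence[j - 1] if j else "O")
    return "".join(out)


def make_pattern(pm: PreMiRNA, bond: int, arm: int, label: int) -> CleavagePattern:
    """Build the full cleavage-pattern entity for the window centred on a bond."""
    start, pat, dotpat = extract_window(pm, bond)
    comp = complementary_sequence(pm, start)
    return CleavagePattern(pm.id, start, pat, dotpat, comp, arm, label)


def terminal_loop_midpoint(pairs: np.ndarray) -> float:
    """Midpoint of the terminal loop: the unpaired run enclosed by the
    innermost base pair of the hairpin.

    Used to assign windows to the 5' or 3' arm: a window belongs to the 5'
    arm iff its centre bond lies at or before this midpoint.
    """
    opens = [p for p in range(1, len(pairs)) if pairs[p] > p]
    if not opens:
        # no helix at all: split the molecule in half
        return (len(pairs) - 1) / 2.0
    i = min(opens, key=lambda p: pairs[p] - p)  # smallest enclosed span
    return (i + int(pairs[i])) / 2.0


def _one_hot(symbols: str, alphabet: str, what: str) -> np.ndarray:
    m = np.zeros((len(alphabet), len(symbols)))
    for col, ch in enumerate(symbols):
        row = alphabet.find(ch)
        if row < 0:
            raise EncodingError(
                f"symbol {ch!r} at position {col + 1} of {what} is outside "
                f"alphabet {alphabet!r}"
            )
        m[row, col] = 1.0
    return m


def encode_pattern(cp) -> np.ndarray:
    """One-hot encode a cleavage pattern into the 13 x 14 classifier input.

    Accepts any object with ``pat``, ``comp`` and ``dotpat`` attributes.
    """
    if len(cp.pat) != WINDOW_LEN:
        raise EncodingError(f"pattern must be {WINDOW_LEN} nt, got {len(cp.pat)}")
    if "O" in cp.pat:
        raise EncodingError("pattern sequence may not contain 'O'")
    blocks = [
        _one_hot(cp.pat, PATTERN_ALPHABET, "Pat"),
        _one_hot(cp.comp, PATTERN_ALPHABET, "Comp"),
        _one_hot(cp.dotpat, PATTERN_STRUCT_ALPHABET, "Dot-Pat"),
    ]
    return np.concatenate(blocks, axis=0)


def decode_pattern(matrix: np.ndarray) -> tuple[str, str, str]:
    """Invert :func:`encode_pattern`, returning ``(pat, comp, dotpat)``."""
    if matrix.shape != (13, WINDOW_LEN):
        raise EncodingError(f"expected a 13x{WINDOW_LEN} matrix, got {matrix.shape}")
    pat = "".join(PATTERN_ALPHABET[r] for r in matrix[0:5].argmax(axis=0))
    comp = "".join(PATTERN_ALPHABET[r] for r in matrix[5:10].argmax(axis=0))
    dotpat = "".join(PATTERN_STRUCT_ALPHABET[r] for r in matrix[10:13].argmax(axis=0))
    return pat, comp, dotpat


def encode_structure(structure: str, max_len: int = MAX_STRUCT_LEN) -> np.ndarray:
    """One-hot encode a dot-bracket string into a 4 x ``max_len`` matrix.

    Rows are ("(", ")", ".", "N"); columns beyond the structure length
    carry the padding symbol N.
    """
    L = len(structure)
    if L > max_len:
        raise EncodingError(
            f"structure of length {L} exceeds the maximum of {max_len}"
        )
    m = np.zeros((4, max_len))
    padded = structure + "N" * (max_len - L)
    for col, ch in enumerate(padded):
        row = STRUCTURE_ALPHABET.find(ch)
        if row < 0:
            raise EncodingError(
                f"symbol {ch!r} at position {col + 1} is outside alphabet "
                f"{STRUCTURE_ALPHABET!r}"
            )
        m[row, col] = 1.0
    return m


def decode_structure(matrix: np.ndarray) -> str:
    """Invert :func:`encode_structure`, stripping the N padding."""
    if matrix.ndim != 2 or matrix.shape[0] != 4:
        raise EncodingError(f"expected a 4xW matrix, got {matrix.shape}")
    chars = [STRUCTURE_ALPHABET[r] for r in matrix.argmax(axis=0)]
    out = "".join(chars)
    return out.rstrip("N")
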