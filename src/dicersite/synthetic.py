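"""Seeded stem-loop pre-miRNA simulator with ground-truth cleavage bonds.

Each simulated molecule is a single hairpin: a 5' stem strand, a terminal
loop, and the 3' stem strand, written 5'->3'. Pairing is taken from the
construction, not re-folded, so the dot-bracket structure is exact by
definition. Helix imperfections are modelled as *symmetric internal loops*:
a stem position is unpaired on both strands at once. This keeps the two
strands in perfect antiparallel register (position i always pairs with
L+1-i when paired), which in turn keeps the planted cleavage signal
self-consistent when the two positive windows pair with each other.

Cleavage geometry. The 5' cleavage bond is drawn uniformly over the
eligible bonds of the 5' arm (the same support negative windows are drawn
from, so that with the signal switched off the two classes are
statistically exchangeable); the 3' bond is coupled as ``bond3 = L + 2 -
bond5``, which makes the two 14-nt positive windows exact pairing partners
of each other.

Planted signal. With probability ``signal_strength`` per molecule, a fixed
4-mer motif is written at window positions 5-8 of both positive windows,
and two stem positions under window positions 12-13 of the 5' window are
opened into an internal loop (an unpaired-run cue). The default motif GAUC
is a reverse-complement palindrome, so the two planted copies agree with
Watson-Crick pairing wherever the windows pair with each other — base-pair
complementarity holds for every generated molecule at any signal strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .rnaio import (
    AnnotationRow,
    SeqRecord,
    ViennaRecord,
    write_annotations,
    write_fasta,
    write_vienna,
)
from .structure import PreMiRNA

__all__ = ["HairpinSpec", "generate_hairpin", "generate_corpus", "write_corpus"]

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {"G": "U", "U": "G"}  # G·U wobble partners


@dataclass
class HairpinSpec:
    """Parameters of the hairpin construction.

    stem_len / loop_len: inclusive ranges for the stem length (base pairs
    plus internal-loop positions) and terminal-loop length; defaults give
    total lengths of 40-132 nt, inside the 40-200 nt corpus bounds.
    bulge_prob: per-stem-position probability of a symmetric internal loop.
    wobble_prob: per-pair probability of a G·U wobble instead of Watson-Crick.
    offset5: inclusive range of the 5' cleavage-bond offset from the 5' end;
    the upper end is additionally capped at the terminal-loop midpoint.
    signal_strength: per-molecule probability of planting the cleavage
    signal (motif + unpaired run) around both cleavage bonds.
    motif: the 4-mer planted at window positions 5-8; the default is a
    reverse-complement palindrome (see module docstring).
    """

    stem_len: tuple[int, int] = (18, 60)
    loop_len: tuple[int, int] = (4, 12)
    bulge_prob: float = 0.08
    wobble_prob: float = 0.08
    min_length: int = 40
    max_length: int = 200
    offset5: tuple[int, int] = (9, 10_000)  # capped at the loop midpoint
    signal_strength: float = 1.0
    motif: str = "GAUC"

    def validate(self) -> None:
        if self.stem_len[0] < 10 or self.stem_len[0] > self.stem_len[1]:
            raise ValidationError(f"invalid stem_len range {self.stem_len}")
        if self.loop_len[0] < 3 or self.loop_len[0] > self.loop_len[1]:
            raise ValidationError(f"invalid loop_len range {self.loop_len}")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValidationError("signal_strength must lie in [0, 1]")
        if self.offset5[0] < 9:
            raise ValidationError(
                "offset5 must start at >= 9 so both 14-nt windows fit"
            )
        lo = 2 * self.stem_len[0] + self.loop_len[0]
        hi = 2 * self.stem_len[1] + self.loop_len[1]
        if lo < self.min_length or hi > self.max_length:
            raise ValidationError(
                f"stem/loop ranges give lengths {lo}-{hi}, outside "
                f"[{self.min_length}, {self.max_length}]"
            )
        if len(self.motif) != 4 or set(self.motif) - set(_BASES):
            raise ValidationError("motif must be a 4-mer over ACGU")


def _pair_base(base: str, rng: np.random.Generator, wobble_prob: float) -> str:
    if base in _WOBBLE and rng.random() < wobble_prob:
        return _WOBBLE[base]
    return _COMPLEMENT[base]


def generate_hairpin(spec: HairpinSpec, rng: np.random.Generator,
                     hp_id: str = "syn-0") -> PreMiRNA:
    """Draw one hairpin with annotated cleavage bonds from the spec."""
    spec.validate()
    s = int(rng.integers(spec.stem_len[0], spec.stem_len[1] + 1))
    loop = int(rng.integers(spec.loop_len[0], spec.loop_len[1] + 1))
    L = 2 * s + loop

    # paired[i] for stem positions 1..s; keep the closing pair intact so the
    # terminal loop stays well defined, and keep position 1 paired for a
    # clean helix end.
    paired = rng.random(s + 1) >= spec.bulge_prob
    paired[0] = False  # index 0 unused
    paired[1] = True
    paired[s] = True

    mid = s + loop / 2.0  # terminal-loop midpoint
    # cap the 5' offset one bond short of the midpoint so the two planted
    # motif regions (window positions 5-8 of each positive window) can
    # never overlap inside the terminal loop
    off_hi = min(spec.offset5[1], int(np.floor(mid)), (L - 2) // 2)
    if off_hi < spec.offset5[0]:
        raise ValidationError(
            f"{hp_id}: no eligible 5' cleavage offset in "
            f"[{spec.offset5[0]}, {off_hi}]"
        )
    bond5 = int(rng.integers(spec.offset5[0], off_hi + 1))
    bond3 = L + 2 - bond5  # the two positive windows pair with each other

    planted = rng.random() < spec.signal_strength
    if planted:
        # unpaired-run cue: open an internal loop under window positions
        # 12-13 of the 5' window (sequence positions bond5+5, bond5+6)
        for pos in (bond5 + 5, bond5 + 6):
            if 2 <= pos <= s - 1:
                paired[pos] = False

    # sequence: random 5' strand and loop, complementary 3' strand
    seq = [""] * (L + 1)  # 1-based
    for i in range(1, s + loop + 1):
        seq[i] = _BASES[rng.integers(4)]
    for i in range(s + loop + 1, L + 1):
        j = L + 1 - i  # stem partner position on the 5' strand
        if paired[j]:
            seq[i] = _pair_base(seq[j], rng, spec.wobble_prob)
        else:
            seq[i] = _BASES[rng.integers(4)]

    if planted:
        for b in (bond5, bond3):
            for k, ch in enumerate(spec.motif):
                pos = b - 2 + k  # window positions 5-8
                seq[pos] = ch
                # restore complementarity at the partner; when the partner
                # lies in the other planted window the write is a no-op
                # because the motif is a reverse-complement palindrome
                j = L + 1 - pos
                stem_pos = pos if pos <= s else j
                if 1 <= stem_pos <= s and paired[stem_pos]:
                    seq[j] = _COMPLEMENT[ch]

    structure = []
    for i in range(1, L + 1):
        if i <= s:
            structure.append("(" if paired[i] else ".")
        elif i <= s + loop:
            structure.append(".")
        else:
            structure.append(")" if paired[L + 1 - i] else ".")

    return PreMiRNA(
        id=hp_id,
        sequence="".join(seq[1:]),
        structure="".join(structure),
        bond5=bond5,
        bond3=bond3,
    )


def generate_corpus(n: int, spec: HairpinSpec, seed: int
                    ) -> tuple[list[PreMiRNA], list[AnnotationRow]]:
    """Draw ``n`` hairpins reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    hairpins = [generate_hairpin(spec, rng, f"syn-mir-{i:05d}") for i in range(n)]
    annotations = [AnnotationRow(h.id, h.bond5, h.bond3) for h in hairpins]
    return hairpins, annotations


def write_corpus(hairpins: list[PreMiRNA], annotations: list[AnnotationRow],
                 out_prefix: str) -> dict:
    """Write FASTA, Vienna and annotation files; returns the paths."""
    paths = {
        "fasta": f"{out_prefix}.fasta",
        "vienna": f"{out_prefix}.vienna",
        "annotations": f"{out_prefix}.annotations.tsv",
    }
    write_fasta([SeqRecord(h.id, h.sequence) for h in hairpins], paths["fasta"])
    write_vienna(
        [ViennaRecord(h.id, h.sequence, h.structure) for h in hairpins],
        paths["vienna"],
    )
    write_annotations(annotations, paths["annotations"])
    return paths
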