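"""Readers and writers for the on-disk formats.

Four formats are handled:

* multi-record FASTA (via Biopython), with DNA ``T`` normalised to RNA ``U``;
* Vienna dot-bracket records in the RNAfold stdout dialect
  (``>id`` / sequence / structure, with an optional trailing free-energy
  annotation such as ``( -1.20)`` after the structure, which is stripped);
* a 3-column cleavage-annotation TSV ``id  bond5  bond3`` where a bond index
  *b* names the phosphodiester bond between nucleotides *b* and *b+1*
  (1-based);
* the main-dataset TSV whose header is exactly
  ``Pat  ID  Seq  Dot-Seq  Dot-Pat  Comp  Arm  Label``.

All readers validate on the way in and raise :class:`FormatError` or
:class:`ValidationError` naming the offending record; all write/read pairs
round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

__all__ = [
    "SeqRecord",
    "ViennaRecord",
    "AnnotationRow",
    "DatasetRow",
    "DATASET_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_vienna",
    "write_vienna",
    "read_annotations",
    "write_annotations",
    "read_dataset",
    "write_dataset",
]

_RNA = set("ACGU")
_STRUCT = set("(.)")
_COMP = set("ACGUO")

DATASET_COLUMNS = ["Pat", "ID", "Seq", "Dot-Seq", "Dot-Pat", "Comp", "Arm", "Label"]


@dataclass(frozen=True)
class SeqRecord:
    """An RNA sequence: uppercase A/C/G/U, id without whitespace."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id or re.search(r"\s", self.id):
            raise ValidationError(f"invalid record id {self.id!r}")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _RNA
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ViennaRecord:
    """A sequence with its dot-bracket secondary structure."""

    id: str
    sequence: str
    structure: str

    def __post_init__(self):
        if len(self.structure) != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.structure) - _STRUCT
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid structure characters {sorted(bad)}"
            )
        depth = 0
        for i, ch in enumerate(self.structure):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValidationError(
                        f"record {self.id!r}: unbalanced ')' at position {i + 1}"
                    )
        if depth != 0:
            raise ValidationError(
                f"record {self.id!r}: {depth} unmatched '(' bracket(s)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRow:
    """Cleavage bond positions of one pre-miRNA (1-based bond indices)."""

    id: str
    bond5: int
    bond3: int

    def __post_init__(self):
        if not (7 <= self.bond5 < self.bond3):
            raise ValidationError(
                f"record {self.id!r}: need 7 <= bond5 < bond3, "
                f"got bond5={self.bond5} bond3={self.bond3}"
            )


@dataclass(frozen=True)
class DatasetRow:
    """One main-dataset entity: a 14-nt cleavage pattern in full context."""

    pat: str
    id: str
    seq: str
    dotseq: str
    dotpat: str
    comp: str
    arm: int
    label: int

    def __post_init__(self):
        if len(self.pat) != 14 or len(self.dotpat) != 14 or len(self.comp) != 14:
            raise ValidationError(f"row {self.id!r}: Pat/Dot-Pat/Comp must be 14 chars")
        if self.pat not in self.seq:
            raise ValidationError(f"row {self.id!r}: Pat is not a substring of Seq")
        if set(self.comp) - _COMP:
            raise ValidationError(f"row {self.id!r}: Comp outside alphabet ACGUO")
        if self.arm not in (5, 3):
            raise ValidationError(f"row {self.id!r}: Arm must be 5 or 3, got {self.arm}")
        if self.label not in (0, 1, 2):
            raise ValidationError(
                f"row {self.id!r}: Label must be 0, 1 or 2, got {self.label}"
            )
        for i in range(14):
            if (self.comp[i] == "O") != (self.dotpat[i] == "."):
                raise ValidationError(
                    f"row {self.id!r}: Comp 'O' and Dot-Pat '.' disagree at "
                    f"position {i + 1}"
                )


def _normalize_rna(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("T", "U")
    if not seq:
        raise FormatError(f"record {record_id!r}: empty sequence")
    bad = set(seq) - _RNA
    if bad:
        raise FormatError(
            f"record {record_id!r}: non-nucleotide characters {sorted(bad)}"
        )
    return seq


def read_fasta(path) -> list[SeqRecord]:
    """Read a multi-record FASTA file; T is mapped to U, case normalised."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises ValueError on bad syntax
        raise FormatError(f"{path}: not valid FASTA: {exc}") from exc
    if not parsed:
        # distinguish an empty file from one with no valid header
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header starting with '>'"
                    )
    for rec in parsed:
        records.append(SeqRecord(rec.id, _normalize_rna(str(rec.seq), rec.id)))
    return records


def write_fasta(records: list[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


_ENERGY_SUFFIX = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")


def read_vienna(path) -> list[ViennaRecord]:
    """Read RNAfold-style dot-bracket records (header/sequence/structure).

    A trailing free-energy annotation after the structure line, e.g.
    ``.((..)). ( -1.20)``, is stripped.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    records = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}:{i + 1}: expected '>' header, got {lines[i]!r}")
        rec_id = lines[i][1:].split()[0] if lines[i][1:].split() else ""
        if not rec_id:
            raise FormatError(f"{path}:{i + 1}: empty record header")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}:{i + 1}: record {rec_id!r} is truncated")
        seq = _normalize_rna(lines[i + 1].strip(), rec_id)
        struct = _ENERGY_SUFFIX.sub("", lines[i + 2]).strip()
        records.append(ViennaRecord(rec_id, seq, struct))
        i += 3
    return records


def write_vienna(records: list[ViennaRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.structure}\n")


def read_annotations(path) -> list[AnnotationRow]:
    """Read the 3-column cleavage-annotation TSV (header: id, bond5, bond3)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    expected = ["id", "bond5", "bond3"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    return [
        AnnotationRow(str(r.id), int(r.bond5), int(r.bond3))
        for r in df.itertuples(index=False)
    ]


def write_annotations(rows: list[AnnotationRow], path) -> None:
    df = pd.DataFrame(
        [(r.id, r.bond5, r.bond3) for r in rows], columns=["id", "bond5", "bond3"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path) -> list[DatasetRow]:
    """Read a main-dataset TSV with the exact Table-style header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != DATASET_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {DATASET_COLUMNS}, found {list(df.columns)}"
        )
    rows = []
    for i, r in enumerate(df.to_dict("records"), 2):
        try:
            rows.append(
                DatasetRow(
                    pat=r["Pat"],
                    id=r["ID"],
                    seq=r["Seq"],
                    dotseq=r["Dot-Seq"],
                    dotpat=r["Dot-Pat"],
                    comp=r["Comp"],
                    arm=int(r["Arm"]),
                    label=int(r["Label"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{i}: {exc}") from exc
    return rows


def write_dataset(rows: list[DatasetRow], path) -> None:
    df = pd.DataFrame(
        [
            (r.pat, r.id, r.seq, r.dotseq, r.dotpat, r.comp, r.arm, r.label)
            for r in rows
        ],
        columns=DATASET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def dataset_to_frame(rows: list[DatasetRow]) -> pd.DataFrame:
    """The rows as a pandas DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            (r.pat, r.id, r.seq, r.dotseq, r.dotpat, r.comp, r.arm, r.label)
            for r in rows
        ],
        columns=DATASET_COLUMNS,
    )
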