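"""Main-dataset construction and train/test splits.

Every usable pre-miRNA contributes exactly four cleavage-pattern entities:
the two annotated positive windows (one per arm) and one randomly chosen
negative window per arm. A negative window's centre bond is drawn uniformly
from the eligible bonds of its arm; by default "eligible" means the centre
bond is not an annotated cleavage bond (the same centre-based property that
defines positives). A stricter mode additionally rejects windows that
contain an annotated bond anywhere among their 13 interior bonds.

Arm membership of a bond is its side of the terminal-loop midpoint (the
unpaired region enclosed by the innermost base pair): at or before the
midpoint is the 5' arm, after it the 3' arm.

Splits reproduce the published protocol: per arm, a seeded random draw of
800 positive and 800 negative patterns forms the binary training set and
the remaining patterns the test set; for the multi-class task the 3'
positives are relabelled 2 and 800 patterns are drawn from each of the four
cells (5'/3' x positive/negative), leaving the remainder as the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import CountError, ValidationError
from .rnaio import DatasetRow
from .structure import PreMiRNA, make_pattern, terminal_loop_midpoint

__all__ = [
    "MainDataset",
    "SplitSpec",
    "eligible_negative_bonds",
    "build_entries",
    "build_main_dataset",
    "split_binary",
    "split_multiclass",
    "make_unbalanced",
    "filter_ae_corpus",
]


@dataclass
class MainDataset:
    rows: list[DatasetRow]
    seed: int
    skipped: list[str]  # ids of pre-miRNAs with no eligible negative window


@dataclass
class SplitSpec:
    task: str  # "binary5" | "binary3" | "multi"
    n_train_pos: int = 800
    n_train_neg: int = 800
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("binary5", "binary3", "multi"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.n_train_pos <= 0 or self.n_train_neg <= 0:
            raise ValidationError("training counts must be positive")


def eligible_negative_bonds(pm: PreMiRNA, arm: int, strict: bool = False) -> list[int]:
    """Centre bonds on the given arm that can seed a negative window.

    A bond b is eligible if the 14-nt window around it fits the sequence,
    b is on the requested arm, and b is not an annotated cleavage bond.
    With ``strict=True`` the window may not contain an annotated bond at
    any of its 13 interior bond positions.
    """
    L = len(pm)
    mid = terminal_loop_midpoint(pm.pairs)
    bonds = []
    for b in range(7, L - 6):
        if (b <= mid) != (arm == 5):
            continue
        if b in (pm.bond5, pm.bond3):
            continue
        if strict and any(b - 6 <= a <= b + 6 for a in (pm.bond5, pm.bond3)):
            continue
        bonds.append(b)
    return bonds


def _to_row(pm: PreMiRNA, bond: int, arm: int, label: int) -> DatasetRow:
    cp = make_pattern(pm, bond, arm, label)
    return DatasetRow(
        pat=cp.pat,
        id=pm.id,
        seq=pm.sequence,
        dotseq=pm.structure,
        dotpat=cp.dotpat,
        comp=cp.comp,
        arm=arm,
        label=label,
    )


def build_entries(pm: PreMiRNA, rng: np.random.Generator,
                  strict_negatives: bool = False) -> list[DatasetRow]:
    """The four entities of one pre-miRNA: a positive and a negative per arm."""
    rows = [
        _to_row(pm, pm.bond5, 5, 1),
        _to_row(pm, pm.bond3, 3, 1),
    ]
    for arm in (5, 3):
        bonds = eligible_negative_bonds(pm, arm, strict=strict_negatives)
        if not bonds:
            raise CountError(
                f"{pm.id}: no eligible negative window on the {arm}' arm"
            )
        rows.append(_to_row(pm, int(rng.choice(bonds)), arm, 0))
    return rows


def build_main_dataset(pms: list[PreMiRNA], seed: int,
                       strict_negatives: bool = False) -> MainDataset:
    """Four entities per usable pre-miRNA; unusable ones are skipped."""
    rng = np.random.default_rng(seed)
    rows: list[DatasetRow] = []
    skipped: list[str] = []
    for pm in pms:
        try:
            rows.extend(build_entries(pm, rng, strict_negatives=strict_negatives))
        except CountError:
            skipped.append(pm.id)
    return MainDataset(rows=rows, seed=seed, skipped=skipped)


def _draw(indices: np.ndarray, n: int, rng: np.random.Generator,
          what: str) -> set[int]:
    if len(indices) < n:
        raise CountError(f"requested {n} {what} but only {len(indices)} available")
    return set(rng.choice(indices, size=n, replace=False).tolist())


def split_binary(ds: MainDataset, arm: int, spec: SplitSpec
                 ) -> tuple[list[DatasetRow], list[DatasetRow]]:
    """Seeded 800/800 draw (by default) within one arm; the rest is the test set."""
    rng = np.random.default_rng(spec.seed)
    sub = [(i, r) for i, r in enumerate(ds.rows) if r.arm == arm]
    pos = np.array([i for i, r in sub if r.label == 1])
    neg = np.array([i for i, r in sub if r.label == 0])
    chosen = _draw(pos, spec.n_train_pos, rng, f"{arm}' positives")
    chosen |= _draw(neg, spec.n_train_neg, rng, f"{arm}' negatives")
    train = [r for i, r in sub if i in chosen]
    test = [r for i, r in sub if i not in chosen]
    return train, test


def split_multiclass(ds: MainDataset, spec: SplitSpec
                     ) -> tuple[list[DatasetRow], list[DatasetRow]]:
    """Relabel 3' positives to class 2, then draw 800 per cell for training."""
    rng = np.random.default_rng(spec.seed)
    rows = [
        replace(r, label=2) if (r.label == 1 and r.arm == 3) else r
        for r in ds.rows
    ]
    cells = {
        "5' positives": np.array([i for i, r in enumerate(rows) if r.label == 1]),
        "3' positives": np.array([i for i, r in enumerate(rows) if r.label == 2]),
        "5' negatives": np.array(
            [i for i, r in enumerate(rows) if r.label == 0 and r.arm == 5]
        ),
        "3' negatives": np.array(
            [i for i, r in enumerate(rows) if r.label == 0 and r.arm == 3]
        ),
    }
    chosen: set[int] = set()
    for what, idx in cells.items():
        n = spec.n_train_pos if "positives" in what else spec.n_train_neg
        chosen |= _draw(idx, n, rng, what)
    train = [r for i, r in enumerate(rows) if i in chosen]
    test = [r for i, r in enumerate(rows) if i not in chosen]
    return train, test


def make_unbalanced(test: list[DatasetRow], n_pos: int,
                    rng: np.random.Generator) -> list[DatasetRow]:
    """Keep all negatives and a random draw of ``n_pos`` per positive class."""
    keep: set[int] = {i for i, r in enumerate(test) if r.label == 0}
    for cls in sorted({r.label for r in test} - {0}):
        idx = np.array([i for i, r in enumerate(test) if r.label == cls])
        keep |= _draw(idx, n_pos, rng, f"class-{cls} positives")
    return [r for i, r in enumerate(test) if i in keep]


def filter_ae_corpus(records, exclude_ids=(), min_len: int = 40,
                     max_len: int = 200) -> list:
    """Length filter (inclusive bounds) plus an id exclusion list."""
    excluded = set(exclude_ids)
    return [
        r for r in records
        if min_len <= len(r) <= max_len and r.id not in excluded
    ]
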