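"""In-silico proteolytic digestion and discriminating-peptide selection.

Trypsin cleaves C-terminal to K/R except before proline; allowing up to one
missed cleavage recovers peptides like QIWLSSPSSGPKR whose internal K is
left uncut often enough to be a usable MRM analyte. Peptides are classified
by bare sequence string into those unique to one homolog (discriminating,
usable for species-specific quantification) and those shared by both
(qualifying, confirming total protein presence only).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .sequences import ProteinSequence

__all__ = [
    "CleavageRule",
    "TRYPSIN",
    "Peptide",
    "PeptideClassification",
    "digest",
    "classify_peptides",
    "select_discriminating",
    "write_peptide_csv",
    "read_peptide_csv",
]


@dataclass(frozen=True)
class CleavageRule:
    """Single-protease cleavage specificity.

    ``cut_after`` residues trigger cleavage on their C-terminal side unless
    the following residue is in ``blocked_by_next``. A blocked site is not a
    site at all and does not count as a missed cleavage.
    """

    cut_after: frozenset[str] = frozenset("KR")
    blocked_by_next: frozenset[str] = frozenset("P")
    max_missed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_after", frozenset(self.cut_after))
        object.__setattr__(self, "blocked_by_next", frozenset(self.blocked_by_next))
        if not self.cut_after:
            raise ValueError("cut_after must be non-empty")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def cleaves_between(self, left: str, right: str) -> bool:
        return left in self.cut_after and right not in self.blocked_by_next


#: Standard trypsin: cut after K/R, not before P, one missed cleavage.
TRYPSIN = CleavageRule()


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide anchored to full-length parent coordinates.

    ``label`` distinguishes the unlabeled analyte form ("light") from the
    stable-isotope internal-standard form ("heavy") in which every
    ``labeled_residue`` (leucine for a [13C6]-Leu SILAC standard) carries a
    fixed mass shift.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    label: str = "light"
    labeled_residue: str = "L"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if self.label not in ("light", "heavy"):
            raise ValueError("label must be 'light' or 'heavy'")
        if self.label == "heavy" and self.labeled_residue not in self.sequence:
            raise ValueError(
                f"heavy peptide {self.sequence} contains no "
                f"labeled residue {self.labeled_residue!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_labeled(self) -> int:
        """Number of label-carrying residues in the sequence."""
        return self.sequence.count(self.labeled_residue)

    def as_heavy(self) -> "Peptide":
        if self.labeled_residue not in self.sequence:
            raise ValueError(
                f"{self.sequence} has no {self.labeled_residue!r}; cannot "
                "form a SILAC heavy counterpart"
            )
        return replace(self, label="heavy")


@dataclass(frozen=True)
class PeptideClassification:
    """Digest peptides partitioned by sequence string across two homologs."""

    unique_to_a: tuple[Peptide, ...]
    unique_to_b: tuple[Peptide, ...]
    shared: tuple[Peptide, ...]

    @property
    def n_distinct(self) -> int:
        """Number of distinct chromatographic species (sequence strings)."""
        return len(
            {p.sequence for group in (self.unique_to_a, self.unique_to_b, self.shared)
             for p in group}
        )


def digest(protein: ProteinSequence, rule: CleavageRule = TRYPSIN) -> list[Peptide]:
    """Enumerate all peptides with 0..max_missed missed cleavages.

    Coordinates are on full-length numbering (the protein's offset is
    honored). Output is ordered by start position, then missed-cleavage
    count.
    """
    seq = protein.residues
    n = len(seq)
    # cut points as indices into seq: a cut after seq[i-1] (0 and n are termini)
    cuts = [0]
    cuts += [
        i
        for i in range(1, n)
        if rule.cleaves_between(seq[i - 1], seq[i])
    ]
    cuts.append(n)

    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + rule.max_missed, len(cuts))):
            i, j = cuts[a], cuts[b]
            peptides.append(
                Peptide(
                    parent_id=protein.id,
                    start=protein.numbering_offset + i,
                    end=protein.numbering_offset + j - 1,
                    sequence=seq[i:j],
                    missed_cleavages=b - a - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def classify_peptides(
    peps_a: Iterable[Peptide], peps_b: Iterable[Peptide]
) -> PeptideClassification:
    """Partition two digests into homolog-unique and shared peptides.

    Identity is the bare sequence string — label- and coordinate-blind —
    because that is what distinguishes chromatographic/MS species.
    """
    peps_a = list(peps_a)
    peps_b = list(peps_b)
    seqs_a = {p.sequence for p in peps_a}
    seqs_b = {p.sequence for p in peps_b}

    def _first_by_seq(peps: list[Peptide], keep: set[str]) -> tuple[Peptide, ...]:
        out, seen = [], set()
        for p in peps:
            if p.sequence in keep and p.sequence not in seen:
                seen.add(p.sequence)
                out.append(p)
        return tuple(out)

    shared_seqs = seqs_a & seqs_b
    return PeptideClassification(
        unique_to_a=_first_by_seq(peps_a, seqs_a - seqs_b),
        unique_to_b=_first_by_seq(peps_b, seqs_b - seqs_a),
        shared=_first_by_seq(peps_a, shared_seqs),
    )


def select_discriminating(
    classification: PeptideClassification, min_length: int = 6
) -> tuple[list[Peptide], list[Peptide]]:
    """Rank each homolog's unique peptides for species-specific MRM.

    Returns the unique peptides of length >= min_length per homolog, longest
    first (longer peptides offer more and higher-m/z product ions). Shared
    peptides stay with the classification as qualifying peptides. Emits a
    warning if a homolog has no usable unique peptide.
    """
    def _rank(peps: tuple[Peptide, ...]) -> list[Peptide]:
        keep = [p for p in peps if len(p) >= min_length]
        keep.sort(key=lambda p: (-len(p), p.sequence))
        return keep

    picked_a = _rank(classification.unique_to_a)
    picked_b = _rank(classification.unique_to_b)
    if not picked_a or not picked_b:
        warnings.warn(
            "no discriminating peptide for at least one homolog; the pair "
            "is indistinguishable under this digest",
            stacklevel=2,
        )
    return picked_a, picked_b


_PEPTIDE_COLUMNS = ["parent_id", "start", "end", "sequence", "missed_cleavages"]


def write_peptide_csv(peptides: Iterable[Peptide], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PEPTIDE_COLUMNS)
        for p in peptides:
            w.writerow([p.parent_id, p.start, p.end, p.sequence, p.missed_cleavages])


def read_peptide_csv(path: str | Path) -> list[Peptide]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            Peptide(
                parent_id=row["parent_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=row["sequence"],
                missed_cleavages=int(row["missed_cleavages"]),
            )
            for row in reader
        ]
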