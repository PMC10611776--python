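"""Protein sequences, proteoform maturation, and homolog comparison.

Full-length mitochondrial proteins such as frataxin are proteolytically
matured in two steps by the mitochondrial processing peptidase (MPP); the
mature proteoform is the C-terminal segment left after the last cleavage.
Quantifying one homolog in the presence of a nearly identical one hinges on
the handful of residue positions where the two differ, so this module keeps
every sequence anchored to full-length residue numbering: a mature frataxin
record stores residues 81-210 with ``numbering_offset=81`` and residue 92 is
residue 92 in both the full-length and the mature record.

Only gap-free, equal-length homolog pairs are compared here; no alignment is
performed (the frataxin orthologs are substitution-only relative to each
other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "STANDARD_RESIDUES",
    "ProteinSequence",
    "MaturationSpec",
    "ResidueDifference",
    "AlignmentRequiredError",
    "mature_from_full",
    "diff_positions",
    "percent_identity",
    "read_fasta",
    "write_fasta",
]


class AlignmentRequiredError(ValueError):
    """Raised when two sequences cannot be compared position-by-position."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein (or proteoform) with full-length residue numbering.

    Parameters
    ----------
    id : str
        Accession or free-text label.
    species : str
        Free-text species tag (e.g. ``"human"``, ``"macaque"``).
    residues : str
        1-letter amino-acid codes.
    numbering_offset : int
        Full-length position of the first stored residue (1 for a
        full-length record; 81 for mature frataxin 81-210).
    """

    id: str
    species: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be non-empty")
        bad = set(self.residues) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residue code(s): {sorted(bad)}")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        """Full-length position of the first residue."""
        return self.numbering_offset

    @property
    def end(self) -> int:
        """Full-length position of the last residue (inclusive)."""
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Residue at a full-length 1-based *position*."""
        if not self.start <= position <= self.end:
            raise IndexError(
                f"position {position} outside [{self.start}, {self.end}]"
            )
        return self.residues[position - self.numbering_offset]

    def subsequence(self, start: int, end: int) -> str:
        """Residue string spanning full-length positions [start, end]."""
        if start > end:
            raise ValueError("start must be <= end")
        if start < self.start or end > self.end:
            raise IndexError(
                f"[{start}, {end}] outside [{self.start}, {self.end}]"
            )
        i = start - self.numbering_offset
        return self.residues[i : i + (end - start + 1)]


@dataclass(frozen=True)
class MaturationSpec:
    """Ordered MPP-style cleavage sites and which segment is retained.

    ``cleavage_sites`` are (left, right) pairs of adjacent full-length
    positions; cleavage severs the peptide bond between them. For two-step
    MPP maturation of frataxin the sites are (41, 42) and (80, 81) and the
    retained segment is the C-terminal one (81-210).
    """

    cleavage_sites: tuple[tuple[int, int], ...] = ()
    retained_segment: str = "c_terminal"

    def __post_init__(self) -> None:
        sites = tuple(tuple(s) for s in self.cleavage_sites)
        object.__setattr__(self, "cleavage_sites", sites)
        for left, right in sites:
            if right != left + 1:
                raise ValueError(
                    f"cleavage site ({left}, {right}) must be adjacent"
                )
        lefts = [s[0] for s in sites]
        if lefts != sorted(set(lefts)):
            raise ValueError("cleavage sites must be strictly increasing")
        if self.retained_segment != "c_terminal":
            raise ValueError("only C-terminal retention is supported")


@dataclass(frozen=True, order=True)
class ResidueDifference:
    """A single substitution between two aligned homologs.

    ``position`` is the full-length residue number; ``residue_a`` /
    ``residue_b`` are the 1-letter codes in the first and second sequence
    (e.g. E92D between human and macaque mature frataxin is position 92,
    residue_a 'E', residue_b 'D').
    """

    position: int
    residue_a: str
    residue_b: str

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("residues must differ")

    def __str__(self) -> str:  # e.g. "E92D"
        return f"{self.residue_a}{self.position}{self.residue_b}"


def mature_from_full(full: ProteinSequence, spec: MaturationSpec) -> ProteinSequence:
    """Derive the mature proteoform by applying sequential cleavages.

    The retained product is the C-terminal segment after the last cleavage
    site; residue numbering is preserved from the full-length protein via
    ``numbering_offset``. A spec with no sites returns the input unchanged.
    """
    if not spec.cleavage_sites:
        return full
    for left, right in spec.cleavage_sites:
        if not (full.start <= left <= full.end and full.start <= right <= full.end):
            raise IndexError(
                f"cleavage site ({left}, {right}) outside sequence "
                f"[{full.start}, {full.end}]"
            )
    new_start = spec.cleavage_sites[-1][1]
    return ProteinSequence(
        id=f"{full.id}-M",
        species=full.species,
        residues=full.subsequence(new_start, full.end),
        numbering_offset=new_start,
    )


def _check_comparable(a: ProteinSequence, b: ProteinSequence) -> None:
    if len(a) != len(b):
        raise AlignmentRequiredError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "only gap-free equal-length comparison is supported"
        )
    if a.numbering_offset != b.numbering_offset:
        raise AlignmentRequiredError(
            "sequences must share the same numbering_offset "
            f"({a.numbering_offset} vs {b.numbering_offset})"
        )


def diff_positions(a: ProteinSequence, b: ProteinSequence) -> list[ResidueDifference]:
    """All substitution positions between two aligned homologs, sorted."""
    _check_comparable(a, b)
    return [
        ResidueDifference(a.numbering_offset + i, ra, rb)
        for i, (ra, rb) in enumerate(zip(a.residues, b.residues))
        if ra != rb
    ]


def percent_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Percent sequence identity over the aligned length, to 1 decimal.

    130-residue mature frataxin homologs with 2 substitutions give 98.5;
    identical sequences give 100.0.
    """
    _check_comparable(a, b)
    n_diff = len(diff_positions(a, b))
    return round(100.0 * (len(a) - n_diff) / len(a), 1)


# ---------------------------------------------------------------------------
# FASTA I/O: the description line is "<id> <species> [free text]"; an
# optional "offset=<n>" token carries non-default numbering.
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein records; species is the first description token after the id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        species = ""
        offset = 1
        for tok in tokens[1:]:
            if tok.startswith("offset="):
                offset = int(tok.split("=", 1)[1])
            elif not species:
                species = tok
        records.append(
            ProteinSequence(
                id=rec.id,
                species=species,
                residues=str(rec.seq).upper(),
                numbering_offset=offset,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: Iterable[ProteinSequence], path: str | Path) -> None:
    recs = []
    for p in proteins:
        desc = p.species
        if p.numbering_offset != 1:
            desc += f" offset={p.numbering_offset}"
        recs.append(SeqRecord(Seq(p.residues), id=p.id, description=desc.strip()))
    SeqIO.write(recs, str(path), "fasta")
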