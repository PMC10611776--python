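"""Monoisotopic mass and m/z arithmetic for MRM transition design.

Covers light and [13C6]-leucine-labeled peptides, multiply protonated
precursors, and y/b fragment ions, plus assembly of a scheduled transition
panel and its Skyline-importable CSV round-trip.

All arithmetic is done at full floating precision; the printed 3-decimal
m/z convention is applied only at serialization, and comparisons against
printed values should use a +/-0.005 tolerance.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .digestion import Peptide

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASSES",
    "WATER_MONO",
    "PROTON_MASS",
    "C13C6_LEU_SHIFT",
    "MassConstants",
    "ProductIon",
    "Transition",
    "TransitionPanel",
    "peptide_monoisotopic_mass",
    "precursor_mz",
    "fragment_mz",
    "heavy_counterpart",
    "build_panel",
    "write_transition_csv",
    "read_transition_csv",
]

#: Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MASS = 1.00727646
#: Mass shift of one [13C6]-leucine: 6 x (13.00335483 - 12) Da.
C13C6_LEU_SHIFT = 6.020129


@dataclass(frozen=True)
class MassConstants:
    """Mass table and labeling convention used by every m/z computation.

    ``fixed_modifications`` maps residue code -> added Da (e.g. carbamido-
    methyl-Cys +57.02146); empty by default since the frataxin panel
    contains no cysteine. ``label_shift_per_residue`` is added once per
    labeled residue in a heavy peptide.
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASSES)
    )
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON_MASS
    label_shift_per_residue: float = C13C6_LEU_SHIFT
    fixed_modifications: Mapping[str, float] = field(default_factory=dict)

    def residue_mass(self, code: str, position: int) -> float:
        try:
            m = self.residue_masses[code]
        except KeyError:
            raise KeyError(
                f"unknown residue {code!r} at position {position}"
            ) from None
        return m + self.fixed_modifications.get(code, 0.0)


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class ProductIon:
    """One fragment-ion channel: series type, index, and charge.

    For a y-ion the index counts C-terminal residues; for a b-ion,
    N-terminal residues.
    """

    type: str  # "y" | "b"
    index: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.type not in ("y", "b"):
            raise ValueError("product ion type must be 'y' or 'b'")
        if self.index < 1:
            raise ValueError("product ion index must be >= 1")
        if self.charge < 1:
            raise ValueError("product ion charge must be >= 1")

    def __str__(self) -> str:  # e.g. "y14^2"
        return f"{self.type}{self.index}^{self.charge}"

    @classmethod
    def parse(cls, text: str) -> "ProductIon":
        text = text.strip()
        ion, _, z = text.partition("^")
        return cls(type=ion[0], index=int(ion[1:]), charge=int(z) if z else 1)


@dataclass(frozen=True)
class Transition:
    """One MRM channel: a precursor/product m/z pair at a scheduled RT."""

    peptide: Peptide
    precursor_charge: int
    precursor_mz: float
    product: ProductIon
    product_mz: float
    retention_time: float

    def __post_init__(self) -> None:
        if not 1 <= self.product.index < len(self.peptide):
            raise ValueError(
                f"product index {self.product.index} out of range for "
                f"{self.peptide.sequence}"
            )
        if self.retention_time <= 0:
            raise ValueError("retention_time must be > 0")

    @property
    def transition_id(self) -> str:
        p = self.peptide
        return f"{p.sequence}/{p.label}/{self.precursor_charge}+/{self.product}"


@dataclass(frozen=True)
class TransitionPanel:
    """A scheduled MRM method: transitions plus an RT acceptance tolerance."""

    transitions: tuple[Transition, ...]
    rt_tolerance: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        ids = [t.transition_id for t in self.transitions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transition id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    def peptides(self) -> list[Peptide]:
        """Distinct (sequence, label) peptides, in panel order."""
        seen, out = set(), []
        for t in self.transitions:
            key = (t.peptide.sequence, t.peptide.label)
            if key not in seen:
                seen.add(key)
                out.append(t.peptide)
        return out

    def transitions_for(self, peptide_seq: str, label: str) -> list[Transition]:
        return [
            t
            for t in self.transitions
            if t.peptide.sequence == peptide_seq and t.peptide.label == label
        ]


def peptide_monoisotopic_mass(
    peptide: Peptide, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """Neutral monoisotopic mass: residue masses + water (+ label shifts)."""
    mass = constants.water_mass + sum(
        constants.residue_mass(c, peptide.start + i)
        for i, c in enumerate(peptide.sequence)
    )
    if peptide.label == "heavy":
        mass += constants.label_shift_per_residue * peptide.n_labeled
    return mass


def precursor_mz(
    mass: float, z: int, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """m/z of the z-fold protonated molecule: (M + z*proton) / z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * constants.proton_mass) / z


def fragment_mz(
    peptide: Peptide,
    product_type: str,
    index: int,
    z: int = 1,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """m/z of a y- or b-ion of the peptide, label-aware.

    y_n carries the n C-terminal residues plus water; b_n the n N-terminal
    residues without water. Label shifts apply to labeled residues that fall
    inside the fragment, so a heavy fragment without leucine has the light
    m/z (e.g. y5 TTYER of the SGT... peptides).
    """
    if product_type not in ("y", "b"):
        raise ValueError("product_type must be 'y' or 'b'")
    if z < 1:
        raise ValueError("charge must be >= 1")
    n = len(peptide)
    if not 1 <= index < n:
        raise ValueError(
            f"fragment index {index} out of range [1, {n - 1}] for "
            f"{peptide.sequence}"
        )
    if product_type == "y":
        frag = peptide.sequence[n - index :]
        offset = peptide.start + (n - index)
        mass = constants.water_mass
    else:
        frag = peptide.sequence[:index]
        offset = peptide.start
        mass = 0.0
    mass += sum(constants.residue_mass(c, offset + i) for i, c in enumerate(frag))
    if peptide.label == "heavy":
        mass += constants.label_shift_per_residue * frag.count(
            peptide.labeled_residue
        )
    return (mass + z * constants.proton_mass) / z


def heavy_counterpart(peptide: Peptide) -> Peptide:
    """The SILAC internal-standard form: same sequence, all leucines heavy."""
    return peptide.as_heavy()


def build_panel(
    light_peptides: Sequence[Peptide],
    ion_selection: Mapping[str, Sequence[ProductIon]],
    precursor_charges: Mapping[str, int],
    rts: Mapping[str, float],
    heavy_ion_selection: Mapping[str, Sequence[ProductIon]] | None = None,
    rt_tolerance: float = 0.1,
    constants: MassConstants = DEFAULT_CONSTANTS,
    include_heavy: bool = True,
) -> TransitionPanel:
    """Assemble a scheduled panel from peptides and per-peptide ion choices.

    All mappings are keyed by peptide sequence. Every light peptide that
    contains a labeled residue gets a heavy internal-standard channel with
    the same precursor charge and RT (SILAC pairs co-elute); heavy product
    ions default to the light selection unless ``heavy_ion_selection``
    overrides them, as the printed frataxin panel does for one peptide.
    """
    heavy_ion_selection = heavy_ion_selection or {}
    transitions: list[Transition] = []
    for pep in light_peptides:
        seq = pep.sequence
        try:
            rt = rts[seq]
        except KeyError:
            raise KeyError(f"no retention time provided for {seq}") from None
        z = precursor_charges[seq]
        forms = [pep]
        if include_heavy and pep.labeled_residue in seq:
            forms.append(pep.as_heavy())
        for form in forms:
            ions = ion_selection[seq]
            if form.label == "heavy":
                ions = heavy_ion_selection.get(seq, ions)
            pmz = precursor_mz(peptide_monoisotopic_mass(form, constants), z, constants)
            for ion in ions:
                transitions.append(
                    Transition(
                        peptide=form,
                        precursor_charge=z,
                        precursor_mz=pmz,
                        product=ion,
                        product_mz=fragment_mz(
                            form, ion.type, ion.index, ion.charge, constants
                        ),
                        retention_time=rt,
                    )
                )
    return TransitionPanel(transitions=tuple(transitions), rt_tolerance=rt_tolerance)


def panel_from_design_csv(
    path: str | Path,
    constants: MassConstants = DEFAULT_CONSTANTS,
    rt_tolerance: float = 0.1,
) -> TransitionPanel:
    """Build a panel from an assay-design CSV, computing every m/z.

    Expected columns: parent_id, start, end, sequence, missed_cleavages,
    label (light|heavy), precursor_charge, rt_min, product_ions (semicolon-
    separated tokens like ``y14^2``). Extra columns are ignored. The design
    records only what an analyst chooses — peptides, charges, product ions,
    schedule — never masses.
    """
    transitions: list[Transition] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pep = Peptide(
                parent_id=row["parent_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=row["sequence"],
                missed_cleavages=int(row.get("missed_cleavages") or 0),
                label=row["label"],
            )
            z = int(row["precursor_charge"])
            pmz = precursor_mz(peptide_monoisotopic_mass(pep, constants), z, constants)
            for token in row["product_ions"].split(";"):
                ion = ProductIon.parse(token)
                transitions.append(
                    Transition(
                        peptide=pep,
                        precursor_charge=z,
                        precursor_mz=pmz,
                        product=ion,
                        product_mz=fragment_mz(
                            pep, ion.type, ion.index, ion.charge, constants
                        ),
                        retention_time=float(row["rt_min"]),
                    )
                )
    return TransitionPanel(transitions=tuple(transitions), rt_tolerance=rt_tolerance)


# ---------------------------------------------------------------------------
# Skyline-importable transition-list CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "PeptideSequence", "PrecursorMz", "PrecursorCharge", "ProductMz",
    "ProductCharge", "FragmentIon", "IsotopeLabelType", "RetentionTime",
    "ParentId", "Start", "End", "MissedCleavages",
]


def write_transition_csv(panel: TransitionPanel, path: str | Path) -> None:
    """Write a Skyline-dialect transition list; m/z printed to 3 decimals."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for t in panel:
            p = t.peptide
            w.writerow([
                p.sequence,
                f"{t.precursor_mz:.3f}",
                t.precursor_charge,
                f"{t.product_mz:.3f}",
                t.product.charge,
                f"{t.product.type}{t.product.index}",
                p.label,
                f"{t.retention_time:g}",
                p.parent_id, p.start, p.end, p.missed_cleavages,
            ])


def read_transition_csv(path: str | Path, rt_tolerance: float = 0.1) -> TransitionPanel:
    """Read a transition list written by :func:`write_transition_csv`.

    m/z values are taken verbatim from the file (3-decimal), so a
    write/read/write cycle is bit-identical.
    """
    transitions = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            frag = row["FragmentIon"]
            pep = Peptide(
                parent_id=row.get("ParentId") or "unknown",
                start=int(row.get("Start") or 1),
                end=int(row.get("End") or len(row["PeptideSequence"])),
                sequence=row["PeptideSequence"],
                missed_cleavages=int(row.get("MissedCleavages") or 0),
                label=row["IsotopeLabelType"],
            )
            transitions.append(
                Transition(
                    peptide=pep,
                    precursor_charge=int(row["PrecursorCharge"]),
                    precursor_mz=float(row["PrecursorMz"]),
                    product=ProductIon(
                        type=frag[0],
                        index=int(frag[1:]),
                        charge=int(row["ProductCharge"]),
                    ),
                    product_mz=float(row["ProductMz"]),
                    retention_time=float(row["RetentionTime"]),
                )
            )
    return TransitionPanel(transitions=tuple(transitions), rt_tolerance=rt_tolerance)
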