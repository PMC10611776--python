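"""Packaged reference assay: the human/macaque mature-frataxin MRM panel.

Frataxin (FXN) is a 210-residue mitochondrial protein matured by two
sequential MPP cleavages (after G41 and after K80) into the 130-residue
FXN-M proteoform (residues 81-210). Human and rhesus macaque FXN-M differ
at exactly two positions, E92D and A187G, so two tryptic peptides per
species carry a substitution and discriminate the homologs, while three
tryptic peptides are shared and serve as qualifying peptides.

The packaged FASTA carries the canonical human full-length sequence
(UniProt Q16595). The macaque record is a synthetic construct: the human
backbone with the two mature-region substitutions applied; its N-terminal
residues 1-80 are not species-verified, which is immaterial here because
every assay operation acts on the mature 81-210 region.

The packaged panel design CSV records, for each of the 12 monitored
channels, the peptide, its light/heavy form, precursor charge, scheduled
retention time, and the three product ions; all m/z values are recomputed
from the sequences, never stored. Macaque-specific light peptides have no
heavy channel of their own — they are normalized against the heavy human
SILAC peptide that differs by the single substitution (see
``INTERNAL_STANDARD_OF``).
"""

from __future__ import annotations

from importlib import resources

from .digestion import TRYPSIN, CleavageRule, Peptide, digest
from .masscalc import (
    MassConstants,
    DEFAULT_CONSTANTS,
    TransitionPanel,
    panel_from_design_csv,
)
from .sequences import MaturationSpec, ProteinSequence, mature_from_full, read_fasta

__all__ = [
    "MPP_MATURATION",
    "HUMAN_QUANTIFIERS",
    "MACAQUE_QUANTIFIERS",
    "QUALIFYING_PEPTIDES",
    "INTERNAL_STANDARD_OF",
    "full_length_pair",
    "mature_pair",
    "monitored_peptides",
    "reference_panel",
]

#: Two-step MPP maturation: cleave after G41 and after K80, keep 81-210.
MPP_MATURATION = MaturationSpec(cleavage_sites=((41, 42), (80, 81)))

#: Species-discriminating tryptic peptides (carry E92/A187 vs D92/G187).
HUMAN_QUANTIFIERS = ("SGTLGHPGSLDETTYER", "NWVYSHDGVSLHELLAAELTK")
MACAQUE_QUANTIFIERS = ("SGTLGHPGSLDDTTYER", "NWVYSHDGVSLHELLGAELTK")

#: Peptides shared by both homologs, monitored for confirmation only.
QUALIFYING_PEPTIDES = ("QIWLSSPSSGPKR", "LGGDLGTYVINK", "LDLSSLAYSGK")

#: Heavy SILAC channel used to normalize each light analyte peptide. The
#: SILAC standard is the human protein, so macaque peptides ratio against
#: the near-identical human heavy peptide.
INTERNAL_STANDARD_OF = {
    "SGTLGHPGSLDETTYER": "SGTLGHPGSLDETTYER",
    "SGTLGHPGSLDDTTYER": "SGTLGHPGSLDETTYER",
    "NWVYSHDGVSLHELLAAELTK": "NWVYSHDGVSLHELLAAELTK",
    "NWVYSHDGVSLHELLGAELTK": "NWVYSHDGVSLHELLAAELTK",
    "QIWLSSPSSGPKR": "QIWLSSPSSGPKR",
    "LGGDLGTYVINK": "LGGDLGTYVINK",
    "LDLSSLAYSGK": "LDLSSLAYSGK",
}

_DATA = resources.files(__package__) / "data"


def full_length_pair() -> tuple[ProteinSequence, ProteinSequence]:
    """The packaged (human, macaque) full-length 1-210 sequences."""
    with resources.as_file(_DATA / "frataxin_full_length.fasta") as path:
        records = read_fasta(path)
    by_species = {r.species: r for r in records}
    return by_species["human"], by_species["macaque"]


def mature_pair() -> tuple[ProteinSequence, ProteinSequence]:
    """The mature 81-210 FXN-M proteoforms (130 residues each)."""
    human, macaque = full_length_pair()
    return (
        mature_from_full(human, MPP_MATURATION),
        mature_from_full(macaque, MPP_MATURATION),
    )


def monitored_peptides(
    protein: ProteinSequence, rule: CleavageRule = TRYPSIN
) -> list[Peptide]:
    """The five monitored tryptic peptides of one FXN-M homolog.

    Digests with the given rule and keeps the peptides whose sequences
    appear in the reference panel design (two discriminating + three
    shared).
    """
    panel_seqs = set(HUMAN_QUANTIFIERS + MACAQUE_QUANTIFIERS + QUALIFYING_PEPTIDES)
    out, seen = [], set()
    for pep in digest(protein, rule):
        if pep.sequence in panel_seqs and pep.sequence not in seen:
            seen.add(pep.sequence)
            out.append(pep)
    return out


def reference_panel(
    constants: MassConstants = DEFAULT_CONSTANTS, rt_tolerance: float = 0.1
) -> TransitionPanel:
    """The 12-channel scheduled MRM panel, all m/z computed from sequence.

    Seven light peptide channels (2 human-specific, 2 macaque-specific, 3
    shared) and five heavy SILAC channels (the human standard's peptides).
    The heavy N-terminal peptide monitors y4 where its light form monitors
    y3; all other SILAC pairs share product-ion indices.
    """
    with resources.as_file(_DATA / "frataxin_panel.csv") as path:
        return panel_from_design_csv(
            path, constants=constants, rt_tolerance=rt_tolerance
        )
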