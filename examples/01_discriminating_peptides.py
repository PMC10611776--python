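"""Find the tryptic peptides that tell two near-identical homologs apart.

Loads the packaged human and macaque frataxin sequences, derives the
mature 81-210 proteoform by two-step MPP cleavage, digests both with
trypsin (1 missed cleavage), and classifies the monitored peptides into
species-unique (quantifier) and shared (qualifying) sets.
"""

from silacmrm import classify_peptides, diff_positions, percent_identity
from silacmrm.frataxin import mature_pair, monitored_peptides

human, macaque = mature_pair()
print(f"mature homologs: {len(human)} residues each, "
      f"{percent_identity(human, macaque)}% identical")
print("substitutions:", ", ".join(str(d) for d in diff_positions(human, macaque)))

cls = classify_peptides(monitored_peptides(human), monitored_peptides(macaque))
print(f"\n{cls.n_distinct} distinct monitored peptides in a 50:50 mixture:")
for name, group in [("human-specific", cls.unique_to_a),
                    ("macaque-specific", cls.unique_to_b),
                    ("shared (qualifying)", cls.shared)]:
    for p in group:
        print(f"  {name:20s} {p.start:>3d}-{p.end:<3d} {p.sequence}")

# The species-specific peptides carry the E92/D92 and A187/G187 positions;
# only they can quantify one homolog in the presence of the other.
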