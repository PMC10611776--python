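"""Regenerate the scheduled MRM transition panel with all m/z computed.

Every precursor and y-ion m/z — light analyte and [13C6]-Leu heavy
internal-standard forms — is computed from the peptide string, the charge
state, and standard monoisotopic masses, then written as a
Skyline-importable transition list.
"""

from silacmrm.frataxin import reference_panel
from silacmrm.masscalc import write_transition_csv

panel = reference_panel()
print(f"{len(panel)} transitions, RT tolerance {panel.rt_tolerance} min\n")
print(f"{'peptide':23s} {'label':6s} {'z':>2s} {'precursor':>9s} "
      f"{'ion':>5s} {'product':>8s} {'RT':>5s}")
for t in panel:
    print(f"{t.peptide.sequence:23s} {t.peptide.label:6s} "
          f"{t.precursor_charge:>2d} {t.precursor_mz:>9.3f} "
          f"{str(t.product):>5s} {t.product_mz:>8.3f} {t.retention_time:>5.2f}")

write_transition_csv(panel, "transitions.csv")
print("\nwrote transitions.csv (Skyline-importable)")
# A heavy precursor sits nLeu x 6.020129 / z above its light partner; a
# heavy fragment shifts only by the leucines inside the fragment.
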