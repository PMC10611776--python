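# silacmrm

Species-discriminating SILAC MRM assay design and stable-isotope-dilution
protein quantification.

## The problem

Gene-therapy pharmacology in non-human primates often requires quantifying a
human transgene product in the presence of the animal's nearly identical
endogenous ortholog. The flagship case packaged here is mature frataxin
(FXN-M): the human and rhesus-macaque 130-residue proteoforms (residues
81–210 of the full-length protein, produced by two sequential mitochondrial
processing peptidase cleavages after G41 and K80) are 98.5% identical,
differing only at E92D and A187G. Antibody-based assays cannot tell them
apart; a targeted LC-MRM/MS assay can, because tryptic peptides spanning the
two substitution sites are unique to each species.

`silacmrm` implements the full in-silico side of such an assay:

- **sequences / digestion** — proteoform maturation, homolog comparison,
  tryptic digestion with missed cleavages, and classification of peptides
  into species-unique (quantifier) and shared (qualifying) sets;
- **masscalc** — monoisotopic precursor and y/b fragment m/z for light and
  [¹³C₆]-leucine-labeled heavy peptides (each heavy leucine adds
  6.020129 Da), scheduled transition panels, and Skyline-importable
  transition-list CSVs;
- **chromsim** — a seeded synthetic chromatogram generator (Gaussian peaks,
  per-transition response factors shared between SILAC partners,
  multiplicative area noise, noisy baseline) so the whole quantification
  path is testable with known ground truth;
- **quant** — trapezoidal peak integration with baseline subtraction, the
  light/heavy ratio R = ΣL/ΣH over each peptide's three transitions,
  weighted least-squares calibration R = a·m + b over a 4–200 ng standard
  series with a fixed 40 ng SILAC spike, back-calculation
  m̂ = (R − b)/a with accuracy/CV validation, peptide→protein averaging,
  tissue concentration (ng/mg), and dose-group fold changes;
- **cli** — a thin `silacmrm` command with `digest`, `design`, `simulate`,
  `quantify` and `report` subcommands.

Because the heavy protein standard is spiked into the homogenate before
isolation, the L/H ratio is established at the start and is immune to
work-up losses, digestion efficiency, injected fraction, and detector gain —
that invariance is what the simulator honors and the tests verify.

## Worked example

`examples/01_discriminating_peptides.py` prints:

```
mature homologs: 130 residues each, 98.5% identical
substitutions: E92D, A187G

7 distinct monitored peptides in a 50:50 mixture:
  human-specific        81-97  SGTLGHPGSLDETTYER
  human-specific       172-192 NWVYSHDGVSLHELLAAELTK
  macaque-specific      81-97  SGTLGHPGSLDDTTYER
  macaque-specific     172-192 NWVYSHDGVSLHELLGAELTK
  shared (qualifying)  136-147 LGGDLGTYVINK
  shared (qualifying)  153-165 QIWLSSPSSGPKR
  shared (qualifying)  198-208 LDLSSLAYSGK
```

The two peptide pairs that differ by a single residue are the quantifiers;
the three shared peptides confirm total frataxin without species
information. `examples/02_transition_panel.py` then regenerates the full
36-transition scheduled panel — e.g. the light human N-terminal peptide at
m/z 607.287 (MH₃³⁺) with products y₁₄²⁺ 787.876, y₅⁺ 669.320, y₃⁺ 467.225,
and its heavy counterpart at 611.300 (two labeled leucines, +2 × 6.020129 Da
on the neutral mass). `examples/03_calibration_validation.py` simulates the
10-level standard series in replicate and reports per-level back-calculated
accuracy (here 95–105%) and CV (here ≤ 10%), inside the conventional
85–115% / ≤15% bioanalytical envelope; `examples/04_tissue_quantification.py`
runs the same machinery over simulated control and dosed tissue samples
through to ng/mg concentrations and a dose-group fold change.

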