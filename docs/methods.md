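# Methods

## Scope and model

`silacmrm` models the computational core of a stable-isotope-dilution
IP-LC-MRM/MS assay that distinguishes and quantifies two nearly identical
protein homologs. The packaged reference assay is mature frataxin (FXN-M):
full-length 210-residue frataxin is matured by two sequential MPP cleavages
(between G41–L42 and K80–S81) into the 130-residue 81–210 proteoform, and
the human and rhesus-macaque forms differ at exactly two positions, E92D
and A187G. Every module generalizes to any substitution-only homolog pair;
nothing is frataxin-specific except the packaged fixture.

## Sequence handling

Sequences carry a `numbering_offset` so that mature proteoforms keep
full-length residue numbering (the mature frataxin record spans 81–210).
Homolog comparison is strictly positional: only equal-length, equal-offset
pairs are compared, and unequal lengths raise an alignment-required error
rather than silently aligning. The packaged human record is the canonical
full-length sequence (UniProt Q16595). The macaque record is a synthetic
construct — the human backbone with the two mature-region substitutions
applied — because only the mature region participates in any computation
here; its residues 1–80 are copied from human and are not species-verified,
as its FASTA header states.

## Digestion

Trypsin is modeled as cleavage C-terminal to K or R, blocked when the next
residue is P; a blocked site is not a site and never counts as a missed
cleavage. The default of one allowed missed cleavage is the minimum that
produces the monitored panel (QIWLSSPSSGPKR requires its internal K to stay
uncut) without flooding the output. Peptide identity for homolog
classification is the bare sequence string — label- and coordinate-blind —
matching how chromatographic/MS species are actually distinguished.
Discriminating peptides are the homolog-unique ones above a length cutoff
(default 6), ranked longest-first since longer peptides offer more usable
high-m/z product ions.

## Mass computation

Neutral monoisotopic mass is the sum of standard residue masses plus water;
m/z is (M + z·1.00727646)/z. The heavy SILAC convention is that every
leucine in a heavy peptide carries +6.020129 Da (6 × (¹³C − ¹²C)); fragment
ions shift only by the labeled residues they contain, which is why the y₅
ion TTYER of the N-terminal peptide has identical light and heavy m/z. All
arithmetic is done at full precision; 3-decimal rounding is applied only at
serialization, and comparisons against printed panels use ±0.005. b-ions
are implemented alongside y-ions for completeness although the reference
panel uses only y-ions. Fixed modifications (e.g. carbamidomethyl-Cys) are
supported through a configurable map but default to none — the reference
peptides contain no cysteine. The residue-mass table is declared in the
package; the test suite cross-checks peptide masses against an independent
proteomics library.

## Synthetic chromatograms

The simulator produces, per transition, a Gaussian elution peak (σ = 0.03
min, consistent with sharp UHPLC peaks on a ~7-min gradient) on a flat
baseline (default level 50, point noise SD 10) sampled every 0.002 min over
±0.2 min around the scheduled retention time. True peak area is
amount × response factor × exp(N(0, σ_ln)) with σ_ln chosen so the
multiplicative noise CV is `noise_cv` (default 0.08). Response factors are
drawn once per (response group, product rank) from a lognormal (median
2000 area units/ng, ln-σ 0.5) fixed by the seed, and are *identical* for
the light and heavy form of a transition — the physical fact that makes the
L/H ratio a valid normalizer. Retention-time jitter (SD 0.01 min) is drawn
per peptide per sample and shared by SILAC partners, so pairs co-elute
exactly. All randomness flows from the single explicit seed.

Grouping two homologous peptides into one response group (as the packaged
`INTERNAL_STANDARD_OF` map does) lets a macaque analyte peptide be
normalized against the heavy *human* SILAC peptide, mirroring the real
assay where the standard protein exists only in the human form. This
equal-response assumption between single-substitution homologs is an
idealization; real ionization of e.g. the E92/D92 pair is similar but not
identical, and the simulator does not model that residual bias, nor matrix
interference, peak tailing, or the suppression of a low-abundance homolog
under a large excess of the other. Passing simulation-based tests therefore
demonstrates correctness of the computational chain, not instrument-level
validation.

## Quantification

Peaks are integrated by the trapezoid rule over ±0.1 min around the
scheduled retention time (the assay's RT acceptance tolerance) after
subtracting a constant baseline estimated as the mean of the outermost 10%
of window samples (5% per edge); areas are floored at zero and the observed
RT is the baseline-subtracted intensity centroid, flagged — never dropped —
when it drifts beyond tolerance. The edge-estimated baseline clips ~2% of a
σ = 0.03 peak's area; because light and heavy peaks share shape, this
cancels exactly in the ratio, which is the quantity that matters.

The per-peptide ratio estimator defaults to ratio-of-sums (ΣL/ΣH over the
three transitions), which stays defined when a single transition is weak; a
sum-of-ratios estimator (Σᵢ Lᵢ/Hᵢ) is provided as a configurable
alternative since both formulations circulate in practice.

Calibration is a weighted least-squares line, ratio = slope·ng + intercept,
over the standard series (default design 4, 10, 15, 20, 30, 40, 80, 100,
150, 200 ng against a fixed 40 ng heavy spike, five replicates, one curve
fitted to all replicate points). The default weighting is 1/x². With
multiplicative area noise the residual SD grows linearly with amount, and
an unweighted fit lets the 150–200 ng standards dominate the intercept,
whose error then propagates as a large *relative* error at 4 ng —
back-calculated low-end accuracy routinely leaves the 85–115% envelope.
1/x² weighting equalizes relative residuals and is the standard
bioanalytical choice for calibrations spanning a 50-fold range; unweighted
and 1/x fits remain available. r² is reported as the weighted coefficient
of determination.

Back-calculation inverts the line; values outside the calibrated range are
flagged below/above range, never zeroed or imputed. The validation table
reports, per level, the replicate mean, SD (ddof = 1, across curve
replicates), CV = 100·SD/mean and accuracy = 100·mean/theoretical. Protein
amount is the arithmetic mean of the protein's specific peptides (with a
warning on single-peptide fallback); tissue concentration is protein ng
divided by tissue mg, with no recovery correction — the pre-isolation spike
makes the ratio refer to the whole sample. Group summaries are mean ± SD
with fold change (1 decimal) against an explicit reference mean; outlier
exclusions are explicit inputs only, never automatic.

## Problem sizes and determinism

The default validation workload — 10 levels × 5 replicates × 36 transitions
at 0.002-min sampling — simulates and quantifies in about a second, and the
full test suite runs in a few seconds. Simulations are bit-reproducible
from (inputs, seed); the acceptance script threads its `--seed` into the
simulation config, while every m/z, digest and identity value it reports is
deterministic arithmetic.

## Known limitations

- No chromatographic deconvolution: overlapping peaks within one
  transition's window are integrated together.
- No interference detection or automatic transition rejection.
- The simulator's equal-response assumption for homolog pairs (above).
- Dose-group statistics stop at mean ± SD and fold change; no mixed-effects
  dose–response modeling.
- Only substitution-only (gap-free) homolog pairs are supported; indels
  would require alignment, which is out of scope.
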