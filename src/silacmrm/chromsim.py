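"""Synthetic MRM chromatogram generator with known ground truth.

Emulates scheduled MRM acquisitions of SILAC-paired tryptic peptides:
each transition yields a Gaussian elution peak on a noisy flat baseline,
with true peak area = amount (ng) x a per-transition response factor x a
multiplicative lognormal noise term. Two physical facts the simulator must
honor, because the whole quantification strategy rests on them:

* light and heavy forms of one peptide co-elute (identical peak center and
  width within a sample, including the shared retention-time jitter), and
* the response factor of a transition is identical for the light and heavy
  form, so the light/heavy area ratio equals the light/heavy amount ratio
  up to noise.

Response factors differ between transitions (as real ionization does) and
are drawn once per (response group, product rank) from a lognormal
distribution fixed by the seed. By default each peptide sequence is its own
response group; grouping two homologous peptides together lets a light
analyte be normalized against a heavy internal standard of the *other*
sequence (e.g. a macaque peptide against the human SILAC standard).

All randomness flows from the single explicit seed in
:class:`SimulationConfig`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .masscalc import Transition, TransitionPanel

__all__ = [
    "SimulationConfig",
    "Chromatogram",
    "GroundTruth",
    "DEFAULT_STANDARDS_NG",
    "DEFAULT_SILAC_NG",
    "draw_response_factors",
    "simulate_sample",
    "simulate_standard_series",
    "write_chromatogram_tsv",
    "read_chromatogram_tsv",
    "write_ground_truth_csv",
]

#: Calibration standard amounts (ng) of the reference assay design.
DEFAULT_STANDARDS_NG = (4.0, 10.0, 15.0, 20.0, 30.0, 40.0, 80.0, 100.0, 150.0, 200.0)
#: SILAC internal-standard spike (ng) of the reference assay design.
DEFAULT_SILAC_NG = 40.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic acquisition.

    peak_width_sigma : Gaussian peak sigma, minutes.
    response_factor_median, response_factor_sigma : lognormal from which
        per-transition response factors (area units per ng) are drawn once.
    noise_cv : fractional multiplicative noise on each peak area.
    baseline_level, baseline_noise_sd : flat baseline and its point noise,
        intensity units.
    sampling_interval : minutes between data points.
    rt_jitter_sd : per-sample retention-time jitter, minutes, shared by all
        transitions of one peptide.
    window_halfwidth : minutes of chromatogram simulated either side of the
        scheduled retention time.
    seed : the single source of randomness; must be explicit.
    response_groups : optional peptide-sequence -> group-key mapping; peptides
        in one group share response factors by product rank.
    """

    peak_width_sigma: float = 0.03
    response_factor_median: float = 2000.0
    response_factor_sigma: float = 0.5
    noise_cv: float = 0.08
    baseline_level: float = 50.0
    baseline_noise_sd: float = 10.0
    sampling_interval: float = 0.002
    rt_jitter_sd: float = 0.01
    window_halfwidth: float = 0.2
    seed: int = 0
    response_groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        for name in (
            "peak_width_sigma", "response_factor_median", "response_factor_sigma",
            "sampling_interval", "window_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_cv", "baseline_level", "baseline_noise_sd", "rt_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.noise_cv < 1:
            raise ValueError("noise_cv must be < 1")

    def group_of(self, peptide_seq: str) -> str:
        if self.response_groups:
            return self.response_groups.get(peptide_seq, peptide_seq)
        return peptide_seq


@dataclass(frozen=True)
class Chromatogram:
    """One transition's intensity trace on a uniform time grid (minutes)."""

    transition_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be 1-D and equal length")
        dt = np.diff(t)
        if len(dt) and (dt.min() <= 0 or np.ptp(dt) > 1e-9):
            raise ValueError("times must be strictly increasing and uniform")
        if (y < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Amounts (ng) actually simulated, keyed by peptide sequence."""

    light_ng: Mapping[str, float]
    heavy_ng: Mapping[str, float]

    def __post_init__(self) -> None:
        for amounts in (self.light_ng, self.heavy_ng):
            for seq, ng in amounts.items():
                if ng < 0:
                    raise ValueError(f"negative amount for {seq}")


def _transition_rank(panel: TransitionPanel, t: Transition) -> int:
    """Position of *t* within its peptide-form's transition triple."""
    siblings = panel.transitions_for(t.peptide.sequence, t.peptide.label)
    return siblings.index(t)


def draw_response_factors(
    panel: TransitionPanel, config: SimulationConfig
) -> dict[str, float]:
    """Per-transition response factors (area units per ng), seed-fixed.

    One lognormal draw per (response group, product rank); light and heavy
    forms — and any peptides sharing a response group — receive the same
    factor at the same rank.
    """
    rng = np.random.default_rng([config.seed, 0x5EED])
    factors: dict[str, float] = {}
    per_group: dict[tuple[str, int], float] = {}
    ln_median = math.log(config.response_factor_median)
    for t in panel:
        key = (config.group_of(t.peptide.sequence), _transition_rank(panel, t))
        if key not in per_group:
            per_group[key] = math.exp(
                rng.normal(ln_median, config.response_factor_sigma)
            )
        factors[t.transition_id] = per_group[key]
    return factors


def simulate_sample(
    panel: TransitionPanel,
    light_ng: Mapping[str, float],
    heavy_ng: Mapping[str, float],
    config: SimulationConfig,
    sample_index: int = 0,
    response_factors: Mapping[str, float] | None = None,
) -> tuple[list[Chromatogram], GroundTruth]:
    """Simulate one injection of a sample over every panel transition.

    ``light_ng`` / ``heavy_ng`` map peptide sequence to spiked amount (0 is
    allowed and yields a baseline-only trace). ``sample_index`` decorrelates
    replicate samples while keeping everything reproducible from
    ``config.seed``; ``response_factors`` may be passed to share one
    instrument response across many samples (as in a standard series).
    """
    for amounts in (light_ng, heavy_ng):
        for seq, ng in amounts.items():
            if ng < 0:
                raise ValueError(f"negative amount for {seq}")
    if response_factors is None:
        response_factors = draw_response_factors(panel, config)

    rng = np.random.default_rng([config.seed, 1, sample_index])
    # one RT jitter per peptide sequence, shared by light/heavy partners
    jitter: dict[str, float] = {}
    for pep in panel.peptides():
        if pep.sequence not in jitter:
            jitter[pep.sequence] = (
                rng.normal(0.0, config.rt_jitter_sd) if config.rt_jitter_sd else 0.0
            )

    sigma_ln = math.sqrt(math.log(1.0 + config.noise_cv**2))
    chroms: list[Chromatogram] = []
    for t in panel:
        amounts = light_ng if t.peptide.label == "light" else heavy_ng
        try:
            ng = amounts[t.peptide.sequence]
        except KeyError:
            raise KeyError(
                f"no {t.peptide.label} amount provided for {t.peptide.sequence}"
            ) from None
        area = ng * response_factors[t.transition_id]
        if sigma_ln and ng > 0:
            area *= math.exp(rng.normal(0.0, sigma_ln))
        n = int(round(2 * config.window_halfwidth / config.sampling_interval)) + 1
        times = t.retention_time - config.window_halfwidth + (
            config.sampling_interval * np.arange(n)
        )
        center = t.retention_time + jitter[t.peptide.sequence]
        sig = config.peak_width_sigma
        peak = (area / (sig * math.sqrt(2.0 * math.pi))) * np.exp(
            -0.5 * ((times - center) / sig) ** 2
        )
        baseline = np.full(n, config.baseline_level)
        if config.baseline_noise_sd:
            baseline = baseline + rng.normal(0.0, config.baseline_noise_sd, size=n)
        chroms.append(
            Chromatogram(
                transition_id=t.transition_id,
                times=times,
                intensities=np.clip(baseline + peak, 0.0, None),
            )
        )
    truth = GroundTruth(light_ng=dict(light_ng), heavy_ng=dict(heavy_ng))
    return chroms, truth


def simulate_standard_series(
    panel: TransitionPanel,
    standard_ng: Sequence[float] = DEFAULT_STANDARDS_NG,
    silac_ng: float = DEFAULT_SILAC_NG,
    replicates: int = 5,
    config: SimulationConfig = SimulationConfig(),
    analyte_peptides: Sequence[str] | None = None,
) -> list[tuple[list[Chromatogram], GroundTruth]]:
    """Simulate a calibration series: one sample per standard x replicate.

    Each sample carries ``standard_ng[i]`` of analyte on every light channel
    and ``silac_ng`` on every heavy channel (by default the analyte peptides
    are exactly those light peptides that have a heavy partner in the
    panel, i.e. the internal-standard protein's peptides). Samples are
    ordered level-major: (level 0, rep 0), (level 0, rep 1), ...
    """
    levels = list(standard_ng)
    if not levels or any(x <= 0 for x in levels):
        raise ValueError("standard amounts must be positive")
    if sorted(levels) != levels:
        raise ValueError("standard amounts must be increasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    heavy_seqs = {p.sequence for p in panel.peptides() if p.label == "heavy"}
    light_seqs = [p.sequence for p in panel.peptides() if p.label == "light"]
    if analyte_peptides is None:
        analyte_peptides = [s for s in light_seqs if s in heavy_seqs]

    response_factors = draw_response_factors(panel, config)
    out = []
    for i, level in enumerate(levels):
        light = {s: (level if s in analyte_peptides else 0.0) for s in light_seqs}
        heavy = {s: silac_ng for s in heavy_seqs}
        for j in range(replicates):
            out.append(
                simulate_sample(
                    panel, light, heavy, config,
                    sample_index=i * replicates + j,
                    response_factors=response_factors,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Long-format TSV I/O
# ---------------------------------------------------------------------------

def write_chromatogram_tsv(
    samples: Mapping[str, Sequence[Chromatogram]], path: str | Path
) -> None:
    """Write chromatograms as long-format TSV.

    Columns: sample_id, transition_id, time_min, intensity.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id", "transition_id", "time_min", "intensity"])
        for sample_id, chroms in samples.items():
            for c in chroms:
                for t, y in zip(c.times, c.intensities):
                    w.writerow([sample_id, c.transition_id, f"{t:.6f}", f"{y:.6f}"])


def read_chromatogram_tsv(path: str | Path) -> dict[str, list[Chromatogram]]:
    """Inverse of :func:`write_chromatogram_tsv`."""
    rows: dict[str, dict[str, list[tuple[float, float]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.setdefault(row["sample_id"], {}).setdefault(
                row["transition_id"], []
            ).append((float(row["time_min"]), float(row["intensity"])))
    out: dict[str, list[Chromatogram]] = {}
    for sample_id, per_transition in rows.items():
        out[sample_id] = [
            Chromatogram(
                transition_id=tid,
                times=np.array([p[0] for p in points]),
                intensities=np.array([p[1] for p in points]),
            )
            for tid, points in per_transition.items()
        ]
    return out


def write_ground_truth_csv(
    truths: Mapping[str, GroundTruth], path: str | Path
) -> None:
    """Sidecar CSV of simulated amounts: sample_id, peptide, label, ng."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "peptide", "label", "ng"])
        for sample_id, truth in truths.items():
            for seq, ng in truth.light_ng.items():
                w.writerow([sample_id, seq, "light", f"{ng:g}"])
            for seq, ng in truth.heavy_ng.items():
                w.writerow([sample_id, seq, "heavy", f"{ng:g}"])
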