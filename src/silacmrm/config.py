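"""Run configuration: a sectioned key/value file that round-trips losslessly.

Every pipeline command resolves its options into a :class:`RunConfig` and
writes the resolved file beside its outputs, so a run can be reproduced
from the output directory alone.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .chromsim import DEFAULT_SILAC_NG, DEFAULT_STANDARDS_NG, SimulationConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved options of one pipeline run."""

    # [digest]
    max_missed: int = 1
    min_length: int = 6
    # [mass]
    label_residue: str = "L"
    label_shift: float = 6.020129
    # [simulate]
    standards_ng: tuple[float, ...] = DEFAULT_STANDARDS_NG
    silac_ng: float = DEFAULT_SILAC_NG
    replicates: int = 5
    noise_cv: float = 0.08
    peak_width_sigma: float = 0.03
    baseline_level: float = 50.0
    baseline_noise_sd: float = 10.0
    sampling_interval: float = 0.002
    rt_jitter_sd: float = 0.01
    # [quant]
    estimator: str = "ratio_of_sums"
    weighting: str = "1/x2"
    rt_window: float = 0.1
    rt_tolerance: float = 0.1
    # [run]
    seed: int = 0

    _SECTIONS = {
        "digest": ("max_missed", "min_length"),
        "mass": ("label_residue", "label_shift"),
        "simulate": (
            "standards_ng", "silac_ng", "replicates", "noise_cv",
            "peak_width_sigma", "baseline_level", "baseline_noise_sd",
            "sampling_interval", "rt_jitter_sd",
        ),
        "quant": ("estimator", "weighting", "rt_window", "rt_tolerance"),
        "run": ("seed",),
    }

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            peak_width_sigma=self.peak_width_sigma,
            noise_cv=self.noise_cv,
            baseline_level=self.baseline_level,
            baseline_noise_sd=self.baseline_noise_sd,
            sampling_interval=self.sampling_interval,
            rt_jitter_sd=self.rt_jitter_sd,
            seed=self.seed,
        )

    def to_ini(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        for section, names in self._SECTIONS.items():
            cp[section] = {}
            for name in names:
                value = getattr(self, name)
                if isinstance(value, tuple):
                    value = ",".join(f"{v:g}" for v in value)
                cp[section][name] = str(value)
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(str(path)):
            raise FileNotFoundError(path)
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for section, names in cls._SECTIONS.items():
            if section not in cp:
                continue
            for name in names:
                if name not in cp[section]:
                    continue
                raw = cp[section][name]
                if name == "standards_ng":
                    kwargs[name] = tuple(float(v) for v in raw.split(","))
                elif types[name] == "int":
                    kwargs[name] = int(raw)
                elif types[name] == "float":
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = raw
        return cls(**kwargs)

    def override(self, **kwargs) -> "RunConfig":
        """A copy with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
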