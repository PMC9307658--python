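"""Configuration dataclasses for the synthetic cohort generator and the pipeline.

All defaults mirror the study design they emulate: 56 participants, 28
paired-/single-pulse stimulations per trial condition, MEP acceptance window
0.2--9 mV, reaction-time window 150--800 ms, precontraction ceiling 0.4 mV,
nine-MEPs-per-condition inclusion rule, alpha 0.05, 10,000 bootstrap
repetitions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

MODALITIES = ("MT", "R1", "R2s", "FA")

CONTAMINATION_KINDS = (
    "premature",
    "slow",
    "incorrect",
    "precontraction",
    "extreme_amplitude",
)


class ConfigError(ValueError):
    """Raised when a configuration field has an invalid value."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    The mediation layer is a linear-Gaussian structural model on a latent
    per-subject myelin factor ``x``::

        m1 = path_a * x + e1               (switch PP/SP ratio, latent scale)
        m2 = path_d21 * m1 + e2            (switch M1 inhibition, latent scale)
        y  = path_b2 * m2 + path_c_direct * x + e3   (switch RT cost, latent scale)

    with independent Gaussian residuals of standard deviation
    ``structural_noise_sd``. The default path coefficients are calibrated so
    that the *measured* subject metrics -- after trial sampling noise from 28
    stimulations per condition -- reproduce the correlation structure
    observed in the motivating experiment (myelin-PP/SP r ~= -0.40,
    PP/SP-M1-inhibition r ~= -0.52, M1-inhibition-RT-cost r ~= -0.31, ~62%
    of the total myelin->behaviour effect carried by the serial indirect
    path).

    Latent metric variables are mapped to strictly positive observable ratios
    through a lognormal link: ``ratio = base * exp(scale * z)`` where ``z`` is
    the standardized latent variable.
    """

    n_subjects: int = 56
    n_voxels: int = 500
    signal_fraction: float = 0.10
    modality_loadings: tuple[float, float, float, float] = (1.5, 1.5, 1.2, 0.9)
    modality_noise_sd: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    path_a: float = -0.655
    path_d21: float = -0.620
    path_b2: float = -0.355
    path_c_direct: float = -0.0891
    structural_noise_sd: tuple[float, float, float] = (1.0, 1.0, 1.0)
    trials_per_condition: int = 28
    contamination_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "premature": 0.01,
            "slow": 0.01,
            "incorrect": 0.05,
            "precontraction": 0.02,
            "extreme_amplitude": 0.02,
        }
    )
    mep_noise: float = 0.5          # lognormal sigma of trial MEPs around the condition median
    rt_noise_ms: float = 60.0       # SD of trial reaction times around the condition mean
    mep_base_mv: float = 1.0        # median SP-stay MEP (1 mV targeting intensity)
    stay_rt_ms: float = 450.0       # mean stay-trial reaction time
    ratio_bases: tuple[float, float, float] = (0.85, 0.75, 1.15)   # PP/SP, M1 inhibition, RT cost
    ratio_scales: tuple[float, float, float] = (0.20, 0.25, 0.08)  # lognormal scales of the ratios
    pp_stay_ratio: float = 0.95     # PP/SP ratio on stay trials (not used by any metric)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_voxels", "trials_per_condition"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("signal_fraction", "pp_stay_ratio"):
            v = getattr(self, name)
            if not 0.0 <= float(self.signal_fraction) <= 1.0:
                raise ConfigError(f"signal_fraction must lie in [0, 1], got {self.signal_fraction!r}")
        for name in ("modality_loadings", "structural_noise_sd", "ratio_bases", "ratio_scales"):
            v = tuple(getattr(self, name))
            object.__setattr__(self, name, v)
        if len(self.modality_loadings) != len(MODALITIES):
            raise ConfigError("modality_loadings must have one entry per modality (MT, R1, R2s, FA)")
        if len(self.modality_noise_sd) != len(MODALITIES):
            raise ConfigError("modality_noise_sd must have one entry per modality (MT, R1, R2s, FA)")
        object.__setattr__(self, "modality_noise_sd", tuple(self.modality_noise_sd))
        for name in ("modality_noise_sd", "structural_noise_sd"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ConfigError(f"{name} entries must be positive")
        if self.mep_noise <= 0:
            raise ConfigError(f"mep_noise must be positive, got {self.mep_noise!r}")
        if self.rt_noise_ms <= 0:
            raise ConfigError(f"rt_noise_ms must be positive, got {self.rt_noise_ms!r}")
        rates = dict(self.contamination_rates)
        unknown = set(rates) - set(CONTAMINATION_KINDS)
        if unknown:
            raise ConfigError(f"contamination_rates has unknown kinds: {sorted(unknown)}")
        for kind in CONTAMINATION_KINDS:
            rates.setdefault(kind, 0.0)
            if not 0.0 <= rates[kind] <= 1.0:
                raise ConfigError(f"contamination_rates[{kind!r}] must lie in [0, 1]")
        if sum(rates.values()) > 1.0 + 1e-12:
            raise ConfigError("contamination_rates must sum to at most 1")
        object.__setattr__(self, "contamination_rates", rates)
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contamination_rates"] = dict(d["contamination_rates"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("modality_loadings", "modality_noise_sd", "structural_noise_sd",
                    "ratio_bases", "ratio_scales"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class FilterThresholds:
    """Trial-level acceptance thresholds; all comparisons are strict, as printed."""

    min_mep_mv: float = 0.2
    max_mep_mv: float = 9.0
    min_rt_ms: float = 150.0
    max_rt_ms: float = 800.0
    max_precontraction_mv: float = 0.4

    def __post_init__(self) -> None:
        if self.min_mep_mv >= self.max_mep_mv:
            raise ConfigError("min_mep_mv must be below max_mep_mv")
        if self.min_rt_ms >= self.max_rt_ms:
            raise ConfigError("min_rt_ms must be below max_rt_ms")
        if self.max_precontraction_mv <= 0:
            raise ConfigError("max_precontraction_mv must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    Paths may be None when the pipeline starts from a simulated cohort held in
    memory. Every stage parameter defaults to the value used in the motivating
    experiment where one is stated.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    grubbs_alpha: float = 0.05
    min_meps_per_condition: int = 9
    n_permutations: int = 1000
    direction: str = "negative"
    transform_voxels: bool = False
    alpha: float = 0.05
    n_boot: int = 10000
    ci_method: str = "percentile"
    standardize: bool = True
    seed: int = 0
    trial_dir: str | None = None
    skeleton_path: str | None = None
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.grubbs_alpha < 1:
            raise ConfigError("grubbs_alpha must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_meps_per_condition < 1:
            raise ConfigError("min_meps_per_condition must be >= 1")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        if self.direction not in ("negative", "positive", "two-sided"):
            raise ConfigError("direction must be 'negative', 'positive' or 'two-sided'")
        if self.ci_method not in ("percentile", "bca"):
            raise ConfigError("ci_method must be 'percentile' or 'bca'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "thresholds" in d and not isinstance(d["thresholds"], FilterThresholds):
            d["thresholds"] = FilterThresholds(**d["thresholds"])
        return cls(**d)

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)
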