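"""Trial configuration: every tunable constant of generation, scoring and
inference, with lossless YAML round-tripping and a content hash for
provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from painrct.errors import ConfigError
from painrct.nnrf import AlignConfig, ArtefactThresholds, FilterConfig, TemplateParams

__all__ = ["TrialConfig"]


@dataclass(frozen=True)
class DemographicsConfig:
    """Cohort covariate distributions (defaults calibrated to a late-preterm
    and term heel-lance population: GA median ~38.4 wk, 61 % male, ~65 % of
    strokes delivered by mothers, jaundice the dominant blood-test reason)."""

    ga_mean: float = 38.4
    ga_sd: float = 1.8
    ga_range: tuple[float, float] = (35.0, 42.0)
    p_male: float = 0.61
    p_site_a: float = 0.74
    p_mother_strokes: float = 0.65
    reason_probs: dict = field(
        default_factory=lambda: {
            "jaundice": 0.48,
            "sepsis": 0.29,
            "screening": 0.07,
            "glucose": 0.05,
            "other": 0.11,
        }
    )
    p_awake: float = 0.27
    postnatal_binom_n: int = 7
    postnatal_binom_p: float = 0.45
    prior_procedures_gamma_shape: float = 2.0
    prior_procedures_gamma_scale: float = 2.0

    def __post_init__(self) -> None:
        total = sum(self.reason_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"blood-test reason probabilities sum to {total}, not 1")
        for name in ("p_male", "p_site_a", "p_mother_strokes", "p_awake"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class EEGSimConfig:
    """Synthetic epoch model: 1/f background noise plus the template at a
    jittered latency on Cz (attenuated copies on the other channels)."""

    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (-0.5, 1.0)
    pink_exponent: float = 1.0
    noise_rms_uv: float = 5.0
    mains_amplitude_uv: float = 0.0
    mains_freq_hz: float = 50.0
    latency_jitter_sd_ms: float = 20.0
    latency_jitter_max_ms: float = 50.0
    neighbour_attenuation: float = 0.5


@dataclass(frozen=True)
class VitalsConfig:
    """Heart-rate / SpO2 trace model around the lance.

    The post-lance surge peak is drawn either side of the 160 bpm
    tachycardia threshold with probability ``p_cross`` (with a safety
    margin so measurement noise cannot flip the detector), unless a
    ``fixed_surge_amplitude`` overrides the draw.
    """

    baseline_hr_mean: float = 135.0
    baseline_hr_sd: float = 10.0
    baseline_hr_max: float = 155.0
    p_cross: float = 0.10
    crossing_peak_range: tuple[float, float] = (162.0, 180.0)
    subthreshold_peak_max: float = 156.0
    fixed_surge_amplitude: float | None = None
    surge_rise_s: float = 5.0
    surge_decay_s: float = 15.0
    hr_noise_sd: float = 0.5
    spo2_baseline: float = 97.0
    spo2_dip_max: float = 5.0
    spo2_recovery_s: float = 20.0
    sample_rate: float = 4.0
    window: tuple[float, float] = (-60.0, 60.0)


@dataclass(frozen=True)
class BehaviourConfig:
    """Monotone link from true response magnitude to facial-action durations."""

    seconds_per_unit: float = 8.0
    weights: tuple[float, float, float] = (1.0, 0.9, 0.8)
    noise_sd: float = 2.0
    observation_window: float = 30.0


@dataclass(frozen=True)
class ComplianceConfig:
    """Stroke-to-lance delay model and the compliance rule.

    Intervention-arm delays are log-normal (median ~17 s); a delay of
    more than ``threshold_s`` (45 s) before the lance is non-compliance.
    If ``target_rate`` is set, the log-SD is solved so that
    P(delay <= threshold) equals it exactly.
    """

    delay_median_s: float = 17.0
    delay_sigma_log: float = 0.8
    target_rate: float | None = None
    threshold_s: float = 45.0
    stroke_duration_s: float = 10.0
    control_start_min_s: float = 30.0
    control_start_spread_s: float = 30.0


@dataclass(frozen=True)
class StaiConfig:
    """Parental state-anxiety totals: latent per-parent anxiety plus stage
    means (defaults near the working-adult mean of ~35)."""

    trait_mean: float = 38.0
    state_baseline_mean: float = 35.0
    post_state_mean: float = 35.0
    latent_scale: float = 6.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class GroundTruthConfig:
    """True data-generating effect parameters stored with every dataset."""

    complier_effect_r: float = 0.4
    control_magnitude_mean: float = 1.07
    control_magnitude_sd: float = 0.66
    score_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.complier_effect_r <= 1:
            raise ConfigError("complier_effect_r must be in [0, 1]")


@dataclass(frozen=True)
class MinimisationConfig:
    p_assign: float = 0.8
    ga_strata: tuple[float, ...] = (37.0, 39.0)
    postnatal_strata: tuple[int, ...] = (3,)


@dataclass(frozen=True)
class InferenceConfig:
    n_permutations: int = 10000
    alpha_primary: float = 0.05
    alpha_family_secondary: float = 0.05
    statistic: str = "huber"


@dataclass(frozen=True)
class MissingnessConfig:
    """Completely-at-random per-outcome loss rates."""

    nnrf: float = 0.0
    pipp: float = 0.0
    tachycardia: float = 0.0
    stai: float = 0.0


_SECTIONS = {
    "demographics": DemographicsConfig,
    "eeg": EEGSimConfig,
    "vitals": VitalsConfig,
    "behaviour": BehaviourConfig,
    "compliance": ComplianceConfig,
    "stai": StaiConfig,
    "ground_truth": GroundTruthConfig,
    "minimisation": MinimisationConfig,
    "template": TemplateParams,
    "filter": FilterConfig,
    "artefact": ArtefactThresholds,
    "align": AlignConfig,
    "inference": InferenceConfig,
    "missingness": MissingnessConfig,
}


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


@dataclass
class TrialConfig:
    """Root configuration for a full synthetic-trial run."""

    seed: int = 0
    n: int = 112
    demographics: DemographicsConfig = field(default_factory=DemographicsConfig)
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)
    vitals: VitalsConfig = field(default_factory=VitalsConfig)
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)
    compliance: ComplianceConfig = field(default_factory=ComplianceConfig)
    stai: StaiConfig = field(default_factory=StaiConfig)
    ground_truth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    minimisation: MinimisationConfig = field(default_factory=MinimisationConfig)
    template: TemplateParams = field(default_factory=TemplateParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    artefact: ArtefactThresholds = field(default_factory=ArtefactThresholds)
    align: AlignConfig = field(default_factory=AlignConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "TrialConfig":
        kwargs = {}
        for key, value in data.items():
            if key in _SECTIONS:
                if not isinstance(value, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                try:
                    kwargs[key] = _SECTIONS[key](**sub)
                except TypeError as exc:
                    raise ConfigError(f"bad key in config section {key!r}: {exc}") from None
            elif key in ("seed", "n"):
                kwargs[key] = int(value)
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrialConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; changes iff any value changes."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def replace(self, **kwargs) -> "TrialConfig":
        return dataclasses.replace(self, **kwargs)
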