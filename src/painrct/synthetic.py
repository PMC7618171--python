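"""Synthetic two-arm neonatal pain-trial generator with stored ground truth.

Everything the analysis pipeline consumes can be generated here: a cohort
of eligible neonates (born >= 35 wk gestation, studied within the first
week), minimisation-based allocations, stroke-timing compliance records,
stimulus-locked EEG epochs (a calibrated response template in 1/f noise),
heart-rate / SpO2 traces, facial-action annotations and parental STAI
sheets. The data-generating effect is multiplicative on the true response
magnitude of compliant intervention babies (magnitude x (1 - r)), and all
true parameters are stored alongside the dataset so recovery can be
tested. All randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from painrct.config import (
    BehaviourConfig,
    ComplianceConfig,
    DemographicsConfig,
    EEGSimConfig,
    StaiConfig,
    TrialConfig,
    VitalsConfig,
)
from painrct.epochs import CHANNELS, EEGEpoch
from painrct.errors import ConfigError, InvalidArgumentError
from painrct.nnrf import ANALYSIS_CHANNEL, Template, build_template
from painrct.randomisation import MinimisationState, allocate

__all__ = [
    "ParticipantRecord",
    "ComplianceRecord",
    "VitalTrace",
    "FacialAnnotation",
    "StaiResponse",
    "GroundTruth",
    "TrialDataset",
    "generate_cohort",
    "simulate_epoch",
    "simulate_vitals",
    "simulate_behaviour",
    "simulate_compliance",
    "is_compliant",
    "simulate_parent_stai",
    "generate_trial",
    "generate_outcome_frame",
    "compliance_sigma",
    "expected_compliance_rate",
]

SEXES = ("female", "male")
SITES = ("A", "B")
REASONS = ("glucose", "jaundice", "screening", "sepsis", "other")
OUTCOMES = ("nnrf", "pipp", "tachycardia", "stai")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    gestational_age_at_birth: float   # weeks
    postnatal_age: int                # days
    sex: str
    site: str
    blood_test_reason: str
    stroking_parent: str
    behavioural_state_baseline: str   # awake / asleep
    prior_painful_procedures: int

    def __post_init__(self) -> None:
        if self.gestational_age_at_birth < 35:
            raise InvalidArgumentError("gestational age below 35 wk is ineligible")
        if not 0 <= self.postnatal_age <= 7:
            raise InvalidArgumentError("postnatal age must be in [0, 7] days")

    @property
    def postmenstrual_age(self) -> float:
        """Weeks: gestational age at birth plus postnatal age."""
        return self.gestational_age_at_birth + self.postnatal_age / 7.0


@dataclass(frozen=True)
class ComplianceRecord:
    arm: str
    stroke_start: float               # s relative to the lance
    stroke_end: float
    delay_to_lance: float             # s, lance minus stroke start (NaN for control)
    compliant: bool


@dataclass
class VitalTrace:
    time: np.ndarray                  # seconds, strictly increasing
    heart_rate: np.ndarray            # bpm
    spo2: np.ndarray                  # percent
    lance_time: float
    sham_time: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.heart_rate = np.asarray(self.heart_rate, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if np.any(self.heart_rate <= 0):
            raise InvalidArgumentError("heart rate must be positive")
        if np.any((self.spo2 < 0) | (self.spo2 > 100)):
            raise InvalidArgumentError("SpO2 must lie in [0, 100]")


@dataclass(frozen=True)
class FacialAnnotation:
    brow_bulge_duration: float
    eye_squeeze_duration: float
    nasolabial_furrow_duration: float
    observation_window: float = 30.0

    def __post_init__(self) -> None:
        for name in ("brow_bulge_duration", "eye_squeeze_duration", "nasolabial_furrow_duration"):
            v = getattr(self, name)
            if not 0 <= v <= self.observation_window + 1e-9:
                raise InvalidArgumentError(
                    f"{name}={v} outside [0, {self.observation_window}] s"
                )


@dataclass(frozen=True)
class StaiResponse:
    respondent: str
    stage: str                        # baseline_trait / baseline_state / post_state
    items: np.ndarray                 # 20 raw responses in [1, 4]

    def __post_init__(self) -> None:
        arr = np.asarray(self.items, dtype=int)
        if arr.shape != (20,) or np.any((arr < 1) | (arr > 4)):
            raise InvalidArgumentError("STAI sheet needs exactly 20 items in [1, 4]")
        object.__setattr__(self, "items", arr)


@dataclass
class GroundTruth:
    """True generating parameters, stored with every dataset."""

    complier_effect: float            # multiplicative reduction r in [0, 1]
    control_magnitude_mean: float
    control_magnitude_sd: float
    compliance_rate: float            # expected P(delay <= threshold) in intervention arm
    tachycardia_base_rate: float
    true_magnitudes: dict = field(default_factory=dict)  # id -> a.u.

    def __post_init__(self) -> None:
        for name in ("complier_effect", "compliance_rate", "tachycardia_base_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidArgumentError(f"{name}={v} outside [0, 1]")


@dataclass
class TrialDataset:
    participants: list
    allocations: pd.DataFrame         # id, arm, imbalance_*, p_used
    compliance: dict                  # id -> ComplianceRecord
    epochs: dict                      # id -> {"lance": EEGEpoch, "sham": EEGEpoch}
    vitals: dict                      # id -> VitalTrace
    facial: dict                      # id -> {"lance": FacialAnnotation, "sham": ...}
    stai: dict                        # id -> list[StaiResponse]
    ground_truth: GroundTruth
    seed: int
    config: TrialConfig
    missing: dict = field(default_factory=lambda: {o: set() for o in OUTCOMES})

    def arm_of(self, pid: str) -> str:
        return self.allocations.set_index("id").loc[pid, "arm"]

    def participants_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": p.id,
                "gestational_age_at_birth": p.gestational_age_at_birth,
                "postnatal_age": p.postnatal_age,
                "postmenstrual_age": p.postmenstrual_age,
                "sex": p.sex,
                "site": p.site,
                "blood_test_reason": p.blood_test_reason,
                "stroking_parent": p.stroking_parent,
                "behavioural_state_baseline": p.behavioural_state_baseline,
                "prior_painful_procedures": p.prior_painful_procedures,
            }
            for p in self.participants
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    n: int, seed, demographics: DemographicsConfig | None = None
) -> list[ParticipantRecord]:
    """Draw an eligible cohort from the configured covariate distributions."""
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    cfg = demographics or DemographicsConfig()
    rng = _rng(seed)
    lo, hi = cfg.ga_range
    a, b = (lo - cfg.ga_mean) / cfg.ga_sd, (hi - cfg.ga_mean) / cfg.ga_sd
    ga = stats.truncnorm.rvs(a, b, loc=cfg.ga_mean, scale=cfg.ga_sd, size=n, random_state=rng)
    pna = rng.binomial(cfg.postnatal_binom_n, cfg.postnatal_binom_p, size=n)
    sex = rng.choice(SEXES, size=n, p=(1 - cfg.p_male, cfg.p_male))
    site = rng.choice(SITES, size=n, p=(cfg.p_site_a, 1 - cfg.p_site_a))
    reasons = list(cfg.reason_probs)
    reason = rng.choice(reasons, size=n, p=[cfg.reason_probs[r] for r in reasons])
    parent = rng.choice(
        ("mother", "father"), size=n, p=(cfg.p_mother_strokes, 1 - cfg.p_mother_strokes)
    )
    state = rng.choice(("awake", "asleep"), size=n, p=(cfg.p_awake, 1 - cfg.p_awake))
    prior = np.rint(
        rng.gamma(cfg.prior_procedures_gamma_shape, cfg.prior_procedures_gamma_scale, size=n)
    ).astype(int)
    return [
        ParticipantRecord(
            id=f"P{i + 1:03d}",
            gestational_age_at_birth=round(float(ga[i]), 2),
            postnatal_age=int(pna[i]),
            sex=str(sex[i]),
            site=str(site[i]),
            blood_test_reason=str(reason[i]),
            stroking_parent=str(parent[i]),
            behavioural_state_baseline=str(state[i]),
            prior_painful_procedures=int(prior[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# EEG


def _pink_noise(rng: np.random.Generator, n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_epoch(
    participant,
    true_magnitude: float,
    noise: EEGSimConfig | None = None,
    seed=None,
    template: Template | None = None,
    event_kind: str = "lance",
) -> EEGEpoch:
    """One stimulus-locked epoch: background noise plus the scaled template.

    The template (scaled by ``true_magnitude``) is inserted on Cz at its
    nominal latency plus a truncated-Gaussian jitter; the other channels
    receive an attenuated copy. Sham epochs are generated with
    ``true_magnitude = 0``.
    """
    cfg = noise or EEGSimConfig()
    rng = _rng(seed)
    template = template or build_template()
    fs = cfg.sampling_rate
    w0, w1 = cfg.epoch_window
    n = int(round((w1 - w0) * fs))
    stim = int(round(-w0 * fs))
    jitter_max = cfg.latency_jitter_max_ms / 1000.0
    if template.analysis_window[1] + jitter_max > w1 or template.analysis_window[0] - jitter_max < 0:
        raise ConfigError(
            "latency jitter can push the template outside the epoch window"
        )

    times = (np.arange(n) - stim) / fs
    data = np.zeros((len(CHANNELS), n))
    if cfg.noise_rms_uv > 0:
        for ch in range(len(CHANNELS)):
            data[ch] = cfg.noise_rms_uv * _pink_noise(rng, n, fs, cfg.pink_exponent)
    if cfg.mains_amplitude_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += cfg.mains_amplitude_uv * np.sin(
            2 * np.pi * cfg.mains_freq_hz * times + phase
        )

    if true_magnitude != 0:
        if cfg.latency_jitter_sd_ms > 0:
            bound = cfg.latency_jitter_max_ms / cfg.latency_jitter_sd_ms
            jitter_ms = float(
                stats.truncnorm.rvs(-bound, bound, scale=cfg.latency_jitter_sd_ms, random_state=rng)
            )
        else:
            jitter_ms = 0.0
        shifted = template.sampled_at(times - jitter_ms / 1000.0)
        cz = CHANNELS.index(ANALYSIS_CHANNEL)
        for ch in range(len(CHANNELS)):
            gain = 1.0 if ch == cz else cfg.neighbour_attenuation
            data[ch] += true_magnitude * gain * shifted

    return EEGEpoch(
        sampling_rate=fs,
        channels=CHANNELS,
        data=data,
        epoch_window=(w0, w1),
        stimulus_index=stim,
        event_kind=event_kind,
    )


# ---------------------------------------------------------------------------
# vitals


def simulate_vitals(
    participant,
    compliance: ComplianceRecord | None = None,
    response: VitalsConfig | None = None,
    seed=None,
) -> VitalTrace:
    """Piecewise-smooth HR / SpO2 traces around the lance.

    The post-lance surge peak is drawn above the 160 bpm threshold with
    probability ``p_cross`` (or set by ``fixed_surge_amplitude``); the
    pre-lance baseline always stays below it.
    """
    cfg = response or VitalsConfig()
    rng = _rng(seed)
    rel = np.arange(cfg.window[0], cfg.window[1] + 0.5 / cfg.sample_rate, 1.0 / cfg.sample_rate)
    baseline = min(float(rng.normal(cfg.baseline_hr_mean, cfg.baseline_hr_sd)), cfg.baseline_hr_max)
    baseline = max(baseline, 60.0)

    if cfg.fixed_surge_amplitude is not None:
        amp = float(cfg.fixed_surge_amplitude)
    elif rng.random() < cfg.p_cross:
        amp = float(rng.uniform(*cfg.crossing_peak_range)) - baseline
    else:
        hi = cfg.subthreshold_peak_max
        lo = min(baseline + 1.0, hi - 0.5)
        amp = max(float(rng.uniform(lo, hi)) - baseline, 0.0)

    shape = np.zeros_like(rel)
    rise = rel >= 0
    shape[rise] = np.where(
        rel[rise] < cfg.surge_rise_s,
        rel[rise] / cfg.surge_rise_s,
        np.exp(-(rel[rise] - cfg.surge_rise_s) / cfg.surge_decay_s),
    )
    hr = baseline + amp * shape + rng.normal(0, cfg.hr_noise_sd, size=rel.size)
    hr = np.maximum(hr, 30.0)

    dip = float(rng.uniform(0, cfg.spo2_dip_max))
    spo2_shape = np.zeros_like(rel)
    post = rel >= 0
    spo2_shape[post] = np.where(
        rel[post] < cfg.surge_rise_s,
        rel[post] / cfg.surge_rise_s,
        np.exp(-(rel[post] - cfg.surge_rise_s) / cfg.spo2_recovery_s),
    )
    spo2 = cfg.spo2_baseline - dip * spo2_shape + rng.normal(0, 0.2, size=rel.size)
    spo2 = np.clip(spo2, 0.0, 100.0)

    lance_time = -cfg.window[0]
    return VitalTrace(
        time=rel + lance_time,
        heart_rate=hr,
        spo2=spo2,
        lance_time=lance_time,
        sham_time=lance_time - 30.0,
    )


# ---------------------------------------------------------------------------
# behaviour, compliance, STAI


def simulate_behaviour(
    participant, true_magnitude: float, config: BehaviourConfig | None = None, seed=None
) -> FacialAnnotation:
    """Facial-action durations with a monotone link to true magnitude."""
    cfg = config or BehaviourConfig()
    rng = _rng(seed)
    base = cfg.seconds_per_unit * max(float(true_magnitude), 0.0)
    durations = []
    for w in cfg.weights:
        d = w * base + (rng.normal(0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
        durations.append(float(np.clip(d, 0.0, cfg.observation_window)))
    return FacialAnnotation(*durations, observation_window=cfg.observation_window)


def compliance_sigma(cfg: ComplianceConfig) -> float:
    """Log-SD of the delay distribution, solved from ``target_rate`` if set."""
    if cfg.target_rate is None:
        return cfg.delay_sigma_log
    if not 0.5 < cfg.target_rate < 1.0:
        raise ConfigError(
            "target_rate must be in (0.5, 1) for a median below the threshold"
        )
    return math.log(cfg.threshold_s / cfg.delay_median_s) / stats.norm.ppf(cfg.target_rate)


def expected_compliance_rate(cfg: ComplianceConfig) -> float:
    """P(delay <= threshold) in the intervention arm under the config."""
    sigma = compliance_sigma(cfg)
    z = math.log(cfg.threshold_s / cfg.delay_median_s) / sigma
    return float(stats.norm.cdf(z))


def is_compliant(arm: str, delay_to_lance: float, threshold_s: float = 45.0) -> bool:
    """The compliance rule: intervention stroking must start no more than
    ``threshold_s`` before the lance (a delay of exactly 45 s is compliant);
    control participants are always compliant."""
    if arm == "control":
        return True
    return delay_to_lance <= threshold_s


def simulate_compliance(
    arm: str, compliance_config: ComplianceConfig | None = None, seed=None
) -> ComplianceRecord:
    """Draw one stroke-timing record.

    Intervention: the stroke starts ``delay`` s before the lance
    (log-normal delay); a delay of more than the 45 s threshold is
    non-compliance. Control: stroking starts at least 30 s after the
    lance and is always compliant (non-compliance is one-sided).
    """
    cfg = compliance_config or ComplianceConfig()
    rng = _rng(seed)
    if arm == "control":
        start = cfg.control_start_min_s + float(rng.uniform(0, cfg.control_start_spread_s))
        return ComplianceRecord(
            arm=arm,
            stroke_start=start,
            stroke_end=start + cfg.stroke_duration_s,
            delay_to_lance=float("nan"),
            compliant=True,
        )
    if arm != "intervention":
        raise InvalidArgumentError(f"arm must be intervention or control, got {arm!r}")
    sigma = compliance_sigma(cfg)
    delay = float(np.exp(rng.normal(math.log(cfg.delay_median_s), sigma)))
    return ComplianceRecord(
        arm=arm,
        stroke_start=-delay,
        stroke_end=-delay + cfg.stroke_duration_s,
        delay_to_lance=delay,
        compliant=is_compliant(arm, delay, cfg.threshold_s),
    )


def _items_from_total(total: int, rng: np.random.Generator, reverse_items) -> np.ndarray:
    """Raw 20-item sheet whose keyed total equals ``total`` (in [20, 80])."""
    total = int(np.clip(total, 20, 80))
    q, r = divmod(total, 20)
    scored = np.full(20, q, dtype=int)
    if r:
        bump = rng.choice(20, size=r, replace=False)
        scored[bump] += 1
    scored = np.clip(scored, 1, 4)
    raw = scored.copy()
    idx = np.array(sorted(reverse_items), dtype=int) - 1
    raw[idx] = 5 - raw[idx]
    return raw


def simulate_parent_stai(
    participant, anxiety_config: StaiConfig | None = None, seed=None
) -> list[StaiResponse]:
    """Three response sheets (trait, state-baseline, state-post) per parent.

    A latent per-parent anxiety score shifts all three totals; totals are
    then decomposed into item responses consistent with the standard
    reverse-keying, so re-scoring the sheets recovers the totals exactly.
    """
    from painrct.scores import STAI_REVERSE_ITEMS

    cfg = anxiety_config or StaiConfig()
    rng = _rng(seed)
    latent = float(rng.normal()) if cfg.latent_scale > 0 else 0.0
    out = []
    for stage, mean in (
        ("baseline_trait", cfg.trait_mean),
        ("baseline_state", cfg.state_baseline_mean),
        ("post_state", cfg.post_state_mean),
    ):
        noise = float(rng.normal(0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
        total = int(round(mean + cfg.latent_scale * latent + noise))
        items = _items_from_total(total, rng, STAI_REVERSE_ITEMS)
        out.append(
            StaiResponse(respondent=f"parent-{participant.id}", stage=stage, items=items)
        )
    return out


# ---------------------------------------------------------------------------
# whole-trial generation


def _allocate_cohort(cohort, config: TrialConfig, rng_alloc) -> pd.DataFrame:
    state = MinimisationState(
        p_assign=config.minimisation.p_assign,
        ga_strata=config.minimisation.ga_strata,
        postnatal_strata=config.minimisation.postnatal_strata,
    )
    rows = []
    for p in cohort:
        _, info = allocate(p, state, rng_alloc)
        rows.append({"id": p.id, **info})
    return pd.DataFrame(rows)[
        ["id", "arm", "imbalance_intervention", "imbalance_control", "p_used"]
    ]


def _true_magnitude(arm, compliant, rng, gt) -> float:
    m0 = float(rng.normal(gt.control_magnitude_mean, gt.control_magnitude_sd))
    if arm == "intervention" and compliant:
        return m0 * (1.0 - gt.complier_effect_r)
    return m0


def generate_trial(config: TrialConfig | None = None) -> TrialDataset:
    """Generate a complete synthetic trial dataset, signals included.

    Participants are allocated sequentially through the minimisation
    module; compliant intervention babies have their true response
    magnitude multiplied by ``1 - r``; all signals are then simulated
    from the per-participant truth, and the truth is stored.
    """
    config = config or TrialConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_alloc, rng_truth, rng_signals, rng_missing = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    cohort = generate_cohort(config.n, rng_cohort, config.demographics)
    allocations = _allocate_cohort(cohort, config, rng_alloc)
    arms = dict(zip(allocations.id, allocations.arm))
    template = build_template(config.template)

    compliance: dict[str, ComplianceRecord] = {}
    truths: dict[str, float] = {}
    epochs, vitals, facial, stai = {}, {}, {}, {}
    for p in cohort:
        arm = arms[p.id]
        rec = simulate_compliance(arm, config.compliance, rng_truth)
        compliance[p.id] = rec
        m = _true_magnitude(arm, rec.compliant, rng_truth, config.ground_truth)
        truths[p.id] = m
        epochs[p.id] = {
            "lance": simulate_epoch(p, m, config.eeg, rng_signals, template, "lance"),
            "sham": simulate_epoch(p, 0.0, config.eeg, rng_signals, template, "sham"),
        }
        vitals[p.id] = simulate_vitals(p, rec, config.vitals, rng_signals)
        facial[p.id] = {
            "lance": simulate_behaviour(p, m, config.behaviour, rng_signals),
            "sham": simulate_behaviour(p, 0.0, config.behaviour, rng_signals),
        }
        stai[p.id] = simulate_parent_stai(p, config.stai, rng_signals)

    missing = {o: set() for o in OUTCOMES}
    loss = config.missingness
    for outcome, rate in (
        ("nnrf", loss.nnrf),
        ("pipp", loss.pipp),
        ("tachycardia", loss.tachycardia),
        ("stai", loss.stai),
    ):
        if rate > 0:
            lost = rng_missing.random(len(cohort)) < rate
            missing[outcome] = {p.id for p, m in zip(cohort, lost) if m}

    gt = GroundTruth(
        complier_effect=config.ground_truth.complier_effect_r,
        control_magnitude_mean=config.ground_truth.control_magnitude_mean,
        control_magnitude_sd=config.ground_truth.control_magnitude_sd,
        compliance_rate=expected_compliance_rate(config.compliance),
        tachycardia_base_rate=config.vitals.p_cross,
        true_magnitudes=truths,
    )
    return TrialDataset(
        participants=cohort,
        allocations=allocations,
        compliance=compliance,
        epochs=epochs,
        vitals=vitals,
        facial=facial,
        stai=stai,
        ground_truth=gt,
        seed=config.seed,
        config=config,
        missing=missing,
    )


def generate_outcome_frame(config: TrialConfig | None = None, seed=None) -> pd.DataFrame:
    """Score-level synthetic trial: one row per participant, no raw signals.

    Observed outcomes are drawn directly from the per-participant truth
    (response magnitude plus measurement noise of SD
    ``ground_truth.score_noise_sd``), which matches the sampling
    distribution of the template-regression scorer on simulated epochs.
    Used for inference simulation studies where thousands of replicate
    trials are needed.
    """
    config = config or TrialConfig()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_alloc, rng_truth, rng_out, rng_missing = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    cohort = generate_cohort(config.n, rng_cohort, config.demographics)
    allocations = _allocate_cohort(cohort, config, rng_alloc)
    arms = dict(zip(allocations.id, allocations.arm))
    gt = config.ground_truth

    rows = []
    for p in cohort:
        arm = arms[p.id]
        rec = simulate_compliance(arm, config.compliance, rng_truth)
        m = _true_magnitude(arm, rec.compliant, rng_truth, config.ground_truth)
        nnrf = m + float(rng_out.normal(0, gt.score_noise_sd))
        pipp = float(np.clip(np.rint(4.0 + 1.5 * m + rng_out.normal(0, 2.5)), 0, 21))
        tachy = int(rng_out.random() < config.vitals.p_cross)
        stai_base = float(np.clip(np.rint(rng_out.normal(35.0, 7.0)), 20, 80))
        stai_post = float(
            np.clip(np.rint(14.0 + 0.6 * stai_base + rng_out.normal(0, 4.0)), 20, 80)
        )
        rows.append(
            {
                "id": p.id,
                "arm": arm,
                "allocated": int(arm == "intervention"),
                "compliant": int(rec.compliant),
                "exposed": int(arm == "intervention" and rec.compliant),
                "ga": p.gestational_age_at_birth,
                "postnatal": p.postnatal_age,
                "sex": p.sex,
                "site": p.site,
                "reason": p.blood_test_reason,
                "true_magnitude": m,
                "nnrf": nnrf,
                "pipp": pipp,
                "tachycardia": tachy,
                "stai_base": stai_base,
                "stai_post": stai_post,
            }
        )
    frame = pd.DataFrame(rows)
    loss = config.missingness
    for outcome, col, rate in (
        ("nnrf", "nnrf", loss.nnrf),
        ("pipp", "pipp", loss.pipp),
        ("tachycardia", "tachycardia", loss.tachycardia),
        ("stai", "stai_post", loss.stai),
    ):
        if rate > 0:
            lost = rng_missing.random(len(frame)) < rate
            frame.loc[lost, col] = np.nan
    return frame
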