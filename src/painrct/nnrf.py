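"""Template-regression quantification of noxious-evoked brain activity.

The primary outcome of the trial is the magnitude of a fixed-shape
response waveform fitted to single-trial EEG: the waveform (a surrogate
for the validated noxious neurodynamic response function) is regressed
onto the Cz channel in a post-stimulus analysis window, and the
least-squares coefficient is the magnitude. With baseline-corrected data
and no intercept the coefficient is the inner-product ratio

    beta = <template, signal> / <template, template>

evaluated at the (optionally) cross-correlation-aligned latency shift.
A magnitude of 1 is calibrated to represent the expected response of a
term-aged neonate to a heel lance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from painrct.epochs import EEGEpoch
from painrct.errors import ConfigError, FlaggedInputError, InvalidArgumentError

__all__ = [
    "TemplateParams",
    "Template",
    "MagnitudeResult",
    "FilterConfig",
    "ArtefactThresholds",
    "AlignConfig",
    "build_template",
    "preprocess",
    "preprocess_template",
    "reject_artefact",
    "nnrf_magnitude",
]

ANALYSIS_CHANNEL = "Cz"


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of the surrogate biphasic response waveform.

    The waveform is a difference of two Gaussians — a negative deflection
    followed by a larger positive one — truncated to the analysis window
    and scaled so its largest absolute amplitude equals
    ``peak_amplitude_uv``.
    """

    sampling_rate: float = 256.0
    analysis_window: tuple[float, float] = (0.4, 0.7)
    neg_center_s: float = 0.450
    neg_sd_s: float = 0.040
    pos_center_s: float = 0.560
    pos_sd_s: float = 0.060
    amplitude_ratio: float = 1.25  # positive : negative
    peak_amplitude_uv: float = 20.0
    max_out_of_window_energy: float = 0.02


@dataclass(frozen=True)
class Template:
    """Calibrated response template on a post-stimulus sample grid."""

    waveform: np.ndarray          # microvolts, samples inside analysis_window
    times: np.ndarray             # seconds post-stimulus, same length
    sampling_rate: float
    analysis_window: tuple[float, float] = (0.4, 0.7)
    calibration_constant: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveform", np.asarray(self.waveform, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.waveform.shape != self.times.shape:
            raise ConfigError("waveform and times must have equal length")
        if self.calibration_constant <= 0:
            raise ConfigError("calibration_constant must be positive")
        lo, hi = self.analysis_window
        if self.times.min() < lo - 1e-9 or self.times.max() > hi + 1e-9:
            raise ConfigError("template support must lie within the analysis window")

    @property
    def energy(self) -> float:
        return float(np.dot(self.waveform, self.waveform))

    def sampled_at(self, times: np.ndarray) -> np.ndarray:
        """Waveform interpolated onto arbitrary sample times (0 outside support)."""
        return np.interp(times, self.times, self.waveform, left=0.0, right=0.0)

    def as_epoch(
        self,
        epoch_window: tuple[float, float] = (-0.5, 1.0),
        sampling_rate: float | None = None,
        event_kind: str = "lance",
    ) -> EEGEpoch:
        """Embed the template (magnitude 1, Cz only) in an otherwise-zero epoch."""
        from painrct.epochs import CHANNELS

        fs = sampling_rate or self.sampling_rate
        n = int(round((epoch_window[1] - epoch_window[0]) * fs))
        stim = int(round(-epoch_window[0] * fs))
        t = (np.arange(n) - stim) / fs
        data = np.zeros((len(CHANNELS), n))
        data[CHANNELS.index(ANALYSIS_CHANNEL)] = self.sampled_at(t)
        return EEGEpoch(
            sampling_rate=fs,
            channels=CHANNELS,
            data=data,
            epoch_window=epoch_window,
            stimulus_index=stim,
            event_kind=event_kind,
        )


@dataclass(frozen=True)
class MagnitudeResult:
    """Outcome of one template regression."""

    magnitude: float
    alignment_shift_ms: float
    goodness_of_fit: float
    artefact_flag: bool = False


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase band-pass plus pre-stimulus baseline correction."""

    band_hz: tuple[float, float] = (0.5, 30.0)
    order: int = 4
    baseline_window: tuple[float, float] = (-0.5, 0.0)


@dataclass(frozen=True)
class ArtefactThresholds:
    peak_to_peak_uv: float = 200.0
    flat_rms_uv: float = 0.1
    channel: str = ANALYSIS_CHANNEL


@dataclass(frozen=True)
class AlignConfig:
    """Latency-alignment search: maximal signed cross-correlation within a bound."""

    max_shift_ms: float = 50.0  # 0 disables the search


def _raw_shape(params: TemplateParams, times: np.ndarray) -> np.ndarray:
    neg = -np.exp(-0.5 * ((times - params.neg_center_s) / params.neg_sd_s) ** 2)
    pos = params.amplitude_ratio * np.exp(
        -0.5 * ((times - params.pos_center_s) / params.pos_sd_s) ** 2
    )
    return neg + pos


def build_template(params: TemplateParams | None = None) -> Template:
    """Construct the calibrated surrogate template.

    The raw difference-of-Gaussians is evaluated on an extended grid to
    measure how much of its energy falls outside the analysis window
    (rejected above ``max_out_of_window_energy``), then truncated to the
    window and scaled to the calibrated peak amplitude.
    """
    params = params or TemplateParams()
    fs = params.sampling_rate
    lo, hi = params.analysis_window
    if hi <= lo:
        raise ConfigError(f"analysis window {params.analysis_window} is empty")

    pad = 4 * max(params.neg_sd_s, params.pos_sd_s)
    wide_t = np.arange(lo - pad, hi + pad, 1.0 / fs)
    wide = _raw_shape(params, wide_t)
    in_win = (wide_t >= lo - 1e-9) & (wide_t <= hi + 1e-9)
    total_energy = float(np.sum(wide**2))
    if total_energy == 0:
        raise ConfigError("template waveform is identically zero")
    frac_out = 1.0 - float(np.sum(wide[in_win] ** 2)) / total_energy
    if frac_out > params.max_out_of_window_energy:
        raise ConfigError(
            f"{frac_out:.1%} of waveform energy lies outside the analysis window "
            f"(limit {params.max_out_of_window_energy:.1%})"
        )

    # place on the post-stimulus sample grid: samples k/fs inside the window
    k = np.arange(int(np.ceil(lo * fs - 1e-9)), int(np.floor(hi * fs + 1e-9)) + 1)
    times = k / fs
    raw = _raw_shape(params, times)
    peak = float(np.max(np.abs(raw)))
    scale = params.peak_amplitude_uv / peak
    return Template(
        waveform=raw * scale,
        times=times,
        sampling_rate=fs,
        analysis_window=params.analysis_window,
        calibration_constant=scale,
    )


def preprocess(epoch: EEGEpoch, filt: FilterConfig | None = None) -> EEGEpoch:
    """Zero-phase band-pass filter and baseline-correct an epoch.

    Returns a new epoch; the baseline window mean is zero per channel
    afterwards (within numerical tolerance).
    """
    filt = filt or FilterConfig()
    lo, hi = filt.band_hz
    if epoch.sampling_rate < 2.0 * hi:
        raise InvalidArgumentError(
            f"sampling rate {epoch.sampling_rate} Hz below 2x upper band edge {hi} Hz"
        )
    sos = sps.butter(filt.order, filt.band_hz, btype="bandpass", fs=epoch.sampling_rate, output="sos")
    # the high-pass transient outlasts a short epoch; reflect-pad by a few
    # low-edge cycles so the zero-phase filter settles before the data start
    pad = int(round(4.0 * epoch.sampling_rate / lo))
    ext = np.pad(epoch.data, ((0, 0), (pad, pad)), mode="reflect")
    data = sps.sosfiltfilt(sos, ext, axis=1)[:, pad:-pad]
    sl = epoch.window_slice(filt.baseline_window)
    data = data - data[:, sl].mean(axis=1, keepdims=True)
    out = epoch.copy()
    out.data = data
    return out


def preprocess_template(template: Template, filt: FilterConfig | None = None) -> Template:
    """Pass the template through the same filter applied to the data.

    Scoring filtered epochs against the identically filtered template
    removes the (small) attenuation bias the band-pass would otherwise
    introduce — the standard matched-regressor construction.
    """
    filt = filt or FilterConfig()
    ep = preprocess(template.as_epoch(), filt)
    sl = ep.window_slice(template.analysis_window)
    times = ep.times[sl]
    return replace(template, waveform=ep.channel(ANALYSIS_CHANNEL)[sl], times=times)


def reject_artefact(epoch: EEGEpoch, thresholds: ArtefactThresholds | None = None) -> bool:
    """Rule-based artefact flag: excessive peak-to-peak swing or a flat line."""
    thresholds = thresholds or ArtefactThresholds()
    x = epoch.channel(thresholds.channel)
    ptp = float(np.max(x) - np.min(x))
    rms = float(np.sqrt(np.mean(x**2)))
    return ptp > thresholds.peak_to_peak_uv or rms < thresholds.flat_rms_uv


def nnrf_magnitude(
    epoch: EEGEpoch,
    template: Template,
    align: AlignConfig | None = None,
    check_artefact: bool = True,
    artefact_thresholds: ArtefactThresholds | None = None,
) -> MagnitudeResult:
    """Score one epoch: the template-regression magnitude on Cz.

    The template is regressed (no intercept — the baseline is already
    removed) onto the Cz samples inside the analysis window, optionally
    after a bounded latency-alignment search that maximises the signed
    cross-correlation between template and signal.

    Raises
    ------
    FlaggedInputError
        If the epoch fails artefact screening and ``check_artefact`` is on.
    InvalidArgumentError
        If the analysis window (plus maximal shift) is not covered.
    """
    align = align or AlignConfig()
    if check_artefact and reject_artefact(epoch, artefact_thresholds):
        raise FlaggedInputError(
            "epoch is artefact-flagged; pass check_artefact=False to override"
        )

    x = epoch.channel(ANALYSIS_CHANNEL)
    sl = epoch.window_slice(template.analysis_window)
    t = template.sampled_at(epoch.times[sl])
    energy = float(np.dot(t, t))
    if energy == 0:
        raise InvalidArgumentError("template has zero energy on the epoch grid")

    max_shift = int(round(align.max_shift_ms / 1000.0 * epoch.sampling_rate))
    best_shift, best_corr = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        a, b = sl.start + s, sl.stop + s
        if a < 0 or b > epoch.n_samples:
            continue
        c = float(np.dot(t, x[a:b]))
        if c > best_corr:
            best_corr, best_shift = c, s

    seg = x[sl.start + best_shift : sl.stop + best_shift]
    beta = float(np.dot(t, seg)) / energy
    ss_tot = float(np.dot(seg, seg))
    gof = 0.0 if ss_tot == 0 else 1.0 - float(np.sum((seg - beta * t) ** 2)) / ss_tot
    return MagnitudeResult(
        magnitude=beta,
        alignment_shift_ms=best_shift / epoch.sampling_rate * 1000.0,
        goodness_of_fit=float(np.clip(gof, 0.0, 1.0)),
        artefact_flag=False,
    )
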