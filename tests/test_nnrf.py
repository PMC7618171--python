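"""Template construction, preprocessing, artefact rules and magnitude scoring."""

import numpy as np
import pytest

from painrct.epochs import CHANNELS, EEGEpoch
from painrct.errors import ConfigError, FlaggedInputError, InvalidArgumentError
from painrct.nnrf import (
    AlignConfig,
    ArtefactThresholds,
    FilterConfig,
    Template,
    TemplateParams,
    build_template,
    nnrf_magnitude,
    preprocess,
    preprocess_template,
    reject_artefact,
)
from painrct.synthetic import simulate_epoch
from painrct.config import EEGSimConfig

NO_ALIGN = AlignConfig(max_shift_ms=0.0)


def _epoch_from_cz(cz, fs=256.0, window=(-0.5, 1.0)):
    n = len(cz)
    data = np.zeros((len(CHANNELS), n))
    data[CHANNELS.index("Cz")] = cz
    return EEGEpoch(sampling_rate=fs, channels=CHANNELS, data=data, epoch_window=window)


class TestTemplate:
    def test_peak_lies_inside_analysis_window(self, template):
        i = np.argmax(np.abs(template.waveform))
        assert 0.4 <= template.times[i] <= 0.7

    def test_self_projection_is_unity(self, template):
        res = nnrf_magnitude(template.as_epoch(), template, NO_ALIGN, check_artefact=False)
        assert res.magnitude == pytest.approx(1.0, abs=1e-12)
        assert res.goodness_of_fit == pytest.approx(1.0, abs=1e-12)

    def test_rescaled_template_recalibrates_to_identical_scores(self, template, rng):
        halved = Template(
            waveform=template.waveform * 0.5,
            times=template.times,
            sampling_rate=template.sampling_rate,
            analysis_window=template.analysis_window,
            calibration_constant=template.calibration_constant * 0.5,
        )
        recalibrated = Template(
            waveform=halved.waveform * 2.0,
            times=halved.times,
            sampling_rate=halved.sampling_rate,
            analysis_window=halved.analysis_window,
            calibration_constant=halved.calibration_constant * 2.0,
        )
        for _ in range(5):
            ep = _epoch_from_cz(rng.normal(0, 5, 384))
            a = nnrf_magnitude(ep, template, NO_ALIGN, check_artefact=False).magnitude
            b = nnrf_magnitude(ep, recalibrated, NO_ALIGN, check_artefact=False).magnitude
            c = nnrf_magnitude(ep, halved, NO_ALIGN, check_artefact=False).magnitude
            assert b == pytest.approx(a, rel=1e-12)
            assert c == pytest.approx(2 * a, rel=1e-12)

    def test_waveform_energy_escaping_window_is_rejected(self):
        with pytest.raises(ConfigError):
            build_template(TemplateParams(analysis_window=(0.43, 0.6)))


class TestPreprocess:
    def test_constant_offset_removed(self):
        ep = _epoch_from_cz(np.full(384, 25.0))
        out = preprocess(ep)
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_baseline_window_mean_is_zero(self, rng):
        ep = _epoch_from_cz(rng.normal(0, 5, 384))
        out = preprocess(ep)
        sl = out.window_slice((-0.5, 0.0))
        assert abs(out.channel("Cz")[sl].mean()) < 1e-9

    def test_mains_frequency_attenuated_below_5pct(self):
        t = (np.arange(384) - 128) / 256.0
        cz = 20.0 * np.sin(2 * np.pi * 50.0 * t)
        out = preprocess(_epoch_from_cz(cz))
        ratio = np.sqrt(np.mean(out.channel("Cz") ** 2)) / np.sqrt(np.mean(cz**2))
        assert ratio < 0.05

    def test_idempotent_within_tolerance(self, rng):
        ep = _epoch_from_cz(rng.normal(0, 5, 384))
        once = preprocess(ep)
        twice = preprocess(once)
        rms = np.sqrt(np.mean((once.channel("Cz") - twice.channel("Cz")) ** 2))
        assert rms < 1.0

    def test_low_sampling_rate_rejected(self):
        ep = _epoch_from_cz(np.zeros(60), fs=40.0)
        with pytest.raises(InvalidArgumentError):
            preprocess(ep, FilterConfig(band_hz=(0.5, 30.0)))


class TestArtefactRejection:
    def test_flat_line_flagged(self):
        assert reject_artefact(_epoch_from_cz(np.zeros(384)))

    def test_large_spike_flagged(self, rng):
        cz = rng.normal(0, 5, 384)
        cz[200] += 500.0
        assert reject_artefact(_epoch_from_cz(cz))

    def test_typical_synthetic_epoch_passes(self, template):
        ep = simulate_epoch(None, 1.0, EEGSimConfig(), seed=3, template=template)
        assert not reject_artefact(ep)


class TestMagnitude:
    def test_zero_epoch_scores_zero(self, template):
        res = nnrf_magnitude(_epoch_from_cz(np.zeros(384)), template, NO_ALIGN, check_artefact=False)
        assert res.magnitude == 0.0

    def test_flagged_epoch_refused(self, template):
        with pytest.raises(FlaggedInputError):
            nnrf_magnitude(_epoch_from_cz(np.zeros(384)), template, NO_ALIGN)

    def test_window_outside_epoch_rejected(self, template):
        ep = _epoch_from_cz(np.ones(128), window=(-0.25, 0.25))
        with pytest.raises(InvalidArgumentError):
            nnrf_magnitude(ep, template, NO_ALIGN, check_artefact=False)

    def test_orthogonal_noise_leaves_magnitude_exact(self, template, rng):
        """Noise orthogonalised against the template cannot move the score."""
        ep = template.as_epoch()
        sl = ep.window_slice(template.analysis_window)
        t = template.sampled_at(ep.times[sl])
        cz = 1.07 * ep.channel("Cz")
        noise = rng.normal(0, 5, ep.n_samples)
        w = noise[sl]
        noise[sl] = w - (np.dot(w, t) / np.dot(t, t)) * t
        out = ep.copy()
        out.data[CHANNELS.index("Cz")] = cz + noise
        res = nnrf_magnitude(out, template, NO_ALIGN, check_artefact=False)
        assert res.magnitude == pytest.approx(1.07, abs=1e-9)

    def test_shift_recovery_within_2pct(self, template):
        shift_s = 0.03
        ep = template.as_epoch()
        t_shifted = template.sampled_at(ep.times - shift_s)
        out = ep.copy()
        out.data[CHANNELS.index("Cz")] = t_shifted
        res = nnrf_magnitude(out, template, AlignConfig(max_shift_ms=50.0), check_artefact=False)
        assert res.magnitude == pytest.approx(1.0, rel=0.02)
        assert res.alignment_shift_ms == pytest.approx(30.0, abs=4.0)

    def test_linearity_of_projection(self, template, rng):
        for _ in range(10):
            x = _epoch_from_cz(rng.normal(0, 5, 384))
            y = _epoch_from_cz(rng.normal(0, 5, 384))
            a, b = rng.normal(), rng.normal()
            combo = _epoch_from_cz(a * x.channel("Cz") + b * y.channel("Cz"))
            sx = nnrf_magnitude(x, template, NO_ALIGN, check_artefact=False).magnitude
            sy = nnrf_magnitude(y, template, NO_ALIGN, check_artefact=False).magnitude
            sc = nnrf_magnitude(combo, template, NO_ALIGN, check_artefact=False).magnitude
            assert sc == pytest.approx(a * sx + b * sy, rel=1e-10, abs=1e-10)

    def test_matches_inner_product_oracle(self, template, rng):
        """Regression coefficient equals the brute-force <t,x>/<t,t> ratio."""
        for _ in range(100):
            ep = _epoch_from_cz(rng.normal(0, 5, 384))
            sl = ep.window_slice(template.analysis_window)
            t = template.sampled_at(ep.times[sl])
            oracle = np.dot(t, ep.channel("Cz")[sl]) / np.dot(t, t)
            res = nnrf_magnitude(ep, template, NO_ALIGN, check_artefact=False)
            assert res.magnitude == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    def test_filtered_template_scoring_recovers_inserted_magnitude(self, template):
        """Matched-regressor scoring through the preprocessing chain."""
        ft = preprocess_template(template)
        cfg = EEGSimConfig(noise_rms_uv=0.0, latency_jitter_sd_ms=0.0)
        ep = preprocess(simulate_epoch(None, 1.07, cfg, seed=0, template=template))
        res = nnrf_magnitude(ep, ft, NO_ALIGN, check_artefact=False)
        assert res.magnitude == pytest.approx(1.07, rel=1e-3)
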