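import numpy as np
import pytest

from synergy_state.io_core import EMGRecording, PipelineConfig
from synergy_state.preprocess import (
    PreprocessError, detect_artifacts, downsample, filter_chain,
    preprocess_pipeline, replace_artifacts, variance_normalize,
)
from synergy_state.synthetic import SimConfig, generate_dataset

TDT_FS = 24414.0625      # acquisition rate (25 MHz / 1024)


def _rec(sig, fs=1000.0, muscles=None):
    sig = np.atleast_2d(sig)
    muscles = muscles or tuple(f"m{i}" for i in range(sig.shape[0]))
    return EMGRecording(sig, fs, muscles)


class TestDownsample:
    def test_constant_stays_constant(self):
        rec = _rec(np.full((2, 50000), 3.7), fs=TDT_FS)
        out = downsample(rec, 1000.0)
        assert out.fs == 1000.0
        # interior samples; FIR edge transients excluded
        assert np.allclose(out.signal[:, 30:-30], 3.7, rtol=1e-3)

    def test_output_length_from_acquisition_rate(self):
        n = 244140
        rec = _rec(np.zeros((1, n)), fs=TDT_FS)
        out = downsample(rec, 1000.0)
        assert abs(out.n_samples - round(n * 1000.0 / TDT_FS)) <= 1

    def test_low_frequency_sinusoid_amplitude_preserved(self):
        t = np.arange(int(TDT_FS * 2)) / TDT_FS
        rec = _rec(np.sin(2 * np.pi * 10 * t), fs=TDT_FS)
        out = downsample(rec, 1000.0)
        mid = out.signal[0, 200:-200]
        assert abs(mid.max() - 1.0) < 0.02
        t_out = np.arange(out.n_samples) / 1000.0
        ref = np.sin(2 * np.pi * 10 * t_out)[200:-200]
        assert np.corrcoef(mid, ref)[0, 1] > 0.999

    def test_invalid_target_rejected(self):
        rec = _rec(np.zeros((1, 1000)), fs=1000.0)
        with pytest.raises(PreprocessError):
            downsample(rec, 0.0)
        with pytest.raises(PreprocessError):
            downsample(rec, 2000.0)


class TestFilterChain:
    def test_dc_input_is_removed(self):
        rec = _rec(np.full((1, 5000), 5.0))
        out = filter_chain(rec)
        assert np.all(np.abs(out.signal[0, 200:-200]) < 5.0 * 1e-6)

    def test_burst_envelope_tracks_analytic_envelope(self):
        fs = 1000.0
        t = np.arange(int(fs * 6)) / fs
        env = np.exp(-0.5 * ((t - 3.0) / 0.5) ** 2)      # slow Gaussian burst
        carrier = np.sin(2 * np.pi * 100 * t)
        rec = _rec(env * carrier, fs=fs)
        out = filter_chain(rec)
        sl = slice(500, -500)
        r = np.corrcoef(out.signal[0, sl], env[sl])[0, 1]
        assert r > 0.95
        assert np.all(out.signal >= 0)

    def test_white_noise_yields_finite_non_negative_envelope(self):
        rng = np.random.default_rng(0)
        out = filter_chain(_rec(rng.normal(size=(2, 4000))))
        assert np.all(np.isfinite(out.signal))
        assert np.all(out.signal >= 0)

    def test_short_signal_rejected(self):
        with pytest.raises(PreprocessError, match="filter length"):
            filter_chain(_rec(np.zeros((1, 100))))


class TestArtifacts:
    def test_empty_mask_is_identity(self, toy_recording):
        out, report = replace_artifacts(
            toy_recording, np.zeros_like(toy_recording.signal, dtype=bool)
        )
        assert np.array_equal(out.signal, toy_recording.signal)
        assert all(v == 0
                   for v in report.n_artifact_samples_replaced.values())

    def test_replacement_uses_percentile_of_unmasked_samples(self):
        # independent oracle: linear-interpolation percentile of 0..999
        # excluding the masked sample
        values = np.arange(1000, dtype=float)
        mask = np.zeros((1, 1000), dtype=bool)
        mask[0, 500] = True
        # 999 values after deletion; rank (999-1)*0.999 = 997.002 falls
        # between sorted values 998 and 999 -> 998 + 0.002
        unmasked = np.delete(values, 500)
        expected = np.percentile(unmasked, 99.9)
        assert expected == pytest.approx(998.002, abs=1e-6)
        out, report = replace_artifacts(_rec(values), mask)
        assert out.signal[0, 500] == pytest.approx(expected)
        assert report.replacement_value["m0"] == pytest.approx(expected)

    def test_mask_covering_most_of_channel_rejected(self, toy_recording):
        mask = np.ones_like(toy_recording.signal, dtype=bool)
        with pytest.raises(PreprocessError, match="50%"):
            replace_artifacts(toy_recording, mask)

    def test_injected_artifacts_are_detected(self, tmp_path):
        cfg = SimConfig(n_loci=5, trials_per_locus=4, conditions=("SST",),
                        artifact_rate=0.001)
        gt = generate_dataset(cfg, 21, tmp_path / "d")
        from synergy_state.io_core import read_dataset
        rec, _, _, _ = read_dataset(tmp_path / "d")
        clean = generate_dataset(cfg.replace(artifact_rate=0.0), 21,
                                 tmp_path / "clean")
        rec_clean, _, _, _ = read_dataset(tmp_path / "clean")
        injected = ~np.isclose(rec.signal, rec_clean.signal)
        mask = detect_artifacts(rec, sd_thresh=8.0)
        hit = mask[injected].mean()
        assert hit >= 0.95


class TestVarianceNormalize:
    def test_divides_by_channel_sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, size=(1, 10000))
        out = variance_normalize(_rec(np.abs(x)))
        assert out.signal[0].var() == pytest.approx(1.0, abs=1e-6)
        ratio = out.signal[0] / np.abs(x)[0]
        assert np.allclose(ratio, ratio[0])

    def test_unequal_channels_end_equal(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(1, 1, size=(2, 8000)))
        x[1] *= 10
        out = variance_normalize(_rec(x))
        assert np.allclose(out.signal.var(axis=1), 1.0, atol=1e-6)

    def test_zero_variance_channel_named_in_error(self):
        sig = np.vstack([np.ones(1000), np.random.default_rng(0).random(1000)])
        with pytest.raises(PreprocessError, match="TA"):
            variance_normalize(_rec(sig, muscles=("TA", "VL")))

    def test_chain_idempotent_after_normalization(self, toy_recording):
        once = variance_normalize(toy_recording)
        twice = variance_normalize(once)
        assert np.allclose(once.signal, twice.signal, atol=1e-6)


class TestPipeline:
    def test_envelope_mode_preserves_percentage_increments(self, small_bundle):
        """Envelope-domain conditioning (artifact replacement + variance
        normalization) leaves SpTA percentage increments essentially
        unchanged, because percentage increments are channel-scale
        invariant."""
        from synergy_state.io_core import read_dataset
        from synergy_state.spta import analyze_unit
        path, gt = small_bundle
        rec, spikes, trials, _ = read_dataset(path)
        cfg = PipelineConfig()
        proc, report = preprocess_pipeline(rec, cfg)
        assert np.allclose(
            [report.post_variance[m] for m in proc.muscles], 1.0, atol=1e-6
        )
        _, fld_raw = analyze_unit(spikes[0], rec, "SST", cfg)
        _, fld_proc = analyze_unit(spikes[0], proc, "SST", cfg)
        denom = np.maximum(fld_raw.values, 1.0)
        assert np.all(np.abs(fld_proc.values - fld_raw.values) / denom < 0.10)
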