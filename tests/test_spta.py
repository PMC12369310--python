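import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synergy_state.io_core import EMGRecording, PipelineConfig, SpikeTrain
from synergy_state.spta import (
    MuscleField, SpTAError, SpTAProfile, analyze_unit, build_muscle_field,
    classify_effect, compute_features, compute_increment, compute_spta,
    spta_significance,
)
from synergy_state.synthetic import (
    SimConfig, make_ground_truth, make_trials, raised_cosine_kernel,
    simulate_emg, simulate_spikes,
)


def brute_force_spta(signal, fs, spike_times, window_ms=(-30.0, 50.0)):
    """Independent oracle: explicit per-spike segment-and-average loop."""
    step = 1000.0 / fs
    offs = range(int(round(window_ms[0] / step)),
                 int(round(window_ms[1] / step)) + 1)
    segs = []
    for t in spike_times:
        i = int(np.floor(t * fs))
        if i + min(offs) >= 0 and i + max(offs) < signal.size:
            segs.append([signal[i + o] for o in offs])
    return np.mean(segs, axis=0)


def _profile(trace, bm, bsd, unit="u", muscle="TA"):
    return SpTAProfile(unit_id=unit, muscle=muscle,
                       trace=np.asarray(trace, dtype=float),
                       n_spikes=100, n_dropped=0,
                       baseline_mean=bm, baseline_sd=bsd)


class TestComputeSpTA:
    @pytest.mark.parametrize("case", range(20))
    def test_matches_explicit_loop_oracle(self, case):
        rng = np.random.default_rng(case)
        n = 4000
        sig = np.abs(rng.normal(1.0, 0.5, size=(2, n)))
        times = np.sort(rng.uniform(0.0, n / 1000.0, size=60))
        times = times[np.diff(times, prepend=-1) > 1e-4]
        st_ = SpikeTrain("u1", times)
        rec = EMGRecording(sig, 1000.0, ("TA", "VL"))
        profiles = compute_spta(st_, rec)
        for j, p in enumerate(profiles):
            oracle = brute_force_spta(sig[j], 1000.0, times)
            assert np.max(np.abs(p.trace - oracle)) < 1e-12

    def test_window_has_81_samples_and_constant_emg_gives_zero_increment(self):
        rec = EMGRecording(np.full((1, 3000), 2.5), 1000.0, ("TA",))
        st_ = SpikeTrain("u1", np.linspace(0.2, 2.8, 40))
        p = compute_spta(st_, rec)[0]
        assert p.trace.size == 81
        assert np.allclose(p.trace, 2.5)
        assert compute_increment(p) == 0.0
        assert not p.significant

    def test_too_few_usable_spikes_rejected(self):
        rec = EMGRecording(np.ones((1, 3000)), 1000.0, ("TA",))
        with pytest.raises(SpTAError, match="insufficient triggers"):
            compute_spta(SpikeTrain("u1", np.linspace(0.2, 2.8, 10)), rec)

    def test_boundary_spikes_are_dropped_and_counted(self):
        rec = EMGRecording(np.ones((1, 2000)), 1000.0, ("TA",))
        times = np.concatenate([[0.01], np.linspace(0.2, 1.8, 40), [1.99]])
        p = compute_spta(SpikeTrain("u1", times), rec)[0]
        assert p.n_dropped == 2
        assert p.n_spikes == 40

    def test_recovers_kernel_peak_latency(self):
        cfg = SimConfig(n_loci=8, trials_per_locus=5, conditions=("SST",),
                        n_units=1)
        gt = make_ground_truth(cfg, 7)
        trials = make_trials(cfg, 7)
        spikes = simulate_spikes(gt, trials, cfg, 7)
        rec = simulate_emg(gt, spikes, trials, cfg, 7)
        profiles, fld = analyze_unit(spikes[0], rec, "SST")
        dominant = int(np.argmax(fld.values))
        assert abs(profiles[dominant].peak_latency_ms - 8.0) <= 1.0


class TestIncrement:
    def test_region_growing_matches_hand_computed_value(self):
        # baseline 1.0, SD 0.1 -> threshold 1.2; supra-threshold region
        # {1.5, 2.0, 1.5} -> increment = 100*(5/3 - 1) = 66.67%
        trace = np.ones(81)
        trace[40:43] = [1.5, 2.0, 1.5]
        p = _profile(trace, bm=1.0, bsd=0.1)
        assert compute_increment(p) == pytest.approx(200.0 / 3.0, abs=1e-9)
        assert p.significant

    def test_non_positive_baseline_rejected(self):
        p = _profile(np.ones(81), bm=0.0, bsd=0.1)
        with pytest.raises(SpTAError, match="baseline"):
            compute_increment(p)

    def test_peak_tie_broken_to_earlier_latency(self):
        trace = np.ones(81)
        trace[35] = trace[40] = 2.0
        p = _profile(trace, bm=1.0, bsd=0.1)
        compute_increment(p)
        assert p.peak_latency_ms == pytest.approx(5.0)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_percentage_increment_invariant_to_channel_rescaling(self, scale):
        trace = np.ones(81)
        trace[38:44] = [1.3, 1.6, 2.1, 1.9, 1.4, 1.25]
        p1 = _profile(trace, bm=1.0, bsd=0.1)
        p2 = _profile(trace * scale, bm=scale, bsd=0.1 * scale)
        assert compute_increment(p1) == pytest.approx(
            compute_increment(p2), rel=1e-9
        )


class TestFeatures:
    def test_triangular_bump_pwhm_from_geometry(self):
        # linear flanks from 2 ms (value 1) to peak 8 ms (value 3) and back;
        # half max at 2 -> crossings at 5 and 11 ms -> PWHM 6
        trace = np.ones(81)
        t = np.arange(81) - 30.0
        up = (t >= 2) & (t <= 8)
        down = (t > 8) & (t <= 14)
        trace[up] = 1 + 2 * (t[up] - 2) / 6
        trace[down] = 3 - 2 * (t[down] - 8) / 6
        p = _profile(trace, bm=1.0, bsd=0.01)
        onset, pwhm = compute_features(p)
        assert pwhm == pytest.approx(6.0, abs=1e-9)
        assert onset > 2.0

    def test_onset_may_search_before_the_trigger(self):
        trace = np.ones(81)
        trace[20:45] = 2.0        # supra-threshold from -10 ms onward
        p = _profile(trace, bm=1.0, bsd=0.1)
        onset, _ = compute_features(p)
        assert onset == pytest.approx(-10.0)

    def test_nonsignificant_profile_has_undefined_features(self):
        p = _profile(np.ones(81), bm=1.0, bsd=0.1)
        assert compute_features(p) == (None, None)

    def test_measured_pwhm_close_to_kernel_width(self):
        kern, off = raised_cosine_kernel(8.0, 10.0, 1000.0, amplitude=2.0)
        trace = np.ones(81)
        i0 = 30 + off
        trace[i0:i0 + kern.size] += kern
        p = _profile(trace, bm=1.0, bsd=0.05)
        _, pwhm = compute_features(p)
        assert abs(pwhm - 10.0) <= 1.5


class TestClassification:
    @pytest.mark.parametrize("onset,pwhm,expected", [
        (6.0, 5.0, "pure"),
        (-0.4, 19.6, "synchrony"),     # study-population means
        (3.5, 7.0, "synchrony"),       # boundary is strict
        (3.6, 6.9, "pure"),
        (10.0, 7.0, "synchrony"),
        (3.5, 5.0, "synchrony"),
    ])
    def test_pure_requires_late_onset_and_narrow_peak(self, onset, pwhm,
                                                      expected):
        assert classify_effect(onset, pwhm) == expected

    def test_decision_is_monotone_in_each_feature(self):
        # moving onset later or pwhm narrower never flips pure -> synchrony
        for onset in np.linspace(3.6, 20, 8):
            for pwhm in np.linspace(0.5, 6.9, 8):
                assert classify_effect(onset, pwhm) == "pure"


class TestMuscleField:
    def test_normalized_field_from_increments(self):
        profiles = []
        for m, inc in zip(("TA", "VL", "VM", "BF", "GM", "GC"),
                          (10.0, 0.0, 5.0, 0.0, 0.0, 0.0)):
            p = _profile(np.ones(81), 1.0, 0.1, muscle=m)
            p.increment_pct = inc
            profiles.append(p)
        fld = build_muscle_field(profiles)
        assert fld.valid
        assert fld.values_norm == pytest.approx(
            [0.894427, 0.0, 0.447214, 0.0, 0.0, 0.0], abs=1e-6
        )

    def test_all_zero_field_is_flagged(self):
        profiles = [_profile(np.ones(81), 1.0, 0.1, muscle=m)
                    for m in ("TA", "VL")]
        for p in profiles:
            p.increment_pct = 0.0
        assert not build_muscle_field(profiles).valid

    def test_suppression_clamped_to_zero(self):
        p = _profile(np.ones(81), 1.0, 0.1)
        p.increment_pct = -12.0
        assert build_muscle_field([p]).values[0] == 0.0


class TestSignificance:
    def test_zero_shuffles_rejected(self, toy_recording):
        st_ = SpikeTrain("u1", np.linspace(0.2, 4.5, 50))
        with pytest.raises(SpTAError, match="n_shuffles"):
            spta_significance(st_, toy_recording, "TA", n_shuffles=0)

    def test_strong_kernel_detected(self):
        cfg = SimConfig(n_loci=6, trials_per_locus=5, conditions=("SST",),
                        n_units=1)
        gt = make_ground_truth(cfg, 13)
        trials = make_trials(cfg, 13)
        spikes = simulate_spikes(gt, trials, cfg, 13)
        rec = simulate_emg(gt, spikes, trials, cfg, 13)
        dominant = int(np.argmax(gt.fields_true["u1"]["SST"]))
        assert spta_significance(spikes[0], rec, rec.muscles[dominant],
                                 n_shuffles=100, seed=13)
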