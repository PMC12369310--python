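import filecmp

import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.stats import pearsonr

from synergy_state.io_core import PipelineConfig
from synergy_state.preprocess import preprocess_pipeline
from synergy_state.rate_correlation import firing_rate_by_locus
from synergy_state.spta import analyze_unit
from synergy_state.synthetic import (
    GroundTruth, SimConfig, generate_dataset, make_ground_truth, make_trials,
    raised_cosine_kernel, simulate_emg, simulate_spikes,
)


def _norm(v):
    return v / np.linalg.norm(v)


class TestGroundTruth:
    @pytest.mark.parametrize("seed", range(5))
    def test_planted_synergies_satisfy_invariants(self, seed):
        gt = make_ground_truth(SimConfig(n_units=4), seed)
        W = gt.W_true
        assert np.all(W >= 0)
        assert np.allclose(np.linalg.norm(W, axis=0), 1.0)
        # every muscle strongly represented in at least one synergy
        assert np.all(W.max(axis=1) > 0.25)

    @pytest.mark.parametrize("seed", range(8))
    def test_rewired_fields_match_their_labels(self, seed):
        gt = make_ground_truth(SimConfig(n_units=6), seed)
        for uid, byc in gt.modification_true.items():
            for cond in ("SSAT", "CoST"):
                label, coefs = byc[cond]
                f_sst = _norm(gt.fields_true[uid]["SST"])
                f = _norm(gt.fields_true[uid][cond])
                if label == "preserved":
                    assert f_sst @ f >= 0.8
                elif label == "merging":
                    # NNLS against the planted synergies recovers >= 2
                    # contributors above the 0.2 rule, incl. the SST synergy
                    c, _ = nnls(gt.W_true, f)
                    assert np.sum(c > 0.2) >= 2
                    assert c[gt.preferred_true[uid]] > 0.2
                else:
                    c, _ = nnls(gt.W_true, f)
                    recon = gt.W_true @ c
                    sp = 0.0 if np.linalg.norm(recon) == 0 \
                        else _norm(recon) @ f
                    assert sp < 0.6

    def test_single_synergy_forces_preserved(self):
        gt = make_ground_truth(SimConfig(n_true=1, n_units=4), 0)
        for byc in gt.modification_true.values():
            assert all(label == "preserved" for label, _ in byc.values())

    def test_ground_truth_json_round_trip(self, tmp_path):
        gt = make_ground_truth(SimConfig(), 3)
        gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert np.allclose(back.W_true, gt.W_true)
        assert back.modification_true.keys() == gt.modification_true.keys()


class TestSpikes:
    def test_homogeneous_rate_inside_and_outside_trains(self):
        cfg = SimConfig(base_rate_hz=40.0, stim_rate_hz=40.0, n_units=1,
                        n_loci=4, trials_per_locus=25, conditions=("SST",))
        gt = make_ground_truth(cfg, 0)
        gt.rate_profile["u1"][:] = 1.0
        trials = make_trials(cfg, 0)
        spikes = simulate_spikes(gt, trials, cfg, 0)[0]
        t_end = max(tr.stim_off for tr in trials) + 1.0
        in_stim = sum(
            np.count_nonzero((spikes.times >= tr.stim_on)
                             & (spikes.times < tr.stim_off))
            for tr in trials
        )
        dur_stim = sum(tr.stim_off - tr.stim_on for tr in trials)
        rate_in = in_stim / dur_stim
        rate_out = (spikes.n_spikes - in_stim) / (t_end - dur_stim)
        se = np.sqrt(rate_in / dur_stim + rate_out / (t_end - dur_stim))
        assert abs(rate_in - rate_out) < 3 * se

    def test_train_spike_count_matches_dead_time_poisson(self):
        # Poisson rate lam thinned by dead time tau has steady-state rate
        # lam / (1 + lam * tau)
        cfg = SimConfig(base_rate_hz=0.0, stim_rate_hz=100.0, n_units=1,
                        n_loci=1, trials_per_locus=500, conditions=("SST",))
        gt = make_ground_truth(cfg, 1)
        gt.rate_profile["u1"][:] = 1.0
        trials = make_trials(cfg, 1)
        spikes = simulate_spikes(gt, trials, cfg, 1)[0]
        lam, tau, T = 100.0, 1e-3, 0.2
        expected = lam / (1.0 + lam * tau) * T
        per_trial = spikes.n_spikes / len(trials)
        se = np.sqrt(expected / len(trials))
        assert abs(per_trial - expected) < 3 * se
        assert np.all(np.diff(spikes.times) >= tau - 1e-12)

    def test_locus_rate_curve_follows_gain_profile(self):
        cfg = SimConfig(n_loci=15, trials_per_locus=5, conditions=("SST",),
                        n_units=1, base_rate_hz=2.0, stim_rate_hz=100.0)
        gt = make_ground_truth(cfg, 2)
        trials = make_trials(cfg, 2)
        spikes = simulate_spikes(gt, trials, cfg, 2)[0]
        prof = firing_rate_by_locus(spikes, trials, "SST",
                                    PipelineConfig(response_margin_s=0.0))
        r = pearsonr(prof.rates, gt.rate_profile["u1"]).statistic
        assert r > 0.9


class TestEMG:
    def test_raised_cosine_pwhm_is_analytic(self):
        for pwhm in (5.0, 10.0):
            k, off = raised_cosine_kernel(8.0, pwhm, 10000.0)
            t_ms = (off + np.arange(k.size)) / 10.0
            above = t_ms[k >= 0.5 * k.max()]
            assert above[-1] - above[0] == pytest.approx(pwhm, abs=0.3)

    def test_emg_non_negative_and_kernel_free_spta_is_flat(self):
        cfg = SimConfig(n_loci=8, trials_per_locus=5, conditions=("SST",),
                        n_units=1, kernel_amplitude=0.0, base_rate_hz=40.0,
                        stim_rate_hz=40.0)
        gt = make_ground_truth(cfg, 4)
        trials = make_trials(cfg, 4)
        spikes = simulate_spikes(gt, trials, cfg, 4)
        rec = simulate_emg(gt, spikes, trials, cfg, 4)
        assert np.all(rec.signal >= 0)
        proc, _ = preprocess_pipeline(rec, PipelineConfig())
        profiles, _ = analyze_unit(spikes[0], proc, "SST")
        for p in profiles:
            se = p.baseline_sd
            assert abs((p.increment_pct or 0.0) / 100.0
                       * p.baseline_mean) < 4 * max(se, 1e-9) + 0.05

    def test_spta_increment_grows_with_kernel_amplitude(self):
        cfg0 = SimConfig(n_loci=8, trials_per_locus=5, conditions=("SST",),
                         n_units=1)
        gt = make_ground_truth(cfg0, 5)
        trials = make_trials(cfg0, 5)
        spikes = simulate_spikes(gt, trials, cfg0, 5)
        totals = []
        for amp in (0.5, 1.5, 3.0):
            rec = simulate_emg(gt, spikes, trials,
                               cfg0.replace(kernel_amplitude=amp), 5)
            proc, _ = preprocess_pipeline(rec, PipelineConfig())
            _, fld = analyze_unit(spikes[0], proc, "SST")
            totals.append(fld.values.sum())
        assert totals[0] < totals[1] < totals[2]


class TestDatasetGeneration:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = SimConfig(n_loci=3, trials_per_locus=2)
        generate_dataset(cfg, 9, tmp_path / "a")
        generate_dataset(cfg, 9, tmp_path / "b")
        for name in ("emg.h5", "spikes.tsv", "trials.tsv", "config.yaml",
                     "ground_truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_trial_table_follows_protocol(self, tmp_path):
        cfg = SimConfig(n_loci=13, trials_per_locus=5)
        gt = generate_dataset(cfg, 10, tmp_path / "d")
        import pandas as pd
        df = pd.read_csv(tmp_path / "d" / "trials.tsv", sep="\t")
        assert (df.condition == "SST").sum() == 65
        ssat = df[df.condition == "SSAT"]
        assert ssat.power_frac.between(1.2, 1.5).all()
        assert df[df.condition == "CoST"].locus2_um.notna().all()
        durs = df.stim_off_s - df.stim_on_s
        assert np.allclose(durs, 0.2)
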