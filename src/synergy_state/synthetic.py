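"""Synthetic spike/EMG co-simulation with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* EMG is a non-negative mixture of planted muscle synergies (columns of
  ``W_true``) driven by smooth per-trial activation envelopes whose
  amplitude varies across stimulation loci, plus tonic background and
  Gaussian noise (clamped at zero).  The signal lives in the
  post-rectification envelope domain at 1 kHz.
* Each simulated unit fires as an inhomogeneous Poisson process with a
  1 ms refractory period: a low background rate between trains, and a
  locus-modulated rate during the 200 ms optical pulse train.
* Every spike injects a raised-cosine kernel into the EMG, weighted by the
  unit's condition-dependent muscle field, so spike-triggered averaging can
  recover the field.
* Across conditions the unit's field is rewired: preserved (same synergy),
  merging (non-negative mixture of its synergy with another), or unmatched
  (a fresh coactivation pattern no synergy mixture explains), emulating the
  hypothesised recruitment of additional premotor interneurons at higher
  stimulation power and under co-stimulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .io_core import (
    CONDITIONS, DEFAULT_MUSCLES, EMGRecording, PipelineConfig, SpikeTrain,
    Trial, make_rng, write_dataset,
)


@dataclass
class SimConfig:
    """Simulation settings; defaults follow the study's stimulation protocol
    (5 ms pulses at 100 Hz over 200 ms trains, 1000 ms intertrial interval,
    5 trials per locus per condition, 13 loci, SSAT at 120-150% of threshold
    power) with noise/kernel levels chosen so that recovery is achievable
    but not trivial."""

    n_muscles: int = 6
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    n_true: int = 3                   # planted synergies (paper: 3 or 4)
    n_units: int = 2                  # 1-2 sorted units per animal
    n_loci: int = 13
    locus_step_um: float = 200.0
    trials_per_locus: int = 5
    conditions: tuple[str, ...] = CONDITIONS
    pulse_width_ms: float = 5.0
    pulse_rate_hz: float = 100.0
    train_ms: float = 200.0
    intertrial_ms: float = 1000.0
    ssat_power: tuple[float, float] = (1.2, 1.5)
    fs: float = 1000.0                # envelope-domain sampling rate
    base_rate_hz: float = 10.0
    stim_rate_hz: float = 80.0
    refractory_ms: float = 1.0
    envelope_amp: float = 1.0
    envelope_jitter: float = 0.3      # per-trial, per-synergy amplitude CV
    tonic_level: float = 0.5
    noise_sd: float = 0.1
    kernel_amplitude: float = 1.5
    kernel_latency_ms: float = 8.0    # peak latency, inside 3-16 ms window
    pwhm_pure_ms: float = 5.0
    pwhm_synchrony_ms: float = 10.0
    artifact_rate: float = 0.0        # fraction of samples; 0 disables
    artifact_sd_mult: float = 10.0
    # across-condition rewiring prevalences (merging, unmatched, preserved)
    probs_ssat: tuple[float, float, float] = (0.6, 0.15, 0.25)
    probs_cost: tuple[float, float, float] = (0.2, 0.6, 0.2)

    def __post_init__(self) -> None:
        if self.n_true > self.n_muscles:
            raise ValueError("n_true must not exceed n_muscles")
        for r in (self.base_rate_hz, self.stim_rate_hz):
            if r < 0:
                raise ValueError("rates must be non-negative")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @property
    def trial_period_s(self) -> float:
        return (self.train_ms + self.intertrial_ms) / 1000.0


@dataclass
class GroundTruth:
    """Planted quantities against which recovery is scored."""

    W_true: np.ndarray                      # [n_muscles, n_true], unit columns
    locus_amplitudes: np.ndarray            # [n_true, n_loci], in (0, 1]
    preferred_true: dict                    # unit_id -> synergy index
    fields_true: dict                       # unit_id -> {condition: vector}
    modification_true: dict                 # unit_id -> {condition: (label, coefs)}
    kernel_latency_ms: dict                 # unit_id -> peak latency
    kernel_pwhm_ms: dict                    # unit_id -> PWHM
    unit_type: dict                         # unit_id -> "pure" | "synchrony"
    rate_profile: dict                      # unit_id -> per-locus gain in (0, 1]

    def to_json(self, path: str | Path) -> None:
        d = {
            "W_true": self.W_true.tolist(),
            "locus_amplitudes": self.locus_amplitudes.tolist(),
            "preferred_true": {u: int(i) for u, i in self.preferred_true.items()},
            "fields_true": {
                u: {c: np.asarray(v).tolist() for c, v in byc.items()}
                for u, byc in self.fields_true.items()
            },
            "modification_true": {
                u: {c: [lab, np.asarray(co).tolist()]
                    for c, (lab, co) in byc.items()}
                for u, byc in self.modification_true.items()
            },
            "kernel_latency_ms": self.kernel_latency_ms,
            "kernel_pwhm_ms": self.kernel_pwhm_ms,
            "unit_type": self.unit_type,
            "rate_profile": {u: np.asarray(v).tolist()
                             for u, v in self.rate_profile.items()},
        }
        Path(path).write_text(json.dumps(d, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            W_true=np.asarray(d["W_true"]),
            locus_amplitudes=np.asarray(d["locus_amplitudes"]),
            preferred_true=d["preferred_true"],
            fields_true={u: {c: np.asarray(v) for c, v in byc.items()}
                         for u, byc in d["fields_true"].items()},
            modification_true={u: {c: (lab, np.asarray(co))
                                   for c, (lab, co) in byc.items()}
                               for u, byc in d["modification_true"].items()},
            kernel_latency_ms=d["kernel_latency_ms"],
            kernel_pwhm_ms=d["kernel_pwhm_ms"],
            unit_type=d["unit_type"],
            rate_profile={u: np.asarray(v)
                          for u, v in d["rate_profile"].items()},
        )


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _sample_synergy_column(rng, n_muscles, strong_idx) -> np.ndarray:
    """Synergy-like column with one dominant muscle, moderate weights on
    the other members of its muscle group and weak participation of the
    rest; unit L2 norm.  The dominant/secondary contrast leaves room in the
    positive orthant for coactivation patterns that no non-negative synergy
    mixture explains (needed for planting 'unmatched' fields)."""
    w = rng.uniform(0.0, 0.12, size=n_muscles)
    w[strong_idx[0]] = rng.uniform(0.8, 1.0)
    if len(strong_idx) > 1:
        w[strong_idx[1:]] = rng.uniform(0.3, 0.5, size=len(strong_idx) - 1)
    return _normalize(w)


def _nnls_reconstruction_sp(target: np.ndarray, W: np.ndarray) -> float:
    """Scalar product between target and its best non-negative mixture of
    the columns of W (both L2-normalized)."""
    coefs, _ = nnls(W, _normalize(target))
    recon = W @ coefs
    if np.linalg.norm(recon) == 0:
        return 0.0
    return float(_normalize(target) @ _normalize(recon))


def make_ground_truth(cfg: SimConfig, seed: int) -> GroundTruth:
    """Plant synergies, per-unit muscle fields and across-condition rewiring.

    Muscle-to-synergy assignment guarantees every muscle carries weight
    > 0.25 in at least one synergy, and rejection sampling keeps planted
    synergies mutually distinct (pairwise scalar product <= 0.6) so that
    matching and merging are identifiable.
    """
    rng = make_rng(seed, "ground_truth")
    m, N = cfg.n_muscles, cfg.n_true

    for _ in range(1000):
        # partition muscles across synergies so all are strongly represented
        perm = rng.permutation(m)
        groups = [list(perm[i::N]) for i in range(N)]
        W = np.column_stack(
            [_sample_synergy_column(rng, m, g) for g in groups]
        )
        gram = W.T @ W
        if np.all(gram[~np.eye(N, dtype=bool)] <= 0.6) and \
                np.all(W.max(axis=1) > 0.25):
            break
    else:
        raise RuntimeError("could not sample a valid synergy basis")

    # smooth unimodal per-locus amplitude profiles with distinct peaks;
    # sharp tuning keeps the synergies' activations distinguishable
    loci = np.arange(cfg.n_loci, dtype=float)
    centers = np.linspace(0.12, 0.88, N) * (cfg.n_loci - 1)
    sigma = max(cfg.n_loci / 6.0, 1.0)
    amps = 0.02 + 0.98 * np.exp(-0.5 * ((loci[None, :] - centers[:, None])
                                      / sigma) ** 2)

    labels = ("merging", "unmatched", "preserved")
    preferred, fields, mods = {}, {}, {}
    lat, pwhm, utype, rprof = {}, {}, {}, {}
    for u in range(cfg.n_units):
        uid = f"u{u + 1}"
        pref = u % N
        preferred[uid] = pref
        utype[uid] = "pure" if u % 2 == 0 else "synchrony"
        lat[uid] = cfg.kernel_latency_ms
        pwhm[uid] = (cfg.pwhm_pure_ms if utype[uid] == "pure"
                     else cfg.pwhm_synchrony_ms)
        rprof[uid] = amps[pref].copy()

        fields[uid] = {"SST": W[:, pref].copy()}
        mods[uid] = {"SST": ("preserved", np.eye(N)[pref])}
        for cond, probs in (("SSAT", cfg.probs_ssat),
                            ("CoST", cfg.probs_cost)):
            if cond not in cfg.conditions:
                continue
            if N == 1:
                label = "preserved"       # nothing to merge with or escape to
            else:
                label = labels[rng.choice(3, p=np.asarray(probs))]
            fields[uid][cond], mods[uid][cond] = _rewire_field(
                rng, W, pref, label, N
            )

    return GroundTruth(
        W_true=W, locus_amplitudes=amps, preferred_true=preferred,
        fields_true=fields, modification_true=mods,
        kernel_latency_ms=lat, kernel_pwhm_ms=pwhm, unit_type=utype,
        rate_profile=rprof,
    )


def _rewire_field(rng, W, pref, label, N):
    """Construct one across-condition field per the requested modification."""
    m = W.shape[0]
    if label == "preserved":
        return W[:, pref].copy(), (label, np.eye(N)[pref])
    if label == "merging":
        other = int(rng.choice([i for i in range(N) if i != pref]))
        c_pref = rng.uniform(0.4, 0.65)
        coefs = np.zeros(N)
        coefs[pref], coefs[other] = c_pref, 1.0 - c_pref
        return W @ coefs, (label, coefs)
    # unmatched: reject until no non-negative mixture of the planted
    # synergies resembles the fresh pattern
    for _ in range(1000):
        k = int(rng.integers(1, 3))
        idx = rng.choice(m, size=k, replace=False)
        v = _sample_synergy_column(rng, m, idx)
        if _nnls_reconstruction_sp(v, W) < 0.6:
            return v, (label, np.zeros(N))
    raise RuntimeError("could not construct an unmatched field "
                       "(similarity constraints infeasible)")


# ---------------------------------------------------------------------------
# trials and spikes

def make_trials(cfg: SimConfig, seed: int) -> list[Trial]:
    """Sequential trial table: per condition, all loci rostral to caudal,
    ``trials_per_locus`` trains each, separated by the intertrial interval."""
    rng = make_rng(seed, "trials")
    trials = []
    t = cfg.intertrial_ms / 1000.0
    period = cfg.trial_period_s
    k = 0
    for cond in cfg.conditions:
        for l in range(cfg.n_loci):
            for _ in range(cfg.trials_per_locus):
                power = 1.0
                if cond == "SSAT":
                    power = float(rng.uniform(*cfg.ssat_power))
                trials.append(Trial(
                    trial_id=f"t{k:04d}", condition=cond,
                    locus_um=l * cfg.locus_step_um,
                    locus2_um=0.0 if cond == "CoST" else None,
                    power_frac=power,
                    stim_on=t, stim_off=t + cfg.train_ms / 1000.0,
                ))
                t += period
                k += 1
    return trials


def _poisson_segment(rng, rate, t_start, t_stop):
    if rate <= 0 or t_stop <= t_start:
        return np.empty(0)
    n = rng.poisson(rate * (t_stop - t_start))
    return np.sort(rng.uniform(t_start, t_stop, size=n))


def _apply_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Sequentially delete spikes closer than the dead time to the last
    accepted spike."""
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def simulate_spikes(
    gt: GroundTruth, trials: list[Trial], cfg: SimConfig, seed: int
) -> list[SpikeTrain]:
    """Inhomogeneous Poisson spiking with a refractory dead time.

    Rate is ``base_rate_hz`` between trains and
    ``stim_rate_hz * g(locus)`` during each train, where ``g`` is the
    unit's smooth per-locus gain profile (tied to its preferred synergy's
    amplitude profile).
    """
    trains = []
    t_end = max(tr.stim_off for tr in trials) + 1.0
    for u, uid in enumerate(sorted(gt.preferred_true)):
        rng = make_rng(seed, f"spikes/{uid}")
        g = gt.rate_profile[uid]
        pieces = [_poisson_segment(rng, cfg.base_rate_hz, 0.0, t_end)]
        for tr in trials:
            l = int(round(tr.locus_um / cfg.locus_step_um))
            stim_rate = cfg.stim_rate_hz * g[l % len(g)]
            extra = max(stim_rate - cfg.base_rate_hz, 0.0)
            pieces.append(_poisson_segment(rng, extra, tr.stim_on, tr.stim_off))
        times = np.sort(np.concatenate(pieces))
        times = _apply_refractory(times, cfg.refractory_ms / 1000.0)
        trains.append(SpikeTrain(unit_id=uid, times=times))
    return trains


# ---------------------------------------------------------------------------
# EMG

def raised_cosine_kernel(
    latency_ms: float, pwhm_ms: float, fs: float, amplitude: float = 1.0
) -> tuple[np.ndarray, int]:
    """Raised-cosine post-spike kernel.

    ``0.5 * (1 + cos(pi * (t - latency) / pwhm))`` on compact support
    ``latency +- pwhm`` — its full width at half maximum is exactly
    ``pwhm_ms``.  Returns the sampled kernel and the sample offset of its
    first point relative to the spike.
    """
    start = int(np.floor((latency_ms - pwhm_ms) * fs / 1000.0))
    stop = int(np.ceil((latency_ms + pwhm_ms) * fs / 1000.0))
    t_ms = np.arange(start, stop + 1) * 1000.0 / fs
    k = 0.5 * (1.0 + np.cos(np.pi * (t_ms - latency_ms) / pwhm_ms))
    k[np.abs(t_ms - latency_ms) > pwhm_ms] = 0.0
    return amplitude * k, start


def envelope_coefficients(
    trials: list[Trial], cfg: SimConfig, amps: np.ndarray, n_samples: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Planted activation coefficients C [n_true x n_samples]: one smooth
    non-negative bump per trial per synergy, amplitude set by the synergy's
    per-locus profile, scaled by the trial's laser power and (when ``rng``
    is given) jittered trial-to-trial so the synergies' activations are not
    collinear."""
    N = amps.shape[0]
    C = np.zeros((N, n_samples))
    fs = cfg.fs
    resp_s = cfg.train_ms / 1000.0 + 0.1   # response outlasts the train
    for tr in trials:
        l = int(round(tr.locus_um / cfg.locus_step_um)) % amps.shape[1]
        i0 = int(np.floor(tr.stim_on * fs))
        n = int(round(resp_s * fs))
        idx = np.arange(i0, min(i0 + n, n_samples))
        bump = np.sin(np.pi * (idx - i0) / n) ** 2
        jitter = np.ones(N)
        if rng is not None and cfg.envelope_jitter > 0:
            jitter = np.maximum(
                rng.normal(1.0, cfg.envelope_jitter, size=N), 0.0
            )
        for i in range(N):
            amp = cfg.envelope_amp * amps[i, l] * tr.power_frac * jitter[i]
            C[i, idx] += amp * bump
    return C


def simulate_emg(
    gt: GroundTruth,
    spikes: list[SpikeTrain],
    trials: list[Trial],
    cfg: SimConfig,
    seed: int,
) -> EMGRecording:
    """Compose envelope-domain EMG: synergy mixtures + spike-locked kernels
    + tonic background + noise, clamped at zero."""
    rng = make_rng(seed, "emg")
    t_end = max(tr.stim_off for tr in trials) + 1.0
    n = int(round(t_end * cfg.fs))
    C = envelope_coefficients(trials, cfg, gt.locus_amplitudes, n, rng=rng)
    signal = gt.W_true @ C + cfg.tonic_level

    stim_ons = np.array([tr.stim_on for tr in trials])
    conds = [tr.condition for tr in trials]
    for st in spikes:
        kern, off = raised_cosine_kernel(
            gt.kernel_latency_ms[st.unit_id], gt.kernel_pwhm_ms[st.unit_id],
            cfg.fs, cfg.kernel_amplitude,
        )
        # each spike contributes its condition's muscle field
        trial_idx = np.clip(np.searchsorted(stim_ons, st.times) - 1,
                            0, len(trials) - 1)
        for t_spk, ti in zip(st.times, trial_idx):
            f = _normalize(gt.fields_true[st.unit_id][conds[ti]])
            i0 = int(np.floor(t_spk * cfg.fs)) + off
            a, b = max(i0, 0), min(i0 + kern.size, n)
            if b > a:
                signal[:, a:b] += np.outer(f, kern[a - i0:b - i0])

    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    if cfg.artifact_rate > 0:
        sd = signal.std(axis=1, keepdims=True)
        n_art = int(round(cfg.artifact_rate * n))
        for j in range(signal.shape[0]):
            idx = rng.choice(n, size=n_art, replace=False)
            signal[j, idx] += cfg.artifact_sd_mult * sd[j, 0]
    return EMGRecording(signal=np.maximum(signal, 0.0), fs=cfg.fs,
                        muscles=cfg.muscles[: cfg.n_muscles], t0=0.0)


def generate_dataset(
    cfg: SimConfig, seed: int, out_dir: str | Path,
    pipeline_config: PipelineConfig | None = None,
) -> GroundTruth:
    """Simulate one animal and write the dataset bundle plus
    ``ground_truth.json``; byte-deterministic for a fixed seed."""
    gt = make_ground_truth(cfg, seed)
    trials = make_trials(cfg, seed)
    spikes = simulate_spikes(gt, trials, cfg, seed)
    rec = simulate_emg(gt, spikes, trials, cfg, seed)
    out_dir = Path(out_dir)
    pc = pipeline_config or PipelineConfig(rng_seed=seed)
    write_dataset(out_dir, rec, spikes, trials, pc)
    gt.to_json(out_dir / "ground_truth.json")
    return gt
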