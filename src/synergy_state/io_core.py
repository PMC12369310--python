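"""Core data model, dataset bundle I/O, configuration and seeding.

A dataset bundle is one directory holding::

    emg.h5        HDF5 container: dataset "signal" [n_muscles x n_samples],
                  attributes fs (Hz), muscles (labels), t0 (s)
    spikes.tsv    columns unit_id, time_s
    trials.tsv    columns trial_id, condition, locus_um, locus2_um,
                  power_frac, stim_on_s, stim_off_s
    config.yaml   serialized :class:`PipelineConfig`

Times are stored in seconds throughout; millisecond window parameters are
converted at their use sites.  Trials are half-open intervals
``[stim_on, stim_off)`` and the sample index of time ``t`` at rate ``fs`` is
``floor((t - t0) * fs)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

CONDITIONS = ("SST", "SSAT", "CoST")

#: hindlimb muscles recorded in the study, in fixed order
DEFAULT_MUSCLES = ("TA", "VL", "VM", "BF", "GM", "GC")


class DatasetError(ValueError):
    """Raised for malformed dataset bundles or invariant violations."""


@dataclass
class EMGRecording:
    """Multichannel EMG as a muscles x samples matrix.

    After preprocessing the signal is a non-negative, variance-normalized
    envelope; raw recordings may be bipolar.
    """

    signal: np.ndarray            # [n_muscles, n_samples]
    fs: float                     # Hz
    muscles: tuple[str, ...]
    t0: float = 0.0               # time of first sample, s

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.muscles = tuple(self.muscles)
        if self.signal.ndim != 2:
            raise DatasetError("EMG signal must be 2-D [n_muscles, n_samples]")
        if self.signal.shape[0] != len(self.muscles):
            raise DatasetError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.muscles)} muscle labels"
            )
        if not self.fs > 0:
            raise DatasetError("sampling rate must be positive")

    @property
    def n_muscles(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def sample_index(self, t: float | np.ndarray) -> np.ndarray:
        """Sample index of time ``t``: floor((t - t0) * fs)."""
        return np.floor((np.asarray(t) - self.t0) * self.fs).astype(np.int64)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class SpikeTrain:
    """Ordered spike times (s) of one sorted unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise DatasetError("spike times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise DatasetError(
                f"non-monotone spike times for unit {self.unit_id!r}"
            )

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Trial:
    """One stimulation trial.

    ``condition`` is SST (single fibre, threshold power), SSAT (single fibre,
    120-150% of threshold) or CoST (two-fibre co-stimulation at threshold);
    ``locus_um`` is the rostrocaudal position of the (moving) fibre and
    ``locus2_um`` the second fibre's position, present only for CoST.
    """

    trial_id: str
    condition: str
    locus_um: float
    power_frac: float
    stim_on: float
    stim_off: float
    locus2_um: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DatasetError(f"unknown condition {self.condition!r}")
        if not self.stim_off - self.stim_on > 0:
            raise DatasetError(f"trial {self.trial_id!r}: stim_off <= stim_on")
        if self.condition == "CoST" and self.locus2_um is None:
            raise DatasetError(f"CoST trial {self.trial_id!r} needs two loci")
        if self.condition == "SSAT" and not 1.2 <= self.power_frac <= 1.5:
            raise DatasetError(
                f"SSAT trial {self.trial_id!r}: power_frac "
                f"{self.power_frac} outside [1.2, 1.5]"
            )


@dataclass
class PipelineConfig:
    """All analysis windows and thresholds, with study defaults.

    Window parameters are in milliseconds relative to the spike trigger.
    """

    spta_window_ms: tuple[float, float] = (-30.0, 50.0)
    test_window_ms: tuple[float, float] = (3.0, 16.0)
    baseline_window_ms: tuple[float, float] = (-30.0, -10.0)
    baseline_sd_mult: float = 2.0
    pure_onset_ms: float = 3.5
    pure_pwhm_ms: float = 7.0
    r2_threshold: float = 0.80
    nnmf_restarts: int = 100
    k_range: tuple[int, int] = (2, 10)
    merge_coef_min: float = 0.2
    merge_reconstruction_sp: float = 0.8
    preserved_sp_min: float = 0.8
    consistency_sp: float = 0.78
    target_fs: float = 1000.0
    hp_order: int = 50
    hp_cut: float = 50.0
    lp_order: int = 50
    lp_cut: float = 20.0
    artifact_pctl: float = 99.9
    artifact_sd_thresh: float = 8.0
    min_spikes: int = 30
    response_margin_s: float = 0.1    # rate/coefficient window = stim + margin
    n_shuffles: int = 200
    input_domain: str = "envelope"    # "raw" applies the full filter chain
    rng_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("spta_window_ms", "test_window_ms", "baseline_window_ms",
                  "k_range"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("spta_window_ms", "test_window_ms", "baseline_window_ms",
                  "k_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def make_rng(seed: int, stage_name: str) -> np.random.Generator:
    """Independent, reproducible random stream for one pipeline stage.

    The stream is keyed on ``(seed, stage_name)``: the same pair always
    yields the same draws, different pairs yield independent streams.
    """
    digest = hashlib.sha256(stage_name.encode("utf-8")).digest()
    stage_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage_key]))


# ---------------------------------------------------------------------------
# bundle I/O

def write_dataset(
    path: str | Path,
    rec: EMGRecording,
    spikes: list[SpikeTrain],
    trials: list[Trial],
    config: PipelineConfig | None = None,
) -> None:
    """Write a dataset bundle directory (deterministic bytes for fixed input)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "emg.h5", "w", track_order=True) as f:
        ds = f.create_dataset("signal", data=rec.signal, track_times=False)
        ds.attrs["fs"] = rec.fs
        ds.attrs["t0"] = rec.t0
        ds.attrs["muscles"] = list(rec.muscles)
    spike_rows = [
        {"unit_id": st.unit_id, "time_s": t}
        for st in spikes for t in st.times
    ]
    pd.DataFrame(spike_rows, columns=["unit_id", "time_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False, float_format="%.9f"
    )
    trial_rows = [
        {
            "trial_id": tr.trial_id,
            "condition": tr.condition,
            "locus_um": tr.locus_um,
            "locus2_um": "" if tr.locus2_um is None else tr.locus2_um,
            "power_frac": tr.power_frac,
            "stim_on_s": tr.stim_on,
            "stim_off_s": tr.stim_off,
        }
        for tr in sorted(trials, key=lambda t: t.stim_on)
    ]
    pd.DataFrame(
        trial_rows,
        columns=["trial_id", "condition", "locus_um", "locus2_um",
                 "power_frac", "stim_on_s", "stim_off_s"],
    ).to_csv(path / "trials.tsv", sep="\t", index=False, float_format="%.9f")
    (config or PipelineConfig()).to_yaml(path / "config.yaml")


def read_dataset(
    path: str | Path,
) -> tuple[EMGRecording, list[SpikeTrain], list[Trial], PipelineConfig]:
    """Read a dataset bundle, validating all invariants."""
    path = Path(path)
    emg_path = path / "emg.h5"
    if not emg_path.exists():
        raise DatasetError(f"missing {emg_path}")
    with h5py.File(emg_path, "r") as f:
        ds = f["signal"]
        if "muscles" not in ds.attrs:
            raise DatasetError("emg.h5 missing channel labels")
        muscles = tuple(
            m.decode() if isinstance(m, bytes) else str(m)
            for m in ds.attrs["muscles"]
        )
        rec = EMGRecording(
            signal=ds[()], fs=float(ds.attrs["fs"]),
            muscles=muscles, t0=float(ds.attrs.get("t0", 0.0)),
        )

    sp = pd.read_csv(path / "spikes.tsv", sep="\t")
    spikes = []
    for unit_id, grp in sp.groupby("unit_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DatasetError(f"non-monotone spike times for unit {unit_id!r}")
        span = (rec.t0, rec.t0 + rec.duration)
        if times.size and (times[0] < span[0] or times[-1] > span[1]):
            raise DatasetError(
                f"unit {unit_id!r}: spike times outside recording span"
            )
        spikes.append(SpikeTrain(unit_id=str(unit_id), times=times))

    tr = pd.read_csv(path / "trials.tsv", sep="\t")
    trials = []
    for row in tr.itertuples(index=False):
        locus2 = getattr(row, "locus2_um", None)
        if locus2 is not None and (pd.isna(locus2) or locus2 == ""):
            locus2 = None
        trials.append(Trial(
            trial_id=str(row.trial_id), condition=str(row.condition),
            locus_um=float(row.locus_um),
            locus2_um=None if locus2 is None else float(locus2),
            power_frac=float(row.power_frac),
            stim_on=float(row.stim_on_s), stim_off=float(row.stim_off_s),
        ))
    trials.sort(key=lambda t: t.stim_on)
    for a, b in zip(trials, trials[1:]):
        if b.stim_on < a.stim_off:
            raise DatasetError(
                f"overlapping trials {a.trial_id!r} and {b.trial_id!r}"
            )

    cfg_path = path / "config.yaml"
    config = PipelineConfig.from_yaml(cfg_path) if cfg_path.exists() \
        else PipelineConfig()
    return rec, spikes, trials, config
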