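"""EMG conditioning: down-sampling, FIR filter chain, artifact replacement
and variance normalization.

The chain mirrors standard intramuscular-EMG envelope extraction: after
down-sampling to 1 kHz, a 50th-order FIR high-pass at 50 Hz removes
movement/baseline components, rectification and a 50th-order FIR low-pass at
20 Hz produce a smooth non-negative envelope, motion artifacts are replaced
by the channel's 99.9th percentile, and each channel is divided by its
standard deviation.  Filters are applied forward-backward (zero phase) so
post-spike latencies in the 3-16 ms test window are not shifted by group
delay.  Percentiles use linear interpolation between order statistics
(``numpy.percentile`` default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io_core import EMGRecording, PipelineConfig


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    n_artifact_samples_replaced: dict[str, int] = field(default_factory=dict)
    replacement_value: dict[str, float] = field(default_factory=dict)
    pre_variance: dict[str, float] = field(default_factory=dict)
    post_variance: dict[str, float] = field(default_factory=dict)
    filters_applied: list[str] = field(default_factory=list)


def downsample(rec: EMGRecording, target_fs: float) -> EMGRecording:
    """Anti-aliased resampling to exactly ``target_fs``.

    Polyphase resampling with a FIR anti-alias filter cutting at
    0.45 * target_fs; output length is round(n * target_fs / fs) within one
    sample and a constant signal stays constant.
    """
    if target_fs <= 0:
        raise PreprocessError("target_fs must be positive")
    if target_fs > rec.fs:
        raise PreprocessError("target_fs must not exceed the input rate")
    if target_fs == rec.fs:
        return EMGRecording(rec.signal.copy(), rec.fs, rec.muscles, rec.t0)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10 ** 6)
    up, down = ratio.numerator, ratio.denominator
    # anti-alias FIR designed at the upsampled rate, cutting at 0.45x the
    # target rate (resample_poly compensates the zero-stuffing gain)
    numtaps = 2 * 10 * max(up, down) + 1
    h = sps.firwin(numtaps, 0.45 * target_fs, fs=rec.fs * up)
    out = sps.resample_poly(rec.signal, up, down, axis=1, window=h)
    return EMGRecording(out, float(target_fs), rec.muscles, rec.t0)


def _fir_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return sps.filtfilt(taps, [1.0], x, axis=-1)


def filter_chain(
    rec: EMGRecording, config: PipelineConfig | None = None
) -> EMGRecording:
    """High-pass -> rectify -> low-pass envelope extraction (zero phase).

    Output is clamped at zero (the zero-phase low-pass can slightly
    undershoot).
    """
    cfg = config or PipelineConfig()
    n_taps = max(cfg.hp_order, cfg.lp_order) + 1
    if rec.n_samples < 3 * n_taps:
        raise PreprocessError(
            f"signal length {rec.n_samples} shorter than 3x filter length"
        )
    hp = sps.firwin(cfg.hp_order + 1, cfg.hp_cut, pass_zero=False, fs=rec.fs)
    hp -= hp.sum() / hp.size          # exact null at DC
    lp = sps.firwin(cfg.lp_order + 1, cfg.lp_cut, pass_zero=True, fs=rec.fs)
    x = _fir_zero_phase(rec.signal, hp)
    x = np.abs(x)
    x = _fir_zero_phase(x, lp)
    return EMGRecording(np.maximum(x, 0.0), rec.fs, rec.muscles, rec.t0)


def smooth_envelope(
    rec: EMGRecording, config: PipelineConfig | None = None
) -> EMGRecording:
    """Low-pass smoothing only, for signals already in the envelope domain
    (the high-pass/rectification steps apply to raw bipolar EMG)."""
    cfg = config or PipelineConfig()
    lp = sps.firwin(cfg.lp_order + 1, cfg.lp_cut, pass_zero=True, fs=rec.fs)
    x = _fir_zero_phase(rec.signal, lp)
    return EMGRecording(np.maximum(x, 0.0), rec.fs, rec.muscles, rec.t0)


def detect_artifacts(
    rec: EMGRecording, sd_thresh: float = 8.0, dilate_ms: float = 5.0,
    median_ms: float = 5.0,
) -> np.ndarray:
    """Deterministic surrogate for visual motion-artifact screening.

    Motion artifacts are sharp isolated deflections, while physiological
    envelope features (including post-spike transients) are smooth on the
    millisecond scale.  Each channel is compared against a short running
    median; samples whose residual exceeds ``sd_thresh`` residual-SDs are
    flagged and the mask is dilated by ``dilate_ms`` on each side.
    Thresholding the raw amplitude instead would flag genuine spike-locked
    EMG peaks on strongly activated muscles.
    """
    width = max(int(round(median_ms * rec.fs / 1000.0)) | 1, 3)
    baseline = sps.medfilt(rec.signal, kernel_size=(1, width))
    resid = rec.signal - baseline
    sd = resid.std(axis=1, keepdims=True)
    mask = np.abs(resid) > sd_thresh * sd
    width = int(round(dilate_ms * rec.fs / 1000.0))
    if width > 0 and mask.any():
        kernel = np.ones(2 * width + 1)
        for j in range(mask.shape[0]):
            mask[j] = np.convolve(mask[j].astype(float), kernel,
                                  mode="same") > 0
    return mask


def replace_artifacts(
    rec: EMGRecording,
    mask: np.ndarray,
    percentile: float = 99.9,
) -> tuple[EMGRecording, PreprocessReport]:
    """Replace masked samples of each channel with that channel's
    ``percentile`` value computed over its unmasked samples."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rec.signal.shape:
        raise PreprocessError("mask shape must match the signal")
    report = PreprocessReport()
    out = rec.signal.copy()
    for j, muscle in enumerate(rec.muscles):
        mj = mask[j]
        if mj.mean() > 0.5:
            raise PreprocessError(
                f"artifact mask covers > 50% of channel {muscle}; "
                "percentile replacement unreliable"
            )
        report.pre_variance[muscle] = float(rec.signal[j].var())
        n_masked = int(mj.sum())
        report.n_artifact_samples_replaced[muscle] = n_masked
        if n_masked:
            value = float(np.percentile(out[j, ~mj], percentile))
            out[j, mj] = value
            report.replacement_value[muscle] = value
        report.post_variance[muscle] = float(out[j].var())
    return EMGRecording(out, rec.fs, rec.muscles, rec.t0), report


def variance_normalize(rec: EMGRecording) -> EMGRecording:
    """Divide each channel by its standard deviation (no mean subtraction,
    preserving non-negativity for NNMF)."""
    sd = rec.signal.std(axis=1)
    for j, muscle in enumerate(rec.muscles):
        if sd[j] <= 0:
            raise PreprocessError(f"zero-variance channel: muscle {muscle}")
    return EMGRecording(rec.signal / sd[:, None], rec.fs, rec.muscles, rec.t0)


def preprocess_pipeline(
    rec: EMGRecording, config: PipelineConfig | None = None
) -> tuple[EMGRecording, PreprocessReport]:
    """Full conditioning chain: down-sample, envelope extraction (full
    filter chain for raw input, low-pass smoothing for envelope-domain
    input), artifact replacement, variance normalization."""
    cfg = config or PipelineConfig()
    out = downsample(rec, cfg.target_fs)
    if cfg.input_domain == "raw":
        out = filter_chain(out, cfg)
        applied = [f"hp FIR order {cfg.hp_order} @ {cfg.hp_cut} Hz",
                   "rectification",
                   f"lp FIR order {cfg.lp_order} @ {cfg.lp_cut} Hz"]
    else:
        # envelope-domain input is already conditioned; re-filtering would
        # attenuate millisecond-scale post-spike transients several-fold
        applied = []
    mask = detect_artifacts(out, cfg.artifact_sd_thresh)
    out, report = replace_artifacts(out, mask, cfg.artifact_pctl)
    out = variance_normalize(out)
    report.filters_applied = [f"resample -> {cfg.target_fs} Hz"] + applied
    for j, muscle in enumerate(out.muscles):
        report.post_variance[muscle] = float(out.signal[j].var())
    return out, report
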