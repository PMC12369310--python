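"""Muscle-synergy extraction by multi-restart non-negative matrix
factorization with R^2-based model-order selection.

The preprocessed EMG matrix D [n_muscles x n_samples] is modelled as
``D = W C^T + R`` with non-negative muscle-weight matrix W
[n_muscles x N] and activation coefficients C [n_samples x N].  The
reconstruction quality is

    R^2 = 1 - SSE / SST,
    SST = sum_ij (D_ij - mean_i(D))^2,   SSE = ||D - W C^T||_F^2,

where mean_i(D) is muscle i's mean.  The factorization minimizes SSE
(multiplicative updates) from many random initializations — entries drawn
uniformly between 0 and max(D) — keeping the restart with the lowest SSE;
the model order is the smallest N reaching R^2 >= 0.80.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .io_core import EMGRecording, PipelineConfig, Trial, make_rng


class SynergyError(ValueError):
    pass


@dataclass
class SynergySet:
    """Extracted synergies for one condition.

    W columns are L2-normalized for reporting; C rows carry the
    counter-scaling so ``W @ C.T`` reproduces the un-normalized
    reconstruction.
    """

    condition: str
    W: np.ndarray                 # [n_muscles, N], unit-norm columns
    C: np.ndarray                 # [n_samples, N]
    R2: float
    N: int
    restart_losses: list[float] = field(default_factory=list)
    r2_by_order: dict[int, float] = field(default_factory=dict)
    muscles: tuple[str, ...] = ()


def r_squared(D: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """R^2 of the reconstruction W C^T against D, with the total sum of
    squares taken around each muscle's mean."""
    D = np.asarray(D, dtype=float)
    resid = D - W @ C.T
    sst = float(((D - D.mean(axis=1, keepdims=True)) ** 2).sum())
    if sst == 0:
        raise SynergyError("constant data: total sum of squares is zero")
    return 1.0 - float((resid ** 2).sum()) / sst


def _fit_once(D, N, W0, H0, tol, max_iter):
    model = NMF(
        n_components=N, init="custom", solver="mu",
        beta_loss="frobenius", tol=tol, max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(D, W=W0, H=H0)
    H = model.components_
    return W, H, float(((D - W @ H) ** 2).sum())


def extract_at_order(
    D: np.ndarray,
    N: int,
    restarts: int = 100,
    seed: int = 0,
    condition: str = "SST",
    muscles: tuple[str, ...] = (),
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SynergySet:
    """Best-of-restarts NNMF at a fixed number of synergies.

    Each restart draws both factor matrices from uniform(0, max(D));
    convergence when the relative SSE change falls below ``tol`` or after
    ``max_iter`` multiplicative updates.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise SynergyError("NNMF input must be non-negative")
    if not 1 <= N <= D.shape[0]:
        raise SynergyError(f"invalid synergy count N={N}")
    rng = make_rng(seed, f"nnmf/{condition}/N={N}")
    hi = float(D.max())
    best = None
    losses = []
    for _ in range(restarts):
        W0 = rng.uniform(0.0, hi, size=(D.shape[0], N))
        H0 = rng.uniform(0.0, hi, size=(N, D.shape[1]))
        W, H, sse = _fit_once(D, N, W0, H0, tol, max_iter)
        losses.append(sse)
        if best is None or sse < best[2]:
            best = (W, H, sse)
    W, H, _ = best
    # report unit-norm synergy columns; counter-scale the coefficients
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    C = (H * norms[:, None]).T
    return SynergySet(
        condition=condition, W=W, C=C, R2=r_squared(D, W, C), N=N,
        restart_losses=losses, muscles=tuple(muscles),
    )


def select_model_order(
    D: np.ndarray,
    r2_threshold: float = 0.80,
    restarts: int = 100,
    seed: int = 0,
    condition: str = "SST",
    muscles: tuple[str, ...] = (),
    **fit_kw,
) -> SynergySet:
    """Smallest N in 1..n_muscles whose best-of-restarts R^2 reaches the
    threshold (the order-n_muscles factorization always suffices)."""
    D = np.asarray(D, dtype=float)
    r2_by_order: dict[int, float] = {}
    chosen = None
    for N in range(1, D.shape[0] + 1):
        ss = extract_at_order(D, N, restarts, seed, condition, muscles,
                              **fit_kw)
        r2_by_order[N] = ss.R2
        if ss.R2 >= r2_threshold:
            chosen = ss
            break
    if chosen is None:                      # numerically short of threshold
        chosen = ss
    chosen.r2_by_order = r2_by_order
    return chosen


def extract_condition(
    rec: EMGRecording,
    trials: list[Trial],
    condition: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[SynergySet, np.ndarray]:
    """Model-order-selected synergies from one condition's concatenated
    trial windows (stimulation onset to offset + response margin).

    Returns the synergy set and the sample indices (into the recording)
    that were concatenated, so coefficient values can be mapped back to
    trial time.
    """
    cfg = config or PipelineConfig()
    idx = condition_sample_indices(rec, trials, condition, cfg)
    if idx.size == 0:
        raise SynergyError(f"no trials for condition {condition}")
    D = rec.signal[:, idx]
    ss = select_model_order(
        D, cfg.r2_threshold, cfg.nnmf_restarts, seed, condition, rec.muscles
    )
    return ss, idx


def condition_sample_indices(
    rec: EMGRecording,
    trials: list[Trial],
    condition: str,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Concatenated sample indices of one condition's response windows."""
    cfg = config or PipelineConfig()
    pieces = []
    for tr in trials:
        if tr.condition != condition:
            continue
        a = int(rec.sample_index(tr.stim_on))
        b = int(rec.sample_index(tr.stim_off + cfg.response_margin_s))
        pieces.append(np.arange(max(a, 0), min(b, rec.n_samples)))
    return np.concatenate(pieces) if pieces else np.empty(0, dtype=int)


def coefficient_amplitudes(
    C: np.ndarray,
    sample_idx: np.ndarray,
    rec: EMGRecording,
    trials: list[Trial],
    condition: str,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Trial- and time-averaged activation-coefficient amplitude per locus.

    ``C`` is [n_samples_cond x N] over the concatenated condition samples
    ``sample_idx``.  Entry (i, l) is the mean over locus l's trials of the
    time-mean of coefficient i within each trial's response window; loci
    with no trials yield NaN.
    """
    cfg = config or PipelineConfig()
    pos = {int(s): k for k, s in enumerate(sample_idx)}
    loci = sorted({tr.locus_um for tr in trials if tr.condition == condition})
    N = C.shape[1]
    out = np.full((N, len(loci)), np.nan)
    for li, locus in enumerate(loci):
        per_trial = []
        for tr in trials:
            if tr.condition != condition or tr.locus_um != locus:
                continue
            a = int(rec.sample_index(tr.stim_on))
            b = int(rec.sample_index(tr.stim_off + cfg.response_margin_s))
            rows = [pos[s] for s in range(a, min(b, rec.n_samples)) if s in pos]
            if rows:
                per_trial.append(C[rows].mean(axis=0))
        if per_trial:
            out[:, li] = np.mean(per_trial, axis=0)
    return out, loci
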