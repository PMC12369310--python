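"""Correlation between unit firing rate and synergy activation amplitude
across stimulation loci.

For each unit, the across-trial mean of the time-averaged firing rate is
computed per stimulation locus (response window = train onset to offset
plus a margin, matching the coefficient-amplitude window).  For each
synergy, the Pearson correlation of its per-locus activation amplitude with
the unit's rate profile is taken across loci; ``C_corres`` is the absolute
correlation with the unit's preferred synergy and ``C_prefer`` the synergy
of maximal absolute correlation.  Signed correlations are retained in the
output; the absolute value enters only the selection and summary
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import PipelineConfig, SpikeTrain, Trial


class CorrelationError(ValueError):
    pass


@dataclass
class RateProfile:
    unit_id: str
    loci: list[float]                     # rostral -> caudal
    rates: np.ndarray                     # Hz, per locus


@dataclass
class CorrelationResult:
    unit_id: str
    r_by_synergy: np.ndarray              # signed Pearson r per synergy
    c_corres_r: float                     # |r| at the preferred synergy
    c_prefer_index: int
    c_prefer_r: float                     # max |r|


def firing_rate_by_locus(
    spikes: SpikeTrain,
    trials: list[Trial],
    condition: str = "SST",
    config: PipelineConfig | None = None,
) -> RateProfile:
    """Across-trial mean of the time-averaged firing rate per locus."""
    cfg = config or PipelineConfig()
    loci = sorted({tr.locus_um for tr in trials if tr.condition == condition})
    rates = np.full(len(loci), np.nan)
    for li, locus in enumerate(loci):
        per_trial = []
        for tr in trials:
            if tr.condition != condition or tr.locus_um != locus:
                continue
            a, b = tr.stim_on, tr.stim_off + cfg.response_margin_s
            n = np.count_nonzero((spikes.times >= a) & (spikes.times < b))
            per_trial.append(n / (b - a))
        if per_trial:
            rates[li] = float(np.mean(per_trial))
    return RateProfile(unit_id=spikes.unit_id, loci=loci, rates=rates)


def correlate(
    rate_profile: RateProfile,
    coefficient_amplitudes: np.ndarray,
    preferred_index: int,
) -> CorrelationResult:
    """Pearson correlation of the unit's rate profile with each synergy's
    per-locus coefficient amplitude.

    Zero-variance series yield an undefined (NaN) correlation with a
    warning; at least 3 loci with both quantities are required.
    """
    A = np.asarray(coefficient_amplitudes, dtype=float)
    x = rate_profile.rates
    if A.shape[1] != x.size:
        raise CorrelationError("locus axes do not align")
    valid = ~np.isnan(x) & ~np.isnan(A).any(axis=0)
    if valid.sum() < 3:
        raise CorrelationError("need at least 3 loci with both quantities")
    rs = np.empty(A.shape[0])
    for i in range(A.shape[0]):
        xi, yi = x[valid], A[i, valid]
        if np.std(xi) == 0 or np.std(yi) == 0:
            warnings.warn(
                f"zero-variance series for synergy {i}; r undefined",
                stacklevel=2,
            )
            rs[i] = np.nan
        else:
            rs[i] = stats.pearsonr(xi, yi).statistic
    absr = np.abs(rs)
    prefer = int(np.nanargmax(absr))
    return CorrelationResult(
        unit_id=rate_profile.unit_id,
        r_by_synergy=rs,
        c_corres_r=float(absr[preferred_index]),
        c_prefer_index=prefer,
        c_prefer_r=float(absr[prefer]),
    )


def pooled_regression(
    rates: np.ndarray, amplitudes: np.ndarray
) -> tuple[float, float, float]:
    """Ordinary least squares of coefficient amplitude on firing rate over
    pooled unit-locus points; returns (slope, R^2, two-sided t-test p for
    the slope)."""
    x = np.asarray(rates, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise CorrelationError("need at least 3 points for regression")
    if np.std(x) == 0:
        raise CorrelationError("degenerate regressor: zero variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue ** 2), float(fit.pvalue)
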