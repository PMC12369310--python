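"""Across-condition modification of a unit's preferred synergy:
merging / unmatched / preserved.

Given a unit's preferred synergy in the source condition (SST) and in a
target condition (SSAT or CoST), the target synergy is regressed on all
source-condition synergies by non-negative least squares.  The modification
is *merging* when the reconstruction resembles the target (scalar product
>= 0.8), at least two source synergies contribute (coefficient > 0.2) and
the unit's own source-preferred synergy is among the contributors.
Otherwise the pair is *preserved* when the two preferred synergies are
directly similar (scalar product >= 0.8) and *unmatched* when not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .io_core import PipelineConfig
from .matching import scalar_product


class ModificationError(ValueError):
    pass


@dataclass
class ModificationResult:
    unit_id: str
    condition_pair: str                   # e.g. "SST->SSAT"
    form: str                             # merging | unmatched | preserved
    nnls_coefficients: np.ndarray         # over source synergies
    contributing: list[int]               # coefficient > threshold
    reconstruction_sp: float
    pairwise_sp: float


def _unit_columns(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=0, keepdims=True)
    if np.any(norms == 0):
        raise ModificationError("zero synergy column")
    return M / norms


def nnls_reconstruct(
    target: np.ndarray, source_synergies: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Non-negative least-squares reconstruction of the (L2-normalized)
    target from the L2-normalized source synergy columns.

    Returns (coefficients, reconstruction, reconstruction scalar product);
    a target orthogonal to every source yields all-zero coefficients and
    scalar product 0.
    """
    if source_synergies.size == 0:
        raise ModificationError("empty source synergy set")
    A = _unit_columns(np.asarray(source_synergies, dtype=float))
    t = np.asarray(target, dtype=float)
    nt = np.linalg.norm(t)
    if nt == 0:
        raise ModificationError("zero target vector")
    coefs, _ = nnls(A, t / nt)
    recon = A @ coefs
    sp = 0.0 if np.linalg.norm(recon) == 0 else scalar_product(recon, t)
    return coefs, recon, sp


def classify_modification(
    unit_id: str,
    preferred_src: np.ndarray,
    preferred_tgt: np.ndarray,
    source_synergies: np.ndarray,
    src_index: int,
    condition_pair: str = "SST->SSAT",
    config: PipelineConfig | None = None,
) -> ModificationResult:
    """Decision sequence: merging -> preserved -> unmatched.

    ``source_synergies`` holds all source-condition synergies as columns and
    ``src_index`` identifies the unit's source-preferred synergy among them.
    """
    cfg = config or PipelineConfig()
    coefs, _, recon_sp = nnls_reconstruct(preferred_tgt, source_synergies)
    contributing = [int(i) for i in np.flatnonzero(coefs > cfg.merge_coef_min)]
    pair_sp = scalar_product(preferred_src, preferred_tgt)
    if (recon_sp >= cfg.merge_reconstruction_sp
            and len(contributing) >= 2 and src_index in contributing):
        form = "merging"
    elif pair_sp >= cfg.preserved_sp_min:
        form = "preserved"
    else:
        form = "unmatched"
    return ModificationResult(
        unit_id=unit_id, condition_pair=condition_pair, form=form,
        nnls_coefficients=coefs, contributing=contributing,
        reconstruction_sp=float(recon_sp), pairwise_sp=float(pair_sp),
    )


def prevalence_table(
    results: list[ModificationResult],
) -> dict[str, dict[str, float]]:
    """Per condition pair, the fraction of each modification form
    (fractions sum to 1)."""
    if not results:
        raise ModificationError("no modification results")
    out: dict[str, dict[str, float]] = {}
    pairs = sorted({r.condition_pair for r in results})
    for pair in pairs:
        sub = [r for r in results if r.condition_pair == pair]
        n = len(sub)
        out[pair] = {
            form: sum(r.form == form for r in sub) / n
            for form in ("merging", "unmatched", "preserved")
        }
    return out
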