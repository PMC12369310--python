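"""Field-synergy matching, across-condition assignment and synergy
clustering.

Similarity between non-negative muscle-space vectors is the scalar product
of their L2-normalized forms (1 = identical direction, 0 = disjoint
support).  Within a condition each muscle field's *preferred synergy* is the
synergy of maximal scalar product; across conditions, sets of fields or
synergies are put in one-to-one correspondence by maximizing the total
scalar product (optimal assignment).  Synergies pooled across animals are
grouped by k-means, with the cluster count chosen at the first local
maximum of the mean silhouette over k = 2..10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .spta import MuscleField
from .synergies import SynergySet


class MatchingError(ValueError):
    pass


@dataclass
class MatchResult:
    """Preferred field-synergy pairs within one condition."""

    condition: str
    unit_ids: list[str]
    similarity: np.ndarray            # [n_fields, n_synergies]
    preferred_synergy: dict[str, int]
    preferred_sp: dict[str, float]


@dataclass
class Assignment:
    """One-to-one across-condition match maximizing total scalar product."""

    pairs: list[tuple[int, int]]      # (index in A, index in B)
    pair_sp: list[float]
    mean_sp: float


@dataclass
class ClusterResult:
    k_selected: int
    labels: np.ndarray                # 1-based cluster ids
    silhouette_by_k: dict[int, float]


def scalar_product(u: np.ndarray, v: np.ndarray) -> float:
    """Scalar product of two L2-normalized non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise MatchingError("scalar product of a zero vector is undefined")
    return float(u @ v / (nu * nv))


def similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise scalar products between columns of A and columns of B."""
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return An.T @ Bn


def preferred_pairs(
    fields: list[MuscleField], synergy_set: SynergySet
) -> MatchResult:
    """Each field's preferred synergy = argmax scalar product (ties to the
    lowest index); invalid (all-zero) fields are excluded."""
    valid = [f for f in fields if f.valid]
    if not valid:
        raise MatchingError("no valid muscle fields to match")
    F = np.column_stack([f.values for f in valid])
    S = similarity_matrix(F, synergy_set.W)
    preferred = {f.unit_id: int(np.argmax(S[i])) for i, f in enumerate(valid)}
    return MatchResult(
        condition=synergy_set.condition,
        unit_ids=[f.unit_id for f in valid],
        similarity=S,
        preferred_synergy=preferred,
        preferred_sp={f.unit_id: float(S[i].max())
                      for i, f in enumerate(valid)},
    )


def match_across_conditions(set_A: np.ndarray, set_B: np.ndarray) -> Assignment:
    """Optimal one-to-one assignment between two sets of muscle-space
    vectors (columns), maximizing the total scalar product; when sizes
    differ the smaller set is fully assigned."""
    if set_A.size == 0 or set_B.size == 0:
        raise MatchingError("cannot match empty sets")
    S = similarity_matrix(set_A, set_B)
    rows, cols = linear_sum_assignment(-S)
    sps = [float(S[r, c]) for r, c in zip(rows, cols)]
    return Assignment(
        pairs=list(zip(rows.tolist(), cols.tolist())),
        pair_sp=sps,
        mean_sp=float(np.mean(sps)),
    )


def brute_force_assignment(set_A: np.ndarray, set_B: np.ndarray) -> Assignment:
    """Exhaustive-permutation reference for small sets (oracle for tests)."""
    S = similarity_matrix(set_A, set_B)
    nA, nB = S.shape
    best = None
    if nA <= nB:
        for perm in permutations(range(nB), nA):
            total = sum(S[i, p] for i, p in enumerate(perm))
            if best is None or total > best[0]:
                best = (total, list(enumerate(perm)))
    else:
        for perm in permutations(range(nA), nB):
            total = sum(S[p, j] for j, p in enumerate(perm))
            if best is None or total > best[0]:
                best = (total, [(p, j) for j, p in enumerate(perm)])
    pairs = best[1]
    sps = [float(S[r, c]) for r, c in pairs]
    return Assignment(pairs=pairs, pair_sp=sps, mean_sp=float(np.mean(sps)))


def cluster_synergies(
    synergies: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterResult:
    """k-means over pooled L2-normalized synergies with silhouette-guided
    selection of k.

    For each k (capped at n_synergies - 1) the mean silhouette on Euclidean
    distance is recorded; the selected k is the smallest local maximum of
    the silhouette curve (edges compared one-sided).
    """
    X = np.asarray(synergies, dtype=float).T        # rows = synergies
    n = X.shape[0]
    if n < 3:
        raise MatchingError("need at least 3 synergies to cluster")
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    ks = [k for k in range(k_range[0], k_range[1] + 1) if k <= n - 1]
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, lab))
        labels_by_k[k] = lab
    k_selected = ks[-1]
    for i, k in enumerate(ks):
        left_ok = i == 0 or sil[k] >= sil[ks[i - 1]]
        right_ok = i == len(ks) - 1 or sil[k] >= sil[ks[i + 1]]
        if left_ok and right_ok:
            k_selected = k
            break
    return ClusterResult(
        k_selected=k_selected,
        labels=labels_by_k[k_selected] + 1,
        silhouette_by_k=sil,
    )


def consistency_rate(
    assignment: Assignment, threshold: float = 0.78
) -> float | None:
    """Fraction of matched pairs whose scalar product reaches the
    across-condition consistency threshold."""
    if not assignment.pair_sp:
        return None
    return float(np.mean([sp >= threshold for sp in assignment.pair_sp]))
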