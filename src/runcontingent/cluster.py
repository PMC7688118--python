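"""k-medoids (PAM) clustering of phenology series and cross-year analysis.

The contingent definition lives here: fish-year phenologies are clustered
around k medoid series under the DTW dissimilarity; the medoid of each
cluster is the "centroid" phenology used to classify later-year tracks by
nearest-centroid assignment, and the year-to-year contingency of labels is
tested with a chi-square test.

PAM runs the classical BUILD (greedy, deterministic) then SWAP phases; ties
break toward the lowest index, so clustering a given dissimilarity matrix
is fully deterministic. An optional random-restart mode accepts an RNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dtw import dtw_distance
from .errors import ValidationError

log = logging.getLogger("runcontingent")


@dataclass
class ClusterModel:
    k: int
    dissimilarity: np.ndarray
    medoid_indices: list[int]
    assignments: np.ndarray  # cluster index per series, 0-based
    total_cost: float
    centroids: list[np.ndarray] = field(default_factory=list)


@dataclass
class CrossClassification:
    """Year-1 vs year-2 label contingency over fish classified in both."""

    table: pd.DataFrame
    concordance: float
    chi2: float
    df: int
    p_value: float
    n_shared: int


def dissimilarity_matrix(
    series: list[np.ndarray],
    step_pattern: str = "symmetric2",
    window_size: int | None = None,
) -> np.ndarray:
    """Symmetric DTW distance matrix over equal-length series."""
    lengths = {len(s) for s in series}
    if len(lengths) > 1:
        raise ValidationError(f"series have unequal lengths {sorted(lengths)}")
    n = len(series)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(
                series[i], series[j], step_pattern, window_size, return_path=False
            ).distance
    return D


def _assign(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    assignments = np.argmin(sub, axis=1)  # argmin takes the first (lowest) on ties
    cost = float(sub[np.arange(len(D)), assignments].sum())
    return assignments, cost


def pam_cluster(
    D: np.ndarray,
    k: int = 2,
    rng: np.random.Generator | None = None,
    n_restarts: int = 0,
) -> ClusterModel:
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    BUILD greedily seeds k medoids (first: the point minimising total
    distance to all others; then the point giving the largest cost
    reduction), SWAP exchanges (medoid, non-medoid) pairs while any swap
    lowers total cost. Because steepest-descent SWAP can stall in a local
    optimum even at small n, the search is restarted deterministically with
    every point forced in turn as the first BUILD medoid and the cheapest
    solution kept; the procedure remains fully deterministic for a given
    matrix. With ``n_restarts`` > 0 and an RNG, random initial medoid sets
    are additionally polished by SWAP.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if k > n:
        raise ValidationError(f"k = {k} exceeds number of series n = {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")

    medoids, assignments, cost = _swap(D, _build(D, k))
    for first in range(n):
        m2, a2, c2 = _swap(D, _build(D, k, first=first))
        if c2 < cost - 1e-12:
            medoids, assignments, cost = m2, a2, c2
    if n_restarts and rng is not None:
        for _ in range(n_restarts):
            start = sorted(rng.choice(n, size=k, replace=False).tolist())
            m2, a2, c2 = _swap(D, start)
            if c2 < cost - 1e-12:
                medoids, assignments, cost = m2, a2, c2
    return ClusterModel(
        k=k,
        dissimilarity=D,
        medoid_indices=list(medoids),
        assignments=assignments,
        total_cost=cost,
    )


def _build(D: np.ndarray, k: int, first: int | None = None) -> list[int]:
    n = len(D)
    totals = D.sum(axis=0)
    medoids = [int(np.argmin(totals)) if first is None else int(first)]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.array(
            [
                np.maximum(nearest - D[:, c], 0.0).sum() if c not in medoids else -np.inf
                for c in range(n)
            ]
        )
        chosen = int(np.argmax(gains))  # ties: argmax takes lowest index
        medoids.append(chosen)
        nearest = np.minimum(nearest, D[:, chosen])
    return sorted(medoids)


def _swap(D: np.ndarray, medoids: list[int]):
    n = len(D)
    medoids = list(medoids)
    assignments, cost = _assign(D, medoids)
    improved = True
    while improved:
        improved = False
        best_delta, best_pair = -1e-12, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                _, trial_cost = _assign(D, trial)
                delta = cost - trial_cost
                if delta > best_delta + 1e-12:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is not None and best_delta > 1e-12:
            mi, h = best_pair
            medoids[mi] = h
            medoids.sort()
            assignments, cost = _assign(D, medoids)
            improved = True
    return medoids, assignments, cost


def extract_centroids(model: ClusterModel, series: list[np.ndarray]) -> ClusterModel:
    """Attach each cluster's medoid series verbatim as its centroid."""
    model.centroids = [np.asarray(series[m], dtype=float) for m in model.medoid_indices]
    return model


def classify_to_centroids(
    series: list[np.ndarray],
    centroids: list[np.ndarray],
    step_pattern: str = "symmetric2",
    window_size: int | None = None,
):
    """Nearest-centroid DTW labels for new series.

    Returns (labels, distances, tie_flags); exact ties go to the
    lower-index centroid and are flagged and logged.
    """
    if not centroids:
        raise ValidationError("classify_to_centroids requires >= 1 centroid")
    labels, distances, ties = [], [], []
    for idx, s in enumerate(series):
        d = np.array(
            [
                dtw_distance(s, c, step_pattern, window_size, return_path=False).distance
                for c in centroids
            ]
        )
        lab = int(np.argmin(d))
        tie = bool(np.sum(np.isclose(d, d[lab], rtol=0.0, atol=1e-9)) > 1)
        if tie:
            log.warning("series %d equidistant from centroids; assigned %d", idx, lab)
        labels.append(lab)
        distances.append(float(d[lab]))
        ties.append(tie)
    return np.array(labels), np.array(distances), np.array(ties)


def cross_classify(
    labels_y1: dict[str, int],
    labels_y2: dict[str, int],
    yates: bool = True,
) -> CrossClassification:
    """Contingency of contingent labels across two years for shared fish.

    Concordance is the fraction of shared fish with the same label in both
    years. The chi-square test of independence uses Yates continuity
    correction for 2x2 tables (disable with ``yates=False``).
    """
    shared = sorted(set(labels_y1) & set(labels_y2))
    if not shared:
        raise ValidationError("no fish classified in both years")
    y1 = pd.Series({t: labels_y1[t] for t in shared}, name="year1")
    y2 = pd.Series({t: labels_y2[t] for t in shared}, name="year2")
    cats = sorted(set(y1) | set(y2))
    table = pd.crosstab(y1, y2).reindex(index=cats, columns=cats, fill_value=0)
    concordance = float((y1 == y2).mean())
    if table.shape == (1, 1):
        chi2, p, dof = 0.0, 1.0, 0
    else:
        correction = yates and table.shape == (2, 2)
        res = stats.chi2_contingency(table.to_numpy(), correction=correction)
        chi2, p, dof = float(res[0]), float(res[1]), int(res[2])
    return CrossClassification(
        table=table,
        concordance=concordance,
        chi2=chi2,
        df=dof,
        p_value=p,
        n_shared=len(shared),
    )
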