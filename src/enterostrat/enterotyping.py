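"""Enterotype identification.

Community profiles are collapsed to genus level, converted to relative
abundance, and compared by the (root) Jensen-Shannon distance.  Samples are
clustered by partitioning around medoids (PAM) for each candidate number of
clusters; the Calinski-Harabasz (CH) index picks the optimum, with the mean
silhouette reported as corroboration.  A classical-scaling PCoA supports
ordination of any distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

from .core_io import CountTable, TaxonomyMap, collapse_rank, to_relative

__all__ = [
    "EnterotypeAssignment",
    "PCoAResult",
    "jensen_shannon_distance",
    "jsd_matrix",
    "pam_cluster",
    "calinski_harabasz",
    "select_enterotypes",
    "pcoa",
]


def _n_combos(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _combinations(n: int, k: int):
    import itertools

    return itertools.combinations(range(n), k)


def _entropy(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in nats with the 0*log(0) = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(x > 0, x * np.log(x), 0.0)
    return -t.sum(axis=axis)


def jensen_shannon_distance(p, q, sqrt: bool = True) -> float:
    """Jensen-Shannon distance between two probability vectors.

    Computes ``JSD = H(M) - (H(p) + H(q))/2`` with ``M = (p+q)/2`` and
    natural-log entropies; returns ``sqrt(JSD)`` by default (the metric form).
    Zero entries need no smoothing: the divergence is finite as is.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be nonnegative")
    for name, v in (("p", p), ("q", q)):
        if not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
    m = 0.5 * (p + q)
    jsd = float(_entropy(m) - 0.5 * (_entropy(p) + _entropy(q)))
    jsd = max(jsd, 0.0)  # clip eps-scale negatives from cancellation
    return float(np.sqrt(jsd)) if sqrt else jsd


def jsd_matrix(relabund: pd.DataFrame, sqrt: bool = True) -> DistanceMatrix:
    """All-pairs Jensen-Shannon distances for a samples x taxa relative table."""
    x = relabund.to_numpy(dtype=float)
    n = x.shape[0]
    h = _entropy(x, axis=1)
    d = np.zeros((n, n))
    for i in range(n - 1):
        m = 0.5 * (x[i][None, :] + x[i + 1:])
        jsd = _entropy(m, axis=1) - 0.5 * (h[i] + h[i + 1:])
        d[i, i + 1:] = d[i + 1:, i] = np.maximum(jsd, 0.0)
    if sqrt:
        d = np.sqrt(d)
    return DistanceMatrix(d, ids=list(relabund.index))


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------


def pam_cluster(
    dm: DistanceMatrix, k: int, exact: bool | str = "auto"
) -> tuple[np.ndarray, list[str], float]:
    """Partitioning around medoids, deterministic.

    For small search spaces (roughly ``C(n, k) * n <= 2e6``, which covers
    k = 2 up to about 200 samples) every medoid set is enumerated, so the
    returned clustering is the global optimum; larger problems use the
    classical BUILD + SWAP local search, whose occasional sub-optimal local
    minima are a property of PAM itself (the reference R implementation
    lands in the same ones).  Ties everywhere break toward the lowest
    sample index.  Returns ``(labels, medoid_ids, total_cost)`` with labels
    in ``1..k`` ordered by medoid position.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_samples ({n}), got {k}")

    if exact == "auto":
        exact = _n_combos(n, k) * n <= 2_000_000
    if exact:
        best_cost, best_meds = np.inf, None
        for combo in _combinations(n, k):
            cost = d[:, combo].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_meds = cost, combo
        medoids = sorted(best_meds)
        labels = np.argmin(d[:, medoids], axis=1) + 1
        ids = list(dm.ids)
        return labels, [ids[m] for m in medoids], float(best_cost)

    # BUILD: greedy cost reduction, first medoid minimizes total distance
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
        nearest = np.minimum(nearest, d[:, medoids[-1]])

    def cost_of(meds: Sequence[int]) -> float:
        return float(d[:, list(meds)].min(axis=1).sum())

    cost = cost_of(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        med_sorted = sorted(medoids)
        non_med = [h for h in range(n) if h not in medoids]
        for mi in med_sorted:
            others = [m for m in medoids if m != mi]
            rest = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in non_med:
                new_cost = float(np.minimum(rest, d[:, h]).sum())
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids = [h if m == mi else m for m in medoids]
            new_cost = cost_of(medoids)
            assert new_cost <= cost + 1e-9, "SWAP must not increase cost"
            cost = new_cost
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1) + 1
    ids = list(dm.ids)
    return labels, [ids[m] for m in medoids], cost


def calinski_harabasz(dm: DistanceMatrix, labels: Sequence[int]) -> float:
    """Distance-based CH index.

    Uses the sum-of-squares identity ``W = sum_c (1/2n_c) sum_{i,j in c}
    d_ij^2`` and ``T = (1/2n) sum_{i,j} d_ij^2`` so the statistic equals the
    classical centroid-based CH whenever the distances are Euclidean.
    """
    d2 = np.asarray(dm.data, dtype=float) ** 2
    labels = np.asarray(labels)
    n = d2.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    w = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            raise ValueError(f"empty cluster {c}")
        w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    t = d2.sum() / (2.0 * n)
    b = t - w
    if w <= 0:
        return float("inf")
    return float((b / (k - 1)) / (w / (n - k)))


# ---------------------------------------------------------------------------
# Enterotype selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnterotypeAssignment:
    """Cluster labels plus the model-selection profile over candidate k."""

    labels: pd.Series  # sample_id -> cluster in 1..chosen_k (1 = largest)
    medoids: list[str]
    ch_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    chosen_k: int

    def group_ids(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def select_enterotypes(
    ct: CountTable,
    tax: TaxonomyMap | None,
    k_range: Iterable[int] = range(2, 7),
    sqrt_jsd: bool = True,
    rank: str | None = "genus",
) -> EnterotypeAssignment:
    """Genus-level JSD + PAM + CH enterotype assignment.

    ``chosen_k`` maximizes the CH index (ties to the smaller k).  Cluster 1
    is the largest cluster (ties broken by medoid sample order), matching the
    convention of naming the major enterotype first.
    """
    table = collapse_rank(ct, tax, rank) if (tax is not None and rank) else ct
    rel = to_relative(table)
    dm = jsd_matrix(rel, sqrt=sqrt_jsd)

    ch_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    results: dict[int, tuple[np.ndarray, list[str]]] = {}
    for k in sorted(k_range):
        labels, medoids, _ = pam_cluster(dm, k)
        ch_by_k[k] = calinski_harabasz(dm, labels)
        sil_by_k[k] = float(
            silhouette_score(dm.data, labels, metric="precomputed")
        )
        results[k] = (labels, medoids)

    chosen_k = min(ch_by_k, key=lambda k: (-ch_by_k[k], k))
    labels, medoids = results[chosen_k]

    # rename clusters by descending size; ties by original (medoid) order
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    order = sorted(sizes, key=lambda c: (-sizes[c], c))
    rename = {old: new + 1 for new, old in enumerate(order)}
    new_labels = pd.Series(
        [rename[c] for c in labels], index=list(dm.ids), name="enterotype"
    )
    new_medoids = [medoids[c - 1] for c in order]
    return EnterotypeAssignment(new_labels, new_medoids, ch_by_k, sil_by_k, chosen_k)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    The doubly centred Gram matrix ``-0.5 J D^2 J`` is eigendecomposed;
    coordinates use positive eigenvalues only, while negative eigenvalues
    remain visible in ``eigenvalues``.  Each axis's sign is fixed so its
    largest-magnitude coordinate is positive.
    """
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    gram = 0.5 * (gram + gram.T)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for a in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    if n_axes is not None:
        coords = coords[:, :n_axes]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        evals,
        prop,
    )
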