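"""Dynamic connectivity states: k-means decomposition and summaries.

All subjects' windowed connectivity vectors are pooled and clustered with
k-means (squared Euclidean distance, k-means++ restarts).  The number of
states is chosen by an elbow criterion on a cluster validity index — the
ratio of mean within-cluster dispersion to mean between-centroid distance,
computed for k = 2..9 — formalized as the k with the largest discrete
second difference of the curve (greatest curvature).  Each subject's
windows within a state are averaged into a representative state matrix;
states a subject never enters have no representative for that subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = tuple(range(2, 10))


@dataclass
class StateModel:
    """Fitted state decomposition of a cohort's windowed connectivity."""

    k: int
    #: k x P centroid matrix
    centroids: np.ndarray
    #: subject_id -> per-window state labels (aligned with window_starts)
    labels: dict[str, np.ndarray]
    #: per-state fraction of all windows (sums to 1)
    occupancy: np.ndarray
    #: per-state number of subjects with >= 1 window in the state
    subject_counts: np.ndarray
    #: subject_id -> {state: mean P-vector over that subject's windows in state}
    subject_state_means: dict[str, dict[int, np.ndarray]]
    #: k -> validity index, when selected by elbow (else empty)
    validity_curve: dict[int, float] = field(default_factory=dict)
    #: how k was chosen: "elbow" or "pinned"
    k_source: str = "pinned"

    def roster(self, state: int) -> list[str]:
        """Subjects that visited ``state``."""
        return [sid for sid, m in self.subject_state_means.items() if state in m]


def _kmeans_l1(
    data: np.ndarray, k: int, seed: int, n_replicates: int, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd-style k-medians (L1 distance, per-coordinate median centroids)."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        centroids = data[rng.choice(len(data), size=k, replace=False)].copy()
        labels = np.zeros(len(data), dtype=int)
        for _ in range(max_iter):
            dist = np.abs(data[:, None, :] - centroids[None]).sum(axis=2)
            new_labels = dist.argmin(axis=1)
            for j in range(k):
                members = data[new_labels == j]
                if len(members) == 0:  # re-seed empty cluster from farthest point
                    far = dist.min(axis=1).argmax()
                    centroids[j] = data[far]
                    new_labels[far] = j
                else:
                    centroids[j] = np.median(members, axis=0)
            if (new_labels == labels).all():
                labels = new_labels
                break
            labels = new_labels
        cost = np.abs(data - centroids[labels]).sum()
        if best is None or cost < best[2]:
            best = (centroids, labels, cost)
    return best


def kmeans_states(
    all_windows: np.ndarray,
    k: int,
    seed: int = 0,
    n_replicates: int = 10,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster pooled window vectors into ``k`` states.

    Squared-Euclidean k-means with k-means++ initialization and
    ``n_replicates`` restarts, keeping the lowest within-cluster sum of
    squares; deterministic given ``seed``.  ``metric="l1"`` switches to a
    k-medians variant.
    """
    data = np.asarray(all_windows, dtype=float)
    if data.shape[0] < k:
        raise ValueError(f"cannot fit {k} states to {data.shape[0]} windows")
    if metric == "l1":
        centroids, labels, _ = _kmeans_l1(data, k, seed, n_replicates)
        return centroids, labels
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_replicates,
        random_state=seed,
        algorithm="lloyd",
    ).fit(data)
    return km.cluster_centers_, km.labels_


def cluster_validity_index(
    all_windows: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> float:
    """Mean within-cluster dispersion over mean between-centroid distance.

    Within-cluster dispersion is the mean Euclidean distance of points to
    their own centroid; the between term is the mean pairwise distance
    among centroids.  Lower is better; 0 for perfectly tight clusters.
    """
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("validity index undefined for k < 2")
    within = np.linalg.norm(all_windows - centroids[labels], axis=1).mean()
    iu, ju = np.triu_indices(k, k=1)
    between = np.linalg.norm(centroids[iu] - centroids[ju], axis=1).mean()
    return float(within / between)


def elbow_from_curve(curve: dict[int, float]) -> int:
    """k maximizing the discrete second difference of the validity curve.

    Ties go to the smallest k.  Candidate ks must not worsen the index
    relative to the smallest k in the range: an "elbow" on a curve that
    has already risen above its starting value is noise, not structure.
    If no candidate has positive curvature (monotone-linear, flat, or
    rising curve — no elbow), the smallest k is returned with a warning.
    """
    ks = sorted(curve)
    if len(ks) < 3:
        logger.warning("validity curve too short for elbow detection; using smallest k")
        return ks[0]
    second = {
        k: curve[prev] - 2.0 * curve[k] + curve[nxt]
        for prev, k, nxt in zip(ks[:-2], ks[1:-1], ks[2:])
    }
    candidates = {
        k: s for k, s in second.items() if s > 0 and curve[k] <= curve[ks[0]]
    }
    if not candidates:
        logger.warning("no elbow in validity curve; falling back to smallest k")
        return ks[0]
    return min(candidates, key=lambda k: (-candidates[k], k))


def elbow_select_k(
    all_windows: np.ndarray,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
    n_replicates: int = 10,
    metric: str = "euclidean",
) -> tuple[int, dict[int, float]]:
    """Run k-means over ``k_range`` and pick k by the elbow criterion.

    Returns the selected k together with the full validity curve.
    """
    curve: dict[int, float] = {}
    for k in k_range:
        centroids, labels = kmeans_states(
            all_windows, k, seed=seed, n_replicates=n_replicates, metric=metric
        )
        curve[k] = cluster_validity_index(all_windows, labels, centroids)
    return elbow_from_curve(curve), curve


def summarize_states(
    vectors_by_subject: dict[str, np.ndarray],
    labels_by_subject: dict[str, np.ndarray],
    k: int,
) -> tuple[np.ndarray, np.ndarray, dict[str, dict[int, np.ndarray]]]:
    """Occupancy, subject counts, and per-subject representative matrices.

    Occupancy is the global frequency of each state over all windows;
    subject counts tally subjects with at least one window in the state;
    each representative is the mean of the subject's windows in the state
    (absent for unvisited states).
    """
    counts = np.zeros(k)
    subject_counts = np.zeros(k, dtype=int)
    means: dict[str, dict[int, np.ndarray]] = {}
    for sid, vecs in vectors_by_subject.items():
        labels = labels_by_subject[sid]
        means[sid] = {}
        for s in np.unique(labels):
            s = int(s)
            mask = labels == s
            counts[s] += mask.sum()
            subject_counts[s] += 1
            means[sid][s] = vecs[mask].mean(axis=0)
    occupancy = counts / counts.sum()
    return occupancy, subject_counts, means


def fit_state_model(
    vectors_by_subject: dict[str, np.ndarray],
    k: int | None = None,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
    n_replicates: int = 10,
    metric: str = "euclidean",
    fisher_z: bool = False,
) -> StateModel:
    """Pool windows, (optionally) pick k by elbow, cluster, and summarize.

    ``fisher_z`` applies arctanh to the window vectors before clustering
    (centroids are reported back on the correlation scale via tanh).
    """
    sids = list(vectors_by_subject)
    stacked = np.vstack([vectors_by_subject[sid] for sid in sids])
    data = np.arctanh(np.clip(stacked, -1 + 1e-12, 1 - 1e-12)) if fisher_z else stacked
    curve: dict[int, float] = {}
    if k is None:
        k, curve = elbow_select_k(
            data, k_range=k_range, seed=seed, n_replicates=n_replicates, metric=metric
        )
        source = "elbow"
    else:
        source = "pinned"
    centroids, flat_labels = kmeans_states(
        data, k, seed=seed, n_replicates=n_replicates, metric=metric
    )
    if fisher_z:
        centroids = np.tanh(centroids)
    labels: dict[str, np.ndarray] = {}
    pos = 0
    for sid in sids:
        n = len(vectors_by_subject[sid])
        labels[sid] = flat_labels[pos : pos + n]
        pos += n
    occupancy, subject_counts, means = summarize_states(
        vectors_by_subject, labels, k
    )
    return StateModel(
        k=k,
        centroids=centroids,
        labels=labels,
        occupancy=occupancy,
        subject_counts=subject_counts,
        subject_state_means=means,
        validity_curve=curve,
        k_source=source,
    )


# ---------------------------------------------------------------------------
# evaluation helpers against simulation ground truth


def windowed_majority_labels(
    timepoint_labels: np.ndarray, window_starts: np.ndarray, taper: np.ndarray
) -> np.ndarray:
    """Taper-weighted majority latent state for each window."""
    k = int(timepoint_labels.max()) + 1
    out = np.empty(len(window_starts), dtype=int)
    for w, start in enumerate(window_starts):
        seg = timepoint_labels[start : start + len(taper)]
        weight = np.bincount(seg, weights=taper, minlength=k)
        out[w] = int(weight.argmax())
    return out


def best_permutation_accuracy(
    truth: np.ndarray, predicted: np.ndarray, k: int
) -> tuple[float, dict[int, int]]:
    """Label agreement after the best state relabeling (Hungarian matching).

    Returns (accuracy, mapping predicted_state -> truth_state).
    """
    confusion = np.zeros((k, k))
    for t, p in zip(truth, predicted):
        confusion[p, t] += 1
    rows, cols = linear_sum_assignment(-confusion)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    acc = confusion[rows, cols].sum() / len(truth)
    return float(acc), mapping
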