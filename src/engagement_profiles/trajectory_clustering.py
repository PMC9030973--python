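"""K-means clustering for joint 2D engagement trajectories.

Partitions users by Euclidean distance over their joint (therapy, social)
weekly-score trajectories — each user is a 2 x W matrix, flattened to a
2W-vector; both dimensions share the 1-4 ordinal scale so no rescaling is
applied.  The fitting strategy follows the kml3d family: Lloyd iterations
restarted many times while cycling through several initialization schemes,
keeping the restart with minimal within-cluster inertia.

Model selection over a small range of K combines three nonparametric
cluster-validity indices — Calinski–Harabasz (higher is better), Ray–Turi
and Davies–Bouldin (lower is better) — with an exclusion rule for solutions
containing clusters below a minimum size, and subsample-resampling stability
quantified by the Rand index against the full-data partition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .activity_engagement import TrajectoryMatrix

INIT_SCHEMES = ("random_partition", "sample", "farthest_first")


# ---------------------------------------------------------------------------
# Distances and core k-means
# ---------------------------------------------------------------------------

def joint_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two joint trajectories (flattened)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a.ravel() - b.ravel()))


def _as_flat(X) -> np.ndarray:
    if isinstance(X, TrajectoryMatrix):
        return X.flattened().astype(float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError("expected (n, 2, W) or (n, d) array or TrajectoryMatrix")
    return X


@dataclass
class ClusterSolution:
    """One fitted partition: labels, centroids and fit bookkeeping."""

    k: int
    labels: np.ndarray  # (n,) ints in 0..k-1
    centroids: np.ndarray  # (k, 2, W) — or (k, d) for generic input
    inertia: float
    n_per_cluster: np.ndarray
    converged: bool
    best_of: int
    users: list[str] | None = None

    def centroid_matrix(self) -> np.ndarray:
        return self.centroids.reshape(self.k, -1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "labels": (
                dict(zip(self.users, map(int, self.labels)))
                if self.users
                else [int(x) for x in self.labels]
            ),
            "centroids": self.centroids.tolist(),
            "inertia": self.inertia,
            "n_per_cluster": [int(x) for x in self.n_per_cluster],
            "converged": self.converged,
            "best_of": self.best_of,
        }


def _init_centroids(flat: np.ndarray, k: int, scheme: str, rng: np.random.Generator):
    n = flat.shape[0]
    if scheme == "random_partition":
        # random labels with every cluster nonempty; centroid = cluster mean
        labels = rng.integers(k, size=n)
        labels[rng.choice(n, size=k, replace=False)] = np.arange(k)
        return np.stack([flat[labels == j].mean(axis=0) for j in range(k)])
    if scheme == "sample":
        return flat[rng.choice(n, size=k, replace=False)].copy()
    if scheme == "farthest_first":
        centroids = [flat[rng.integers(n)]]
        d2 = ((flat - centroids[0]) ** 2).sum(axis=1)
        for _ in range(1, k):
            centroids.append(flat[int(np.argmax(d2))])
            d2 = np.minimum(d2, ((flat - centroids[-1]) ** 2).sum(axis=1))
        return np.stack(centroids)
    raise ValueError(f"unknown initialization scheme {scheme!r}")


def _lloyd(flat: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations with farthest-point repair for empty clusters.

    Returns (labels, centroids, inertia, converged, inertia_history); the
    inertia history is non-increasing by construction of the two half-steps.
    """
    k = centroids.shape[0]
    labels = np.full(flat.shape[0], -1)
    history = []
    converged = False
    for _ in range(max_iter):
        d2 = ((flat[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        own = d2[np.arange(len(flat)), new_labels]
        for j in range(k):  # empty-cluster repair keeps k fixed
            if not (new_labels == j).any():
                far = int(np.argmax(own))
                new_labels[far] = j
                own[far] = 0.0
        inertia = float(own.sum())
        history.append(inertia)
        if (new_labels == labels).all():
            converged = True
            break
        labels = new_labels
        centroids = np.stack([flat[labels == j].mean(axis=0) for j in range(k)])
    # final inertia under the final centroids
    d2 = ((flat[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(len(flat)), labels].sum())
    return labels, centroids, inertia, converged, history


def joint_kmeans(
    X,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 0.0,
) -> ClusterSolution:
    """Multi-restart k-means on joint trajectories; best restart by inertia.

    Restarts cycle evenly through three initialization schemes: random
    partition, k sampled users, and greedy farthest-first seeding.
    """
    flat = _as_flat(X)
    n = flat.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    users = X.users if isinstance(X, TrajectoryMatrix) else None

    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    best = None
    for scheme, _ in zip(itertools.cycle(INIT_SCHEMES), range(n_restarts)):
        centroids0 = _init_centroids(flat, k, scheme, rng)
        labels, centroids, inertia, converged, hist = _lloyd(
            flat, centroids0, max_iter, tol
        )
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centroids, inertia, converged)
    labels, centroids, inertia, converged = best
    shape = (k,) + (X.values.shape[1:] if isinstance(X, TrajectoryMatrix) else (flat.shape[1],))
    return ClusterSolution(
        k=k,
        labels=labels,
        centroids=centroids.reshape(shape),
        inertia=inertia,
        n_per_cluster=np.bincount(labels, minlength=k),
        converged=converged,
        best_of=n_restarts,
        users=users,
    )


# ---------------------------------------------------------------------------
# Cluster-validity indices
# ---------------------------------------------------------------------------

def _check_partition(flat: np.ndarray, labels: np.ndarray, k: int) -> None:
    if k < 2:
        raise ValueError("indices undefined for k < 2")
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise ValueError("empty cluster: validity indices undefined")


def _scatter(flat, labels, k):
    centroids = np.stack([flat[labels == j].mean(axis=0) for j in range(k)])
    grand = flat.mean(axis=0)
    within = sum(
        float(((flat[labels == j] - centroids[j]) ** 2).sum()) for j in range(k)
    )
    counts = np.bincount(labels, minlength=k)
    between = float((counts * ((centroids - grand) ** 2).sum(axis=1)).sum())
    return centroids, within, between, counts


def calinski_harabasz(X, solution: ClusterSolution) -> float:
    """CH = [B / (k-1)] / [W / (n-k)]: between/within dispersion ratio."""
    flat = _as_flat(X)
    k, labels = solution.k, solution.labels
    _check_partition(flat, labels, k)
    _, within, between, _ = _scatter(flat, labels, k)
    n = flat.shape[0]
    if within == 0.0:
        raise ValueError("zero within-cluster dispersion: CH undefined")
    return (between / (k - 1)) / (within / (n - k))


def ray_turi(X, solution: ClusterSolution) -> float:
    """Mean within-cluster squared distance over min squared centroid gap."""
    flat = _as_flat(X)
    k, labels = solution.k, solution.labels
    _check_partition(flat, labels, k)
    centroids, within, _, _ = _scatter(flat, labels, k)
    n = flat.shape[0]
    min_gap = min(
        float(((centroids[i] - centroids[j]) ** 2).sum())
        for i in range(k)
        for j in range(i + 1, k)
    )
    if min_gap == 0.0:
        raise ValueError("coincident centroids: Ray-Turi undefined")
    return (within / n) / min_gap


def davies_bouldin(X, solution: ClusterSolution) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d(c_i, c_j) ratio.

    s_i is the mean member-to-centroid Euclidean distance within cluster i.
    """
    flat = _as_flat(X)
    k, labels = solution.k, solution.labels
    _check_partition(flat, labels, k)
    centroids = np.stack([flat[labels == j].mean(axis=0) for j in range(k)])
    s = np.array(
        [
            float(np.linalg.norm(flat[labels == j] - centroids[j], axis=1).mean())
            for j in range(k)
        ]
    )
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if j == i:
                continue
            gap = float(np.linalg.norm(centroids[i] - centroids[j]))
            if gap == 0.0:
                raise ValueError("coincident centroids: Davies-Bouldin undefined")
            worst = max(worst, (s[i] + s[j]) / gap)
        total += worst
    return total / k


@dataclass
class FitIndexReport:
    k: int
    calinski_harabasz: float
    ray_turi: float
    davies_bouldin: float
    excluded: bool = False
    exclusion_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "calinski_harabasz": self.calinski_harabasz,
            "ray_turi": self.ray_turi,
            "davies_bouldin": self.davies_bouldin,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }


# ---------------------------------------------------------------------------
# Rand index and stability
# ---------------------------------------------------------------------------

def rand_index(labels_a, labels_b) -> float:
    """Plain (unadjusted) Rand index between two partitions of one set.

    Fraction of element pairs that are co-clustered in both partitions or
    separated in both; 1 iff the partitions are identical up to relabeling.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two elements")
    _, a_codes = np.unique(a, return_inverse=True)
    _, b_codes = np.unique(b, return_inverse=True)
    contingency = np.zeros((a_codes.max() + 1, b_codes.max() + 1))
    np.add.at(contingency, (a_codes, b_codes), 1)

    def comb2(x):
        return (x * (x - 1) / 2.0).sum()

    total = n * (n - 1) / 2.0
    both_same = comb2(contingency)
    same_a = comb2(contingency.sum(axis=1))
    same_b = comb2(contingency.sum(axis=0))
    return float((total + 2 * both_same - same_a - same_b) / total)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index (expected value 0 for random partitions)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    _, a_codes = np.unique(a, return_inverse=True)
    _, b_codes = np.unique(b, return_inverse=True)
    contingency = np.zeros((a_codes.max() + 1, b_codes.max() + 1))
    np.add.at(contingency, (a_codes, b_codes), 1)

    def comb2(x):
        return (x * (x - 1) / 2.0).sum()

    sum_ij = comb2(contingency)
    sum_a = comb2(contingency.sum(axis=1))
    sum_b = comb2(contingency.sum(axis=0))
    total = n * (n - 1) / 2.0
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class StabilityReport:
    k: int
    rand_scores: np.ndarray
    ari_scores: np.ndarray
    mean_rand: float
    mean_ari: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "rand_scores": [float(x) for x in self.rand_scores],
            "ari_scores": [float(x) for x in self.ari_scores],
            "mean_rand": self.mean_rand,
            "mean_ari": self.mean_ari,
        }


def stability(
    X,
    k: int,
    n_resamples: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    n_restarts: int = 20,
    reference: ClusterSolution | None = None,
) -> StabilityReport:
    """Subsample-resampling stability of a k-cluster solution.

    Each resample reclusters ``frac`` of the users (drawn without
    replacement) and scores agreement — Rand index, ARI additionally
    logged — between the resample partition and the full-data reference
    partition restricted to the drawn users.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    flat = _as_flat(X)
    n = flat.shape[0]
    if reference is None:
        reference = joint_kmeans(X, k, n_restarts=max(n_restarts, 50), seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, k, 0x57AB]))
    m = max(k + 1, int(round(frac * n)))
    rand_scores = np.empty(n_resamples)
    ari_scores = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        sub = joint_kmeans(
            flat[idx], k, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        rand_scores[r] = rand_index(reference.labels[idx], sub.labels)
        ari_scores[r] = adjusted_rand_index(reference.labels[idx], sub.labels)
    return StabilityReport(
        k=k,
        rand_scores=rand_scores,
        ari_scores=ari_scores,
        mean_rand=float(rand_scores.mean()),
        mean_ari=float(ari_scores.mean()),
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Full model-selection audit trail over the candidate range of K."""

    chosen_k: int | None
    chosen: ClusterSolution | None
    solutions: dict[int, ClusterSolution]
    fit_indices: dict[int, FitIndexReport]
    stability_reports: dict[int, StabilityReport]
    votes: dict[int, int] = field(default_factory=dict)
    rationale: str = ""

    def to_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "chosen": self.chosen.to_dict() if self.chosen else None,
            "solutions": {k: s.to_dict() for k, s in self.solutions.items()},
            "fit_indices": {k: r.to_dict() for k, r in self.fit_indices.items()},
            "stability": {k: r.to_dict() for k, r in self.stability_reports.items()},
            "votes": self.votes,
            "rationale": self.rationale,
        }


def select_solution(
    X,
    k_range=range(2, 5),
    min_cluster_size: int = 15,
    n_restarts: int = 100,
    n_resamples: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    stability_restarts: int = 20,
) -> SelectionReport:
    """Fit each candidate K, score it, exclude small-cluster solutions and
    pick the winner by index majority vote.

    Solutions with any cluster below ``min_cluster_size`` members are
    excluded.  Each of the three validity indices casts one vote for its
    best admissible K (CH highest; Ray–Turi and Davies–Bouldin lowest);
    ties break by higher mean stability Rand index.  If every K is
    excluded the report says so explicitly and ``chosen_k`` is None.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    solutions: dict[int, ClusterSolution] = {}
    fit_indices: dict[int, FitIndexReport] = {}
    stab: dict[int, StabilityReport] = {}
    for k in ks:
        sol = joint_kmeans(X, k, n_restarts=n_restarts, seed=seed)
        solutions[k] = sol
        report = FitIndexReport(
            k=k,
            calinski_harabasz=calinski_harabasz(X, sol),
            ray_turi=ray_turi(X, sol),
            davies_bouldin=davies_bouldin(X, sol),
        )
        small = int(sol.n_per_cluster.min())
        if small < min_cluster_size:
            report.excluded = True
            report.exclusion_reason = (
                f"smallest cluster has {small} members (< {min_cluster_size})"
            )
        fit_indices[k] = report
        stab[k] = stability(
            X,
            k,
            n_resamples=n_resamples,
            frac=frac,
            seed=seed,
            n_restarts=stability_restarts,
            reference=sol,
        )

    admissible = [k for k in ks if not fit_indices[k].excluded]
    votes = {k: 0 for k in admissible}
    if admissible:
        best_ch = max(admissible, key=lambda k: fit_indices[k].calinski_harabasz)
        best_rt = min(admissible, key=lambda k: fit_indices[k].ray_turi)
        best_db = min(admissible, key=lambda k: fit_indices[k].davies_bouldin)
        for k in (best_ch, best_rt, best_db):
            votes[k] += 1
        top = max(votes.values())
        leaders = [k for k in admissible if votes[k] == top]
        chosen_k = max(leaders, key=lambda k: stab[k].mean_rand)
    else:
        chosen_k = None

    lines = [
        f"{'k':>3} {'CH':>10} {'Ray-Turi':>10} {'DB':>10} {'meanRand':>9} "
        f"{'minsize':>8} {'status':<28}"
    ]
    for k in ks:
        r = fit_indices[k]
        status = r.exclusion_reason if r.excluded else (
            f"votes={votes.get(k, 0)}" + ("  <- selected" if k == chosen_k else "")
        )
        lines.append(
            f"{k:>3} {r.calinski_harabasz:>10.3f} {r.ray_turi:>10.4f} "
            f"{r.davies_bouldin:>10.4f} {stab[k].mean_rand:>9.4f} "
            f"{int(solutions[k].n_per_cluster.min()):>8} {status:<28}"
        )
    if chosen_k is None:
        lines.append("no admissible solution: every candidate k was excluded")
    rationale = "\n".join(lines)

    return SelectionReport(
        chosen_k=chosen_k,
        chosen=solutions.get(chosen_k),
        solutions=solutions,
        fit_indices=fit_indices,
        stability_reports=stab,
        votes=votes,
        rationale=rationale,
    )
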