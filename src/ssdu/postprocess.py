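"""Cluster-level ranking of a refined ensemble.

The refined ensemble is grouped by the classic greedy neighbor-count rule
used by docking servers: repeatedly take the remaining conformation with
the most remaining neighbors (pairwise distance strictly below a 9 A
threshold), make it a cluster center and remove it with its neighbors, up
to 30 clusters of at least 10 members.  Each cluster is summarized by 9
features (average energy of its top 25/50/75/100% lowest-energy members,
its size, and average distance-to-center of the 25/50/75/100% nearest
members), labeled +1 when its center is of Acceptable-or-better quality,
and ranked by a random forest's positive-class probability.  Performance
is measured as mean out-of-sample AUC over repeated grouped 60/40
train/test splits with positive-class oversampling in the training half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

__all__ = [
    "ClusterRecord",
    "QUALITY_TIERS",
    "greedy_cluster",
    "cluster_features",
    "quality_from_rmsd",
    "label_clusters",
    "train_ranker",
    "rank_and_enrich",
]

QUALITY_TIERS = ("Incorrect", "Acceptable", "Medium", "High")
# synthetic surrogate bands (Angstrom, placement RMSD to the planted truth)
DEFAULT_QUALITY_THRESHOLDS = {"Acceptable": 10.0, "Medium": 5.0, "High": 1.0}


@dataclass
class ClusterRecord:
    """A greedy cluster: members, its center, features, label, probability."""

    members: np.ndarray
    center: int
    features: Optional[np.ndarray] = None
    label: Optional[int] = None
    probability: Optional[float] = None

    @property
    def size(self) -> int:
        return int(self.members.size)


def greedy_cluster(
    D: np.ndarray,
    threshold: float = 9.0,
    max_clusters: int = 30,
    min_size: int = 10,
) -> List[ClusterRecord]:
    """Greedy neighbor-count clustering on a symmetric distance matrix.

    Neighbors are pairs with distance strictly below ``threshold`` (self
    excluded).  At each round the remaining conformation with the most
    remaining neighbors becomes a center (ties: lowest index); it and its
    neighbors form a cluster and are removed.  Stops at ``max_clusters`` or
    when the best candidate would have fewer than ``min_size`` members.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    adj = (D < threshold) & ~np.eye(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    clusters: List[ClusterRecord] = []
    while len(clusters) < max_clusters and alive.any():
        counts = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the first maximum: lowest index
        members = np.flatnonzero(adj[center] & alive)
        members = np.sort(np.append(members, center))
        if members.size < min_size:
            break
        clusters.append(ClusterRecord(members=members, center=center))
        alive[members] = False
    return clusters


def cluster_features(
    cluster: ClusterRecord,
    energies: np.ndarray,
    center_distances: np.ndarray,
) -> np.ndarray:
    """The 9-feature summary of one cluster.

    Features 1-4: mean energy of the ``ceil(p * size)`` lowest-energy
    members for p = 25/50/75/100%; feature 5: cluster size; features 6-9:
    mean distance-to-center of the ``ceil(p * size)`` nearest members (the
    members sorted by increasing distance from the center).
    """
    energies = np.asarray(energies, dtype=float)[cluster.members]
    dists = np.asarray(center_distances, dtype=float)[cluster.members]
    size = cluster.size
    e_sorted = np.sort(energies)
    d_sorted = np.sort(dists)
    feats = []
    for p in (0.25, 0.5, 0.75, 1.0):
        m = int(np.ceil(p * size))
        feats.append(float(e_sorted[:m].mean()))
    feats.append(float(size))
    for p in (0.25, 0.5, 0.75, 1.0):
        m = int(np.ceil(p * size))
        feats.append(float(d_sorted[:m].mean()))
    out = np.array(feats)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite cluster features")
    cluster.features = out
    return out


def quality_from_rmsd(
    rmsd_to_truth: float,
    thresholds: Optional[Dict[str, float]] = None,
) -> str:
    """CAPRI-like quality tier from placement RMSD to the planted truth.

    Synthetic surrogate for an external model-quality score: High < 1 A,
    Medium < 5 A, Acceptable < 10 A, otherwise Incorrect (configurable).
    """
    th = thresholds or DEFAULT_QUALITY_THRESHOLDS
    if rmsd_to_truth < th["High"]:
        return "High"
    if rmsd_to_truth < th["Medium"]:
        return "Medium"
    if rmsd_to_truth < th["Acceptable"]:
        return "Acceptable"
    return "Incorrect"


def label_clusters(
    clusters: Sequence[ClusterRecord],
    quality_fn: Callable[[int], str],
) -> List[ClusterRecord]:
    """+1 when the center's quality is Acceptable or better, else -1."""
    for cl in clusters:
        q = quality_fn(cl.center)
        if q not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier {q!r}")
        cl.label = 1 if QUALITY_TIERS.index(q) >= 1 else -1
    return list(clusters)


def _grouped_split(groups: np.ndarray, split_frac: float, rng: np.random.Generator):
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    n_train = max(1, int(round(split_frac * uniq.size)))
    train_groups = set(perm[:n_train].tolist())
    train = np.array([g in train_groups for g in groups])
    return train, ~train


def train_ranker(
    features: np.ndarray,
    labels: np.ndarray,
    groups: Optional[np.ndarray] = None,
    split_frac: float = 0.6,
    n_repeats: int = 15,
    seed: int = 0,
    n_estimators: int = 200,
    max_retries: int = 20,
) -> Tuple[RandomForestClassifier, float]:
    """Random-forest ranking with repeated grouped splits and oversampling.

    Splits assign ``split_frac`` of the *groups* (complexes) to training
    and the rest to test; positives are resampled with replacement to
    parity in the training half only.  The per-sample score is the forest's
    positive-class probability (mean over trees of the positive fraction in
    the reached leaf).  Returns a forest refit on the full (oversampled)
    data plus the mean out-of-sample AUC over ``n_repeats`` splits.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be +1/-1")
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    groups = np.arange(len(y)) if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)

    def oversample(Xt, yt, r):
        pos = np.flatnonzero(yt == 1)
        neg = np.flatnonzero(yt == -1)
        if pos.size == 0 or neg.size == 0:
            return None
        minority, majority = (pos, neg) if pos.size < neg.size else (neg, pos)
        extra = r.choice(minority, size=majority.size - minority.size, replace=True) \
            if majority.size > minority.size else np.array([], dtype=int)
        idx = np.concatenate([np.arange(len(yt)), extra])
        return Xt[idx], yt[idx]

    aucs = []
    for rep in range(n_repeats):
        ok = False
        for _try in range(max_retries):
            tr, te = _grouped_split(groups, split_frac, rng)
            if np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2:
                ok = True
                break
        if not ok:
            raise ValueError("could not draw a split with both classes on each side")
        samp = oversample(X[tr], y[tr], rng)
        Xtr, ytr = samp
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(Xtr, ytr)
        prob = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        aucs.append(roc_auc_score((y[te] == 1).astype(int), prob))
    samp = oversample(X, y, rng)
    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    final.fit(*samp)
    return final, float(np.mean(aucs))


def rank_and_enrich(
    clusters: Sequence[ClusterRecord],
    quality_fn: Callable[[int], str],
    k_list: Sequence[int] = (3, 5, 10),
    rank_by: str = "probability",
) -> Dict[int, Dict[str, int]]:
    """Counts of Acceptable/Medium/High-or-better centers among top-k clusters.

    ``rank_by='probability'`` sorts by decreasing positive-class
    probability; ``rank_by='size'`` is the baseline server behavior
    (largest clusters first).  Counts are cumulative tiers: a High center
    counts in all three tiers.
    """
    if rank_by == "probability":
        if any(cl.probability is None for cl in clusters):
            raise ValueError("clusters lack probabilities; run the ranker first")
        order = np.argsort([-cl.probability for cl in clusters], kind="stable")
    elif rank_by == "size":
        order = np.argsort([-cl.size for cl in clusters], kind="stable")
    else:
        raise ValueError("rank_by must be 'probability' or 'size'")
    tiers = {"Acceptable": 1, "Medium": 2, "High": 3}
    out: Dict[int, Dict[str, int]] = {}
    for k in k_list:
        top = [clusters[i] for i in order[:k]]
        counts = {}
        for tier, level in tiers.items():
            counts[tier] = sum(
                1 for cl in top if QUALITY_TIERS.index(quality_fn(cl.center)) >= level
            )
        out[int(k)] = counts
    return out
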