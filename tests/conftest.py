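"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from ssdu.landscape import (
    default_funnel_spec,
    generate_decoy_ensemble,
    make_funnel_landscape,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def single_funnel():
    """A rugged single-funnel landscape with its ground truth and ensemble."""
    spec = default_funnel_spec(n_funnels=1, rho_rug=0.5, p_out=0.1, seed=7)
    model = make_funnel_landscape(spec)
    truth, truth_energy = model.ground_truth()
    ensemble = generate_decoy_ensemble(model, spec, 300, temperature=1.0, seed=7)
    return {"spec": spec, "model": model, "truth": truth,
            "truth_energy": truth_energy, "ensemble": ensemble}


# ---------------------------------------------------------------------------
# Brute-force DBSCAN oracle: density connectivity from first principles.
# ---------------------------------------------------------------------------


def dbscan_oracle(X: np.ndarray, eps: float, n_min: int) -> np.ndarray:
    """Labels by explicit density-connectivity (independent of ssdu.refine).

    Core points = points with >= n_min neighbors within eps (self included).
    Clusters = connected components of the core-core reachability graph.
    Border points join the cluster of the first core point in input order
    that reaches them (the package's documented rule).  Components are
    numbered by their lowest-index core point in input order.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import cdist

    n = X.shape[0]
    D = cdist(X, X)
    within = D <= eps
    core = within.sum(axis=1) >= n_min
    core_idx = np.flatnonzero(core)
    labels = np.full(n, -1, dtype=int)
    if core_idx.size:
        sub = within[np.ix_(core_idx, core_idx)]
        _, comp = connected_components(csr_matrix(sub), directed=False)
        # renumber components by first core point in input order
        seen = {}
        for ci, c in zip(core_idx, comp):
            if c not in seen:
                seen[c] = len(seen)
        for ci, c in zip(core_idx, comp):
            labels[ci] = seen[c]
        for i in range(n):
            if labels[i] == -1:
                for ci in core_idx:
                    if within[ci, i]:
                        labels[i] = labels[ci]
                        break
    return labels


def canonical_partition(labels: np.ndarray):
    """Partition as a frozenset of member-index frozensets plus outlier set."""
    labels = np.asarray(labels)
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == c).tolist())
        for c in np.unique(labels) if c >= 0
    )
    outliers = frozenset(np.flatnonzero(labels == -1).tolist())
    return clusters, outliers


# ---------------------------------------------------------------------------
# Brute-force greedy-clustering oracle.
# ---------------------------------------------------------------------------


def greedy_oracle(D: np.ndarray, threshold: float, max_clusters: int, min_size: int):
    """Re-implementation of the greedy neighbor-count rule, loop-by-loop."""
    n = D.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining and len(clusters) < max_clusters:
        best_center, best_members = None, None
        for i in sorted(remaining):
            members = sorted(
                j for j in remaining if j != i and D[i, j] < threshold
            )
            members = [i] + members
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        if len(best_members) < min_size:
            break
        clusters.append((best_center, sorted(best_members)))
        remaining -= set(best_members)
    return clusters
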