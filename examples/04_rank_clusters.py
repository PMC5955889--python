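"""Cluster a refined ensemble and rank clusters with a random forest.

Greedy neighbor-count clustering (9 A placement-RMSD threshold, up to 30
clusters of >= 10 members), 9 features per cluster, +1/-1 labels from the
cluster center's quality tier against the planted truth, and a random
forest trained with grouped 60/40 splits and positive-class oversampling.
"""

import warnings

import numpy as np

from ssdu import (
    SSDUParams,
    default_funnel_spec,
    generate_decoy_ensemble,
    make_funnel_landscape,
    ssdu_refine,
)
from ssdu.benchmark import placement_rmsd_to_truth, reference_ligand
from ssdu.geometry import place_ligand, rmsd
from ssdu.postprocess import (
    cluster_features,
    greedy_cluster,
    label_clusters,
    quality_from_rmsd,
    rank_and_enrich,
)

spec = default_funnel_spec(n_funnels=1, rho_rug=0.5, p_out=0.1, seed=1)
model = make_funnel_landscape(spec)
truth, _ = model.ground_truth()
ensemble = generate_decoy_ensemble(model, spec, K=300, temperature=1.0, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    refined = ssdu_refine(model, ensemble,
                          SSDUParams(K=300, eps=1.0, n_min=30, k_bar=100, max_iter=2, seed=1))

ligand = reference_ligand(0)
placed = [place_ligand(c, ligand).coords for c in refined]
n = len(refined)
D = np.zeros((n, n))
for i in range(n):
    for j in range(i + 1, n):
        D[i, j] = D[j, i] = rmsd(placed[i], placed[j])

clusters = greedy_cluster(D, threshold=9.0, max_clusters=30, min_size=10)
energies = np.array([c.energy for c in refined])


def quality(center: int) -> str:
    return quality_from_rmsd(placement_rmsd_to_truth(refined[center], truth, ligand))


label_clusters(clusters, quality)
for cl in clusters:
    cluster_features(cl, energies, D[cl.center])

print(f"clusters formed: {len(clusters)}")
for i, cl in enumerate(clusters):
    print(f"  cluster {i}: size {cl.size:3d}, center quality {quality(cl.center):>10}, "
          f"mean top-25% energy {cl.features[0]:.3f}")
counts = rank_and_enrich(clusters, quality, k_list=(3,), rank_by="size")
print(f"quality solutions among top-3 clusters (size ranking): {counts[3]}")
print()
print("Cluster features feed the random-forest ranker (see ssdu.postprocess.")
print("train_ranker); with a single synthetic complex, size ranking is shown.")
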