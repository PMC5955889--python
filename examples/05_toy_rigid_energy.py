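"""Score rigid-body placements with the toy Lennard-Jones + Coulomb energy.

The pluggable energy-model contract also accepts physical point-set models:
here two small synthetic bodies, scored over a range of center-to-center
distances and locally minimized.
"""

import numpy as np

from ssdu import Conformation, EnergyWeights, RigidBody, local_minimize, toy_rigid_energy

rng = np.random.default_rng(0)
receptor = RigidBody(rng.normal(scale=3.0, size=(20, 3)), charges=rng.normal(scale=0.2, size=20))
ligand = RigidBody(rng.normal(scale=2.0, size=(10, 3)), charges=rng.normal(scale=0.2, size=10))

model = toy_rigid_energy(receptor, ligand, EnergyWeights(w_vdw=1.0, w_coul=0.1),
                         lj_epsilon=0.2, lj_sigma=3.5)

print("energy vs center-to-center distance:")
for r in (6.0, 8.0, 10.0, 14.0, 20.0):
    print(f"  r = {r:5.1f} A   E = {model([r, 0, 0, 0, 0, 0]):10.3f}")

start = Conformation(10.0, 0.1, -0.1, 0.2, 0.0, 0.1)
out = local_minimize(model, start)
print(f"\nlocal minimization: E {model(start):.3f} -> {out.energy:.3f} "
      f"at r = {out.r:.2f} A")
print()
print("Close approach is penalized by the soft-core repulsion, far placements")
print("decay to zero, and rigid-body minimization finds a contact distance.")
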