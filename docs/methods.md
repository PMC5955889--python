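# Methods

## Model and procedure

A rigid-body receptor–ligand conformation is parameterized as
ψ = (r, a, b, y₁, y₂, y₃). The receptor is fixed with its centroid at the
origin; the ligand centroid sits at r·n(a, b), where n is the sphere
exponential map anchored at the pole (0, 0, 1): n(a, b) rotates the pole
by angle ‖(a, b)‖ about the axis (−b, a, 0)/‖(a, b)‖. The ligand
orientation is the rotation exp([y]ₓ) (axis y/‖y‖, angle ‖y‖), kept in
the open ball ‖y‖ < π so that PCA over orientations is meaningful. These
conventions are stand-ins for a manifold parameterization whose published
definition is not fully specified; they are fixed package-wide and all
modules share them.

Inside a well-packed low-energy cluster, r varies little, so refinement
operates on x = (a, b, y₁, y₂, y₃) and re-attaches the cluster-mean r̄
when realizing samples. The refinement loop is:

1. **DBSCAN** on x (Euclidean metric, radius ε, minimum population
   N_min). Core points have ≥ N_min neighbors within ε (self included);
   clusters are maximal density-connected sets; remaining points are
   outliers. Border points join the cluster of the first core point in
   input scan order that reaches them — classic DBSCAN leaves border
   assignment order-dependent, and fixing the rule makes runs
   reproducible, which is why the package carries its own ~40-line
   implementation rather than delegating to a library whose scan order
   cannot be pinned.
2. **PCA** per cluster: z = Wᵀ(x − x̄) with columns of W ordered by
   decreasing variance; σᵢ are standard deviations (square roots of
   covariance eigenvalues, the SVD singular-value convention), covariance
   normalized by 1/(K−1), and each column's sign fixed so its
   largest-magnitude entry is positive (reproducibility across
   platforms). φ = (z₁, z₂, z₃) spans the permissive subspace; a config
   flag reduces it to 2. The five coordinates are not standardized before
   PCA by default (they share angular units); a z-scoring flag exists.
3. **Fit set and local minimization**: the ⌈η·size⌉ lowest-energy
   members (ties broken by input order) are locally minimized — L-BFGS-B
   on the 6D parameterization with finite-difference gradients and an
   r > 0 bound; the input is kept whenever the line search cannot improve
   it, so energies never increase. η is interpreted as the fraction of
   lowest-energy cluster members forming the underestimation fit set:
   underestimating the envelope of the best local minima is the intended
   use of the method lineage, and the published definition of η is not
   explicit enough to exclude alternatives, so this reading is documented
   here as a design choice.
4. **SOS-convex underestimation** (the core): a degree-2d polynomial U
   over φ ∈ R³ solves

       min Σᵢ [fᵢ − U(φᵢ)]  s.t.  fᵢ ≥ U(φᵢ) ∀i,  U SOS-convex.

   SOS-convexity requires the Hessian form y'∇²U(φ)y to admit a Gram
   representation v'Gv with G ⪰ 0 over the basis v = {φ^γ yᵢ : deg γ ≤
   d−1}, a sufficient and tractable certificate of convexity. The Gram
   freedom (matrices representing the zero polynomial) is parameterized
   by an orthonormal kernel basis computed once per (n, d) by SVD. Data
   are centered/scaled per coordinate and energies shifted to minimum
   zero and scaled to unit spread before the solve; coefficients are
   back-transformed exactly afterwards, so the preconditioning is
   mathematically invisible. A ridge of 1e-9 on the coefficient norm
   breaks ties in underdetermined fits (allowed with a warning).
5. **Biased sampling**: z* = (φ*, mean z₄, mean z₅) with φ* the
   underestimator minimum (damped Newton; convexity makes any stationary
   point global). k̄ samples perturb z* by independent uniforms in
   (−0.5βσᵢ, 0.5βσᵢ), are mapped back by x = W(z* + s) + x̄, re-attached
   to r̄, and locally minimized.
6. **Merge and filter**: all new conformations join the ensemble and the
   K lowest energies are retained, so the k-th best energy is
   non-increasing in the iteration index for every k.

Stopping: max_iter iterations (default 3) or relative best-energy
improvement below 1e-4, whichever comes first (the published stopping
rule is "until meeting the stopping criteria"; the relative-improvement
floor is this package's concretization).

Side-chain repacking is out of scope: the loop is rigid-body only, and
the energy-model contract is a deterministic scalar f(ψ).

## Parameters

| name | default | meaning |
|---|---|---|
| ε | 1.0 | DBSCAN neighbor radius in reduced coordinates (radians-scale) |
| N_min | 100 (30 at desk scale) | minimum cluster population |
| η | 0.3 | fraction of lowest-energy members in the fit set |
| 2d | 4 | underestimator degree (2, 4, 6 supported) |
| β | 2.0 | resampling half-range in units of 0.5σᵢ per principal coordinate |
| k̄ | K | samples per cluster per iteration |
| max_iter | 3 | iteration cap |
| K | 1000 (300 at desk scale) | ensemble size kept by the energy filter |

ε = 1.0, N_min = 100, η = 0.3, three iterations and k̄ = K follow the
published protocol for K = 1000–1500 ensembles. Experiments in this
package run at desk scale K = 300; N_min is scaled with the same
N_min/K ≈ 0.1 ratio (n_min = 30) so that Boltzmann-weighted secondary
funnels retain enough members to reach the core-point threshold. β has
no published value; 2.0 covers ±1σ per coordinate and is exposed in the
config. Degree 4 is the default because the method's rationale is that
polynomials are more flexible than quadratics, degree 4 is the smallest
even degree where SOS-convexity is a strict relaxation of convexity, and
the problem stays tiny in n = 3 (12×12 Gram).

## The semidefinite solver

No SDP library is part of the dependency set; `ssdu.sdp` is a dense
log-det barrier path-following method for linear matrix inequalities
(blocks F₀ + Σ xₖFₖ ⪰ 0 and elementwise a + Ax ≥ 0, linear-plus-quadratic
objective). The inner loop is damped Newton with the self-concordant step
rule α = 1/(1+λ) for Newton decrement λ ≥ 0.25 and full steps below it —
the decrement is affine-invariant, so no merit-function comparisons are
needed (at barrier weight t ~ 1e9 a merit value of order t·f drowns small
decrements in floating-point noise; an earlier Armijo-based line search
stalled for exactly this reason). Newton systems are Jacobi-scaled before
Cholesky. The barrier weight grows by ×20 per stage until the certified
gap ν/t (ν = total barrier parameter) falls below tolerance (1e-9 on
preconditioned data). Because iterates stay strictly interior, every fit
satisfies the underestimation constraints by construction; the reported
per-sample gaps are recomputed in raw coordinates and checked against the
feasibility tolerance 1e-6.

The strictly feasible start for a fit is U₀ = −1 + δ·Σⱼ‖φ‖^{2j} with δ
small enough that U₀ < f everywhere; its Gram representative is made
strictly positive definite by a phase-I solve maximizing the smallest
eigenvalue over the Gram kernel (the same solver, warm problem). The
same phase-I construction implements `is_sos_convex`: margin ≥ 0 within
tolerance returns the PSD Gram certificate, a negative margin is a
refusal, and solver failure raises distinctly.

## Synthetic landscape and decoy generator

The generator emulates the statistical shape of FFT-sampling output, not
its physics: per funnel j, a quadratic basin dⱼ + (x−cⱼ)'Aⱼ(x−cⱼ) +
k_r(r−rⱼ)² with Aⱼ anisotropic (permissive eigenvalues ~2–2.5,
restrictive 300–400, so every permissive spread is ≥ ~10× every
restrictive spread and three principal components carry >75% of cluster
variance); a deterministic sinusoidal ruggedness ρ·Σᵢ sin(ωᵢxᵢ+φᵢ) with
seed-fixed phases standing in for the dense local-minima structure; and a
min over funnels. Decoys are Gaussian clouds around the funnel centers
with covariance T·Aⱼ⁻¹ (Boltzmann-like occupancy weights e^{−dⱼ/T}
across funnels; r jittered with the Boltzmann variance T/(2k_r) of its
quadratic well — the r law is this package's choice, only the x-law being
prescribed), plus a fraction p_out of uniform outliers in a bounding box.
Defaults: depth −10, funnel depth offsets 0.5, k_r = 50 Å⁻², ρ = 0.5,
p_out = 0.1, r_ref = 25 Å.

What passing tests on this generator do show: the loop finds the global
minimum of a rugged anisotropic multi-funnel surface, respects funnel
identity, and enriches the near-native fraction. What they do not show:
performance under a real force field (multi-frequency terms, clashes,
side-chain coupling), real FFT-sampler biases, or absolute improvement
numbers on experimental complexes — those require an external docking
stack and benchmark set.

The toy rigid-body energy implements only the Lennard-Jones and Coulomb
terms of the weighted-sum docking potential; the knowledge-based terms
(solvation, hydrogen bonding, statistical reference-state and rotamer
potentials) need external parameter databases and are rejected by the
weights type rather than silently ignored. A soft-core floor replaces
rᵢⱼ by max(rᵢⱼ, 0.6σ) in *every* pairwise term: flooring only the r⁻¹²
repulsion would leave the attractive r⁻⁶ divergent inside the core and
the energy unbounded below, defeating both local minimization and
underestimation; flooring all terms realizes the intent (bounded clash
energies) cleanly.

## Post-processing

Greedy neighbor-count clustering on a pairwise placement-RMSD matrix
(strictly below 9 Å, self excluded, ties to the lowest index), at most 30
clusters of at least 10 members. Placement RMSD — no superposition —
is the natural metric between placements of the same ligand and avoids a
Kabsch step inside the distance; it diverges from interface-atom RMSD,
which would require a native interface definition. Percentile feature
counts use ⌈p·size⌉ so the 25% set is never empty. Quality tiers for
synthetic data are placement-RMSD bands against the planted truth
(Acceptable < 10 Å, Medium < 5 Å, High < 1 Å, configurable), standing in
for an external model-quality program. The random forest uses 200 trees
(tree count is not prescribed anywhere; it is a config default, not a
tested constant), grouped 60/40 splits by complex, minority-class
oversampling to parity in the training half only, and mean out-of-sample
AUC over 15 repeats.

Improvement reporting follows two conventions: *average* = mean of
per-case percentage improvements, *total* = percentage improvement of
aggregated counts. Cases with zero counts before and after are removed;
a case with zero before and nonzero after has no defined ratio and is
excluded from the average but kept in the total (the published rule
covers only the double-zero case; this extension is the package's).

## Numerical choices and degenerate inputs

- Feasibility tolerance 1e-6 on underestimation gaps; solver gap 1e-9;
  convexity spot-checks allow −1e-8·(1+‖H‖) on Hessian eigenvalues.
- `minimize_convex` detects unbounded-below polynomials (possible for
  degenerate degree-2 fits with vanishing quadratic part) by iterate
  blow-up and non-stationary termination, and raises with a diagnosis.
- An ensemble of K identical conformations passes through the loop:
  zero-variance PCA is allowed, the underestimator degenerates to a
  constant with an immediate stationary start, and merge-and-filter
  returns the input.
- All randomness flows from one seed; per-(iteration, cluster) child
  seeds come from `SeedSequence(seed, spawn_key=(iteration, cluster))`,
  so results are independent of cluster enumeration order and runs are
  bit-reproducible. Ensemble tables store floats in shortest round-trip
  decimal form, making write/read cycles exact.

## Known limitations

- The exponential-coordinate and tangent-space conventions are fixed
  stand-ins; a different published convention would change coordinates
  but not the algorithm.
- DBSCAN and the pairwise RMSD matrix are O(n²); fine for n ≤ a few
  thousand, the intended ensemble scale.
- The barrier solver is dense and unoptimized beyond Jacobi scaling; it
  is sized for this package's 12–30 dimensional Gram blocks, not for
  general SDP workloads.
- Degree 6 runs through the same code path as 2 and 4 but with a 30×30
  Gram block and a phase-I-found interior start; it is exercised only
  lightly and is not the default.
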