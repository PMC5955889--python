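import numpy as np
import pytest

from ssdu.geometry import RigidBody
from ssdu.landscape import (
    EnergyWeights,
    Funnel,
    FunnelSpec,
    default_funnel_spec,
    generate_decoy_ensemble,
    ground_truth,
    make_funnel_landscape,
    toy_rigid_energy,
)


def simple_funnel(center, depth, lam, seed=0):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
    A = Q @ np.diag(lam) @ Q.T
    return Funnel(center=np.asarray(center, float), r_ref=25.0, depth=depth,
                  curvature=0.5 * (A + A.T))


class TestFunnelLandscape:
    def test_smooth_single_funnel_minimum_at_center(self):
        fn = simple_funnel(np.zeros(5), -5.0, [2, 2, 2, 300, 400])
        model = make_funnel_landscape(FunnelSpec(funnels=[fn], rho_rug=0.0))
        center_psi = np.concatenate([[fn.r_ref], fn.center])
        assert model(center_psi) == pytest.approx(-5.0)
        for d in np.eye(6) * 0.3:
            assert model(center_psi + d) > -5.0

    def test_two_funnels_global_minimum_is_deeper_center(self):
        f1 = simple_funnel(np.zeros(5), -8.0, [2, 2, 2, 300, 400], seed=1)
        f2 = simple_funnel(np.full(5, 2.0), -6.0, [2, 2, 2, 300, 400], seed=2)
        spec = FunnelSpec(funnels=[f1, f2], rho_rug=0.0)
        conf, e = ground_truth(spec)
        assert e == pytest.approx(-8.0, abs=1e-6)
        assert np.allclose(conf.x, f1.center, atol=1e-4)

    def test_rugged_minimum_matches_grid_search_oracle(self):
        fn = simple_funnel(np.zeros(5), -5.0, [2, 2.2, 2.5, 300, 400], seed=3)
        spec = FunnelSpec(funnels=[fn], rho_rug=0.5, seed=3)
        model = make_funnel_landscape(spec)
        conf, e = model.ground_truth()
        # brute-force oracle: dense grid over a box around the center
        g = np.linspace(-1.0, 1.0, 13)
        grids = np.meshgrid(*([g] * 5), indexing="ij")
        X = np.stack([G.ravel() for G in grids], axis=1) + fn.center
        Psi = np.column_stack([np.full(len(X), fn.r_ref), X])
        vals = model.energy_many(Psi)
        k = int(np.argmin(vals))
        step = g[1] - g[0]
        assert e <= vals[k] + 1e-9
        assert np.linalg.norm(conf.x - X[k]) <= np.sqrt(5) * step

    def test_ground_truth_beats_random_search(self):
        spec = default_funnel_spec(1, rho_rug=0.5, p_out=0.0, seed=5)
        model = make_funnel_landscape(spec)
        conf, e = model.ground_truth()
        rng = np.random.default_rng(5)
        fn = spec.funnels[0]
        X = fn.center + rng.uniform(-1.5, 1.5, size=(100_000, 5))
        Psi = np.column_stack([np.full(len(X), fn.r_ref), X])
        best = model.energy_many(Psi).min()
        assert e <= best + 1e-6
        for probe in spec.funnels:
            assert e <= model(np.concatenate([[probe.r_ref], probe.center])) + 1e-9

    def test_determinism(self):
        spec = default_funnel_spec(1, rho_rug=0.5, seed=11)
        m1, m2 = make_funnel_landscape(spec), make_funnel_landscape(spec)
        psi = np.array([25.0, 0.1, -0.2, 0.3, 0.0, -0.1])
        assert m1(psi) == m2(psi)
        assert m1(psi) == m1(psi)

    def test_non_pd_curvature_rejected(self):
        with pytest.raises(ValueError):
            Funnel(center=np.zeros(5), r_ref=25.0, depth=0.0, curvature=-np.eye(5))


class TestDecoyEnsemble:
    def test_row_count_and_outlier_count(self):
        spec = default_funnel_spec(1, p_out=0.15, seed=2)
        model = make_funnel_landscape(spec)
        ens, labels = generate_decoy_ensemble(model, spec, 200, seed=2, return_labels=True)
        assert len(ens) == 200
        assert (labels == -1).sum() == round(0.15 * 200)

    def test_sample_covariance_follows_sampling_law(self):
        spec = default_funnel_spec(1, p_out=0.0, rho_rug=0.0, seed=4)
        model = make_funnel_landscape(spec)
        T = 0.8
        ens = generate_decoy_ensemble(model, spec, 10_000, temperature=T, seed=4)
        X = np.array([c.x for c in ens])
        C = np.cov(X, rowvar=False)
        target = T * np.linalg.inv(spec.funnels[0].curvature)
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)))
        assert np.all(np.abs(C - target) <= 0.15 * scale)

    def test_low_temperature_concentrates_at_centers(self):
        spec = default_funnel_spec(2, p_out=0.0, rho_rug=0.0, separation=6.0, seed=6)
        model = make_funnel_landscape(spec)
        ens = generate_decoy_ensemble(model, spec, 400, temperature=1e-6, seed=6)
        centers = np.array([f.center for f in spec.funnels])
        X = np.array([c.x for c in ens])
        d = np.linalg.norm(X[:, None, :] - centers[None], axis=2).min(axis=1)
        assert d.max() < 0.01

    def test_permissive_directions_spread_wider(self):
        spec = default_funnel_spec(1, p_out=0.0, seed=8)
        model = make_funnel_landscape(spec)
        ens = generate_decoy_ensemble(model, spec, 2000, seed=8)
        X = np.array([c.x for c in ens])
        lam, V = np.linalg.eigh(spec.funnels[0].curvature)
        proj = (X - X.mean(axis=0)) @ V  # eigh: ascending, so first 3 = permissive
        spread = proj.std(axis=0)
        assert spread[:3].min() >= 10.0 * spread[3:].max() * 0.95

    def test_reproducible_from_seed(self):
        spec = default_funnel_spec(1, seed=9)
        model = make_funnel_landscape(spec)
        e1 = generate_decoy_ensemble(model, spec, 50, seed=9)
        e2 = generate_decoy_ensemble(model, spec, 50, seed=9)
        assert all(np.array_equal(a.psi, b.psi) and a.energy == b.energy
                   for a, b in zip(e1, e2))


class TestToyRigidEnergy:
    def test_lj_minimum_at_two_to_the_sixth_sigma(self):
        eps, sig = 0.3, 3.0
        rec = RigidBody([[0.0, 0, 0]])
        lig = RigidBody([[0.0, 0, 0]])
        model = toy_rigid_energy(rec, lig, EnergyWeights(w_vdw=2.0), lj_epsilon=eps, lj_sigma=sig)
        r_min = 2 ** (1 / 6) * sig
        assert model([r_min, 0, 0, 0, 0, 0]) == pytest.approx(2.0 * (-eps), rel=1e-12)
        assert abs(model([500.0, 0, 0, 0, 0, 0])) < 1e-10

    def test_hand_summed_two_by_two_system(self):
        eps, sig = 0.25, 3.0
        rec = RigidBody([[0.0, 0, 0], [2.0, 0, 0]], charges=[1.0, -0.5])
        lig = RigidBody([[-1.0, 0, 0], [1.0, 0, 0]], charges=[0.3, 0.2])
        w = EnergyWeights(w_vdw=1.0, w_coul=0.5)
        model = toy_rigid_energy(rec, lig, w, lj_epsilon=eps, lj_sigma=sig)
        psi = np.array([8.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        # ligand centroid at (0,0,8): atoms at (-1,0,8) and (1,0,8)
        from ssdu.landscape import COULOMB_KCAL

        expected = 0.0
        for (xr, qr) in [((0.0, 0, 0), 1.0), ((2.0, 0, 0), -0.5)]:
            for (xl, ql) in [((-1.0, 0, 8.0), 0.3), ((1.0, 0, 8.0), 0.2)]:
                r = np.linalg.norm(np.subtract(xr, xl))
                r = max(r, 0.6 * sig)
                expected += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                expected += 0.5 * COULOMB_KCAL * qr * ql / r
        assert model(psi) == pytest.approx(expected, rel=1e-12)

    def test_missing_charges_with_coulomb_is_config_error(self):
        rec = RigidBody([[0.0, 0, 0]])
        lig = RigidBody([[0.0, 0, 0]])
        with pytest.raises(ValueError):
            toy_rigid_energy(rec, lig, EnergyWeights(w_vdw=1.0, w_coul=1.0))

    def test_unknown_energy_terms_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            EnergyWeights.from_dict({"w_vdw": 1.0, "w_dars": 0.1})
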