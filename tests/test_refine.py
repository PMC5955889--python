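import warnings

import numpy as np
import pytest

from conftest import canonical_partition, dbscan_oracle
from ssdu.geometry import Conformation
from ssdu.landscape import FunnelSpec, default_funnel_spec, make_funnel_landscape
from ssdu.refine import (
    LocalMinOpts,
    SSDUParams,
    dbscan,
    local_minimize,
    reconstruct,
    sample_around,
    select_fit_set,
    ssdu_refine,
)
from ssdu.subspace import fit_pca, to_principal


class TestDbscan:
    def test_two_well_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(200, 5)),
                       rng.normal(100, 0.1, size=(200, 5))])
        a = dbscan(X, eps=1.0, n_min=10)
        assert a.n_clusters == 2
        assert (a.labels == -1).sum() == 0
        assert canonical_partition(a.labels) == canonical_partition(dbscan_oracle(X, 1.0, 10))

    def test_all_isolated_points_are_outliers(self, rng):
        X = np.arange(20, dtype=float)[:, None] * 10.0 * np.ones((1, 5))
        a = dbscan(X, eps=1.0, n_min=2)
        assert a.n_clusters == 0
        assert np.all(a.labels == -1)

    def test_permutation_invariance_on_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(50, 5)),
                       rng.normal(50, 0.1, size=(60, 5))])
        perm = rng.permutation(len(X))
        a1 = dbscan(X, 1.0, 5)
        a2 = dbscan(X[perm], 1.0, 5)
        part1, out1 = canonical_partition(a1.labels)
        # map permuted labels back to original indices
        inv_labels = np.empty(len(X), dtype=int)
        inv_labels[perm] = a2.labels
        part2, out2 = canonical_partition(inv_labels)
        assert part1 == part2 and out1 == out2

    def test_matches_density_connectivity_oracle_on_random_instances(self, rng):
        for trial in range(10):
            n = int(rng.integers(40, 150))
            X = rng.normal(size=(n, 3)) * rng.uniform(0.3, 2.0)
            eps = float(rng.uniform(0.3, 1.2))
            n_min = int(rng.integers(3, 12))
            a = dbscan(X, eps, n_min)
            assert canonical_partition(a.labels) == canonical_partition(
                dbscan_oracle(X, eps, n_min)
            )

    def test_cluster_sizes_at_least_n_min(self, rng):
        X = rng.normal(size=(300, 5))
        a = dbscan(X, 1.0, 20)
        assert all(s >= 20 for s in a.sizes)


class TestSelectFitSet:
    def test_eta_one_returns_everything(self):
        idx = select_fit_set(np.array([3.0, 1.0, 2.0]), eta=1.0)
        assert sorted(idx) == [0, 1, 2]

    def test_ceiling_rule_and_lowest_energy(self):
        e = np.array([5.0, 1.0, 4.0, 2.0, 9.0, 3.0, 8.0, 7.0, 6.0, 0.0])
        idx = select_fit_set(e, eta=0.3)
        assert len(idx) == 3
        assert set(e[idx]) == {0.0, 1.0, 2.0}

    def test_selected_max_below_excluded_min(self, rng):
        e = rng.normal(size=37)
        idx = select_fit_set(e, eta=0.4)
        excluded = np.setdiff1d(np.arange(37), idx)
        assert e[idx].max() <= e[excluded].min()


class TestLocalMinimize:
    @pytest.fixture
    def quadratic_model(self):
        fn_spec = default_funnel_spec(1, rho_rug=0.0, p_out=0.0, seed=0)
        return make_funnel_landscape(fn_spec), fn_spec.funnels[0]

    def test_stationary_start_unchanged(self, quadratic_model):
        model, fn = quadratic_model
        start = Conformation.from_psi(np.concatenate([[fn.r_ref], fn.center]))
        out = local_minimize(model, start)
        assert np.allclose(out.psi, start.psi, atol=1e-4)

    def test_converges_to_analytic_minimizer(self, quadratic_model, rng):
        model, fn = quadratic_model
        start = Conformation.from_psi(
            np.concatenate([[fn.r_ref + 0.2], fn.center + rng.normal(scale=0.2, size=5)])
        )
        out = local_minimize(model, start, LocalMinOpts(maxiter=300))
        assert np.allclose(out.x, fn.center, atol=1e-4)
        assert out.r == pytest.approx(fn.r_ref, abs=1e-4)

    def test_never_increases_energy(self, single_funnel, rng):
        model = single_funnel["model"]
        for c in single_funnel["ensemble"][:20]:
            out = local_minimize(model, c)
            assert out.energy <= model(c) + 1e-12


class TestSampling:
    @pytest.fixture
    def basis(self, rng):
        X = rng.normal(size=(200, 5)) * np.array([2.0, 1.5, 1.0, 0.2, 0.1])
        return fit_pca(X), X

    def test_beta_zero_degenerate(self, basis):
        b, X = basis
        Z = to_principal(b, X)
        out = sample_around(b, np.array([0.5, -0.2, 0.1]), Z, beta=0.0, k_bar=7, seed=1)
        assert out.shape == (7, 5)
        assert np.allclose(out, out[0], atol=1e-12)

    def test_range_constraint_in_principal_coords(self, basis):
        b, X = basis
        Z = to_principal(b, X)
        phi_star = np.array([0.5, -0.2, 0.1])
        beta = 2.0
        out = sample_around(b, phi_star, Z, beta=beta, k_bar=500, seed=2)
        Zs = to_principal(b, out)
        z_star = np.concatenate([phi_star, Z[:, 3:].mean(axis=0)])
        for i in range(5):
            assert np.all(np.abs(Zs[:, i] - z_star[i]) <= 0.5 * beta * b.sigma[i] + 1e-12)

    def test_empirical_spread_matches_uniform_moments(self, basis):
        b, X = basis
        Z = to_principal(b, X)
        beta = 1.5
        out = sample_around(b, np.zeros(3), Z, beta=beta, k_bar=10_000, seed=3)
        Zs = to_principal(b, out)
        expected = beta * b.sigma / np.sqrt(12.0)
        assert np.allclose(Zs.std(axis=0), expected, rtol=0.05)

    def test_reconstruct_attaches_mean_r(self):
        out = reconstruct(np.zeros((3, 5)) + 0.1, r_bar=7.0)
        assert len(out) == 3
        assert all(c.r == 7.0 for c in out)
        with pytest.raises(ValueError):
            reconstruct(np.zeros((2, 5)), r_bar=-1.0)


class TestSsduRefine:
    def test_output_contract_and_monotonicity(self, single_funnel):
        model, ensemble = single_funnel["model"], single_funnel["ensemble"]
        params = SSDUParams(K=300, eps=1.0, n_min=30, seed=7, k_bar=60, max_iter=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined = ssdu_refine(model, ensemble, params)
        assert len(refined) == len(ensemble)
        e_in = np.sort([c.energy for c in ensemble])
        e_out = np.sort([c.energy for c in refined])
        assert np.all(e_out <= e_in + 1e-12)

    def test_determinism_bit_for_bit(self, single_funnel):
        model, ensemble = single_funnel["model"], single_funnel["ensemble"]
        params = SSDUParams(K=300, eps=1.0, n_min=30, seed=3, k_bar=40, max_iter=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = ssdu_refine(model, ensemble, params)
            r2 = ssdu_refine(model, ensemble, params)
        assert all(np.array_equal(a.psi, b.psi) and a.energy == b.energy
                   for a, b in zip(r1, r2))

    def test_all_outliers_returns_input_with_warning(self, rng):
        spec = default_funnel_spec(1, rho_rug=0.0, p_out=0.0, seed=0)
        model = make_funnel_landscape(spec)
        # spread points far apart: nothing reaches the core threshold
        psis = np.column_stack([np.full(50, 25.0)] + [np.arange(50) * 10.0] * 5)
        ensemble = [Conformation.from_psi(p) for p in psis]
        params = SSDUParams(K=50, eps=0.5, n_min=5, seed=0, k_bar=10, max_iter=1)
        with pytest.warns(UserWarning, match="no clusters"):
            refined = ssdu_refine(model, ensemble, params)
        assert all(np.array_equal(a.psi, b.psi) for a, b in zip(ensemble, refined))

    def test_degenerate_identical_ensemble_passes_through(self):
        spec = default_funnel_spec(1, rho_rug=0.0, p_out=0.0, seed=0)
        model = make_funnel_landscape(spec)
        psi = np.concatenate([[spec.funnels[0].r_ref], spec.funnels[0].center])
        ensemble = [Conformation.from_psi(psi) for _ in range(40)]
        params = SSDUParams(K=40, eps=0.5, n_min=5, seed=0, k_bar=10, max_iter=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined = ssdu_refine(model, ensemble, params)
        assert len(refined) == 40
        assert min(c.energy for c in refined) <= model(psi) + 1e-12
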