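"""Coarse-grained 2-D model: fast manifold, drift/noise closed forms, SDE."""

import numpy as np
import pytest

import epitip as et
from epitip.cg import (
    CGModel,
    NoRootInDomainError,
    euler_maruyama_simulate,
    fast_stationary_density,
)
from epitip.micro import collective_observables, meanfield_initial, micro_steady_state
from epitip.params import ScalingSettings


def _reference_drift(model, X1, X2):
    """Independent term-by-term transcription of the averaged drift.

    Written as four explicit Michaelis–Menten quotients, structured
    deliberately differently from the implementation (no shared kappas).
    """
    p = model.params
    l1, sn, ph = model.l1, model.sqrtN, model.phi_hat
    X3 = l1 * p.s_sites - X1 - X2
    Btil = l1 * p.B / sn
    add_m = (p.k3 * p.k1 * (p.e0 / sn) * l1 * (p.alpha1 + ph * X1) * X3) / (
        p.k2 + p.k3 + p.k1 * l1 * (p.alpha1 + ph * X1) * X3
    )
    rem_m = (p.k6 * p.k4 * (p.u0 / sn) * l1 * (p.alpha4 + ph * X2) * X1) / (
        p.k5 + p.k6 + p.k4 * l1 * (p.alpha4 + ph * X2) * X1
    )
    add_a = (p.k9 * p.k7 * (p.h0 / sn) * l1 * (p.alpha7 + ph * X2) * X3) / (
        p.k8 + p.k9 + p.k7 * l1 * (p.alpha7 + ph * X2) * X3
    )
    rem_a = (p.k12 * p.k10 * (p.s0_enz / sn) * l1 * (p.alpha10 + ph * X1) * X2) / (
        p.k11 + p.k12 + Btil + p.k10 * l1 * (p.alpha10 + ph * X1) * X2
    )
    return add_m - rem_m, add_a - rem_a


def _reference_noise(model, X1, X2):
    """Independent transcription of the averaged noise intensities."""
    p = model.params
    l1, sn, ph, gh = model.l1, model.sqrtN, model.phi_hat, model.gamma_hat
    X3 = l1 * p.s_sites - X1 - X2
    f = model.fast_manifold((X1, X2))

    def term(kb, ku, kc, alpha, Xfb, enz, sub):
        return kb * (
            (2 * ku + kc) / (ku + kc) * alpha + (gh + ku / (ku + kc) * ph) * Xfb
        ) * enz * sub

    N1 = term(p.k1, p.k2, p.k3, p.alpha1, X1, f.e2, X3) + term(
        p.k4, p.k5, p.k6, p.alpha4, X2, f.eU, X1
    )
    N2 = term(p.k7, p.k8, p.k9, p.alpha7, X2, f.eH, X3) + term(
        p.k10, p.k11, p.k12, p.alpha10, X1, f.eS, X2
    )
    return N1, N2


class TestFastManifold:
    def test_zero_enzyme_pools_give_zero_complexes(self, bundle):
        params, scaling, conn, spec, _ = bundle
        model = CGModel(
            params.replace(e0=0.0, u0=0.0, h0=0.0, s0_enz=0.0), spec, scaling
        )
        f = model.fast_manifold((0.3 * model.total, 0.3 * model.total))
        assert f.c_E == f.c_U == f.c_H == f.c_S == f.c_SD == 0.0

    def test_single_enzyme_michaelis_menten_occupancy(self, bundle):
        # bound EZH2 at a slow state follows e_tot * kS / (kS + K) with
        # K = k2 + k3 (hand-checked closed form)
        params, scaling, conn, spec, _ = bundle
        model = CGModel(params, spec, scaling)
        X = (0.2 * model.total, 0.1 * model.total)
        f = model.fast_manifold(X)
        X3 = model.total - X[0] - X[1]
        kS = params.k1 * model.l1 * (params.alpha1 + model.phi_hat * X[0]) * X3
        expect = (params.e0 / model.sqrtN) * kS / (kS + params.k2 + params.k3)
        assert f.c_E == pytest.approx(expect, rel=1e-12)
        assert f.e2 == pytest.approx(params.e0 / model.sqrtN - expect, rel=1e-12)

    def test_sequestered_fraction_scales_with_B(self, cg_model):
        p = cg_model.params
        f = cg_model.fast_manifold((1.0, 1.0))
        assert f.c_SD / f.eS == pytest.approx(
            cg_model.B_tilde / (p.k11 + p.k12), rel=1e-12
        )

    def test_out_of_domain_rejected(self, cg_model):
        with pytest.raises(NoRootInDomainError):
            cg_model.fast_manifold((2.0 * cg_model.total, cg_model.total))


class TestDriftNoise:
    def test_zero_flux_state(self, bundle):
        # no methylation and no basal EZH2 activity: both terms of the
        # methylation drift vanish (removal needs X1 > 0 too)
        params, scaling, conn, spec, _ = bundle
        model = CGModel(params.replace(alpha1=0.0), spec, scaling)
        D = model.drift((0.0, 0.5))
        assert D[0] == 0.0

    def test_large_B_quenches_deacetylation(self, bundle):
        params, scaling, conn, spec, _ = bundle
        model_inf = CGModel(params.replace(B=1e12), spec, scaling)
        X = (1.0, 1.0)
        D = model_inf.drift(X)
        p = params
        add_a = model_inf.drift((1.0, 1.0))[1]
        # removal term gone: D2 equals the pure addition flux
        kap7 = p.k7 * model_inf.l1 * (p.alpha7 + model_inf.phi_hat * X[1])
        X3 = model_inf.total - 2.0
        expect = p.k9 * (p.h0 / model_inf.sqrtN) * kap7 * X3 / (
            p.k8 + p.k9 + kap7 * X3
        )
        assert D[1] == pytest.approx(expect, rel=1e-9)

    def test_drift_matches_independent_transcription(self, cg_model, rng):
        for _ in range(20):
            X1 = rng.uniform(0, cg_model.total)
            X2 = rng.uniform(0, cg_model.total - X1)
            D = cg_model.drift((X1, X2))
            ref = _reference_drift(cg_model, X1, X2)
            np.testing.assert_allclose(D, ref, rtol=1e-12)

    def test_noise_matches_independent_transcription(self, cg_model, rng):
        for _ in range(20):
            X1 = rng.uniform(0, cg_model.total)
            X2 = rng.uniform(0, cg_model.total - X1)
            N = cg_model.noise((X1, X2))
            ref = _reference_noise(cg_model, X1, X2)
            np.testing.assert_allclose(N, ref, rtol=1e-12)
            assert np.all(N >= 0.0)

    def test_noise_zero_at_bare_state_without_basal_activity(self, bundle):
        params, scaling, conn, spec, _ = bundle
        model = CGModel(
            params.replace(alpha1=0.0, alpha4=0.0, alpha7=0.0, alpha10=0.0),
            spec, scaling,
        )
        N = model.noise((0.0, 0.0))
        np.testing.assert_allclose(N, 0.0, atol=1e-15)

    def test_noise_homogeneous_in_rate_constants(self, bundle):
        params, scaling, conn, spec, _ = bundle
        c = 3.0
        scaled = params.replace(**{f"k{i}": c * getattr(params, f"k{i}")
                                   for i in range(1, 13)})
        # B is a rate-like term: scale it too so the denominators keep shape
        scaled = scaled.replace(B=c * params.B)
        m0 = CGModel(params, spec, scaling)
        m1 = CGModel(scaled, spec, scaling)
        X = (1.2, 0.7)
        np.testing.assert_allclose(m1.noise(X), c * m0.noise(X), rtol=1e-12)

    def test_vectorised_evaluation_matches_scalar(self, cg_model, rng):
        Xs = np.column_stack([
            rng.uniform(0, cg_model.total / 2, 16),
            rng.uniform(0, cg_model.total / 2, 16),
        ])
        D = cg_model.drift_many(Xs)
        N = cg_model.noise_many(Xs)
        for k in range(16):
            np.testing.assert_allclose(D[k], cg_model.drift(Xs[k]), rtol=1e-12)
            np.testing.assert_allclose(N[k], cg_model.noise(Xs[k]), rtol=1e-12)

    def test_meanfield_rhs_equals_drift_and_fixed_point_residual(
        self, cg_model, cg_fixed_points
    ):
        X = (1.0, 0.5)
        np.testing.assert_array_equal(cg_model.meanfield_rhs(X), cg_model.drift(X))
        for fp in cg_fixed_points:
            assert np.max(np.abs(cg_model.drift(fp.X))) < 1e-10

    def test_conservation_of_total(self, cg_model):
        st = cg_model.state(1.0, 2.0)
        assert st.X1 + st.X2 + st.X3 == pytest.approx(cg_model.total)


class TestMicroCGConsistency:
    def test_all_to_all_fixed_points_agree_in_small_eps_limit(self):
        # uniform all-to-all: the reduction is exact up to the O(eps)
        # substrate bound in enzyme complexes; at eps -> 0 the projected
        # microscopic fixed points coincide with the CG ones
        n = 6
        params, _ = et.default_bistable(n)
        scaling = ScalingSettings(omega27=1e7, omega_e=10.0)
        conn = et.make_all_to_all(n, 1.0 / (n - 1))
        spec = et.spectral_quantities(conn)
        model = CGModel(params, spec, scaling)
        net = et.build_reaction_network(params, conn, scaling)
        stables = [
            fp for fp in et.find_fixed_points_model(model, grid_density=18)
            if fp.is_stable
        ]
        for kind in ("hypoacetylated", "hyperacetylated"):
            x, _ = micro_steady_state(net, meanfield_initial(net, kind))
            c = collective_observables(x, spec, scaling, s_sites=params.s_sites)
            X = np.array([c.X1, c.X2])
            fp = min(stables, key=lambda f: np.linalg.norm(f.X - X))
            assert np.linalg.norm(fp.X - X) / np.linalg.norm(X) < 1e-6


class TestEulerMaruyama:
    def test_zero_noise_limit_matches_deterministic_path(self, cg_model):
        from scipy.integrate import solve_ivp

        X0 = np.array([0.6, 0.2]) * cg_model.total / 2
        times, states = euler_maruyama_simulate(
            cg_model, X0, dt=1e-3, t_end=1.0, seed=0, omega27=np.inf
        )
        sol = solve_ivp(
            lambda t, y: cg_model.drift(y), (0, 1.0), X0,
            rtol=1e-10, atol=1e-12, t_eval=[1.0],
        )
        np.testing.assert_allclose(states[-1], sol.y[:, 0], atol=5e-3)

    def test_reflecting_boundary_keeps_simplex(self, cg_model):
        # violent noise: X3 must stay non-negative throughout
        times, states = euler_maruyama_simulate(
            cg_model, (0.1, 0.1), dt=0.01, t_end=10.0, seed=5, omega27=5.0
        )
        X3 = cg_model.total - states[:, 0] - states[:, 1]
        assert np.all(states >= -1e-9)
        assert np.all(X3 >= -1e-9)

    def test_reproducible_by_seed(self, cg_model):
        a = euler_maruyama_simulate(cg_model, (1.0, 1.0), 0.01, 1.0, seed=9)
        b = euler_maruyama_simulate(cg_model, (1.0, 1.0), 0.01, 1.0, seed=9)
        np.testing.assert_array_equal(a[1], b[1])


class TestFastStationaryDensity:
    def test_normalisation_and_laplace_mode(self, cg_model):
        Xs = (1.5, 0.8)
        e_tot = cg_model.params.e0 / cg_model.sqrtN
        grid = np.linspace(0.0, e_tot, 600)
        psi = fast_stationary_density("ezh2", Xs, cg_model, grid, omega_e=1000.0)
        assert np.trapezoid(psi, grid) == pytest.approx(1.0, abs=1e-8)
        mode = grid[np.argmax(psi)]
        root = cg_model.fast_manifold(Xs).c_E
        assert abs(mode - root) <= (grid[1] - grid[0]) + 1e-12

    def test_density_sharpens_with_system_size(self, cg_model):
        Xs = (1.5, 0.8)
        e_tot = cg_model.params.e0 / cg_model.sqrtN
        grid = np.linspace(0.0, e_tot, 600)

        def variance(omega):
            psi = fast_stationary_density("ezh2", Xs, cg_model, grid, omega_e=omega)
            mu = np.trapezoid(grid * psi, grid)
            return np.trapezoid((grid - mu) ** 2 * psi, grid)

        v = [variance(o) for o in (250.0, 500.0, 1000.0, 2000.0)]
        assert v[0] > v[1] > v[2] > v[3]
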