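"""Microscopic reaction network: exact SSA, mean-field ODEs, observables."""

import numpy as np
import pytest

import epitip as et
from epitip.connectivity import ConnectivityMatrix
from epitip.micro import (
    N_SPECIES,
    build_reaction_network,
    collective_observables,
    concentrations,
    average_marks,
    gillespie_simulate,
    initial_condition,
    meanfield_initial,
    micro_meanfield_rhs,
    micro_steady_state,
)
from epitip.params import KineticParameters, ScalingSettings


def _zero_rate_params(**on):
    """All rate constants zero except the ones switched on."""
    kw = {f"k{i}": 0.0 for i in range(1, 13)}
    kw.update(alpha1=0.0, alpha4=0.0, alpha7=0.0, alpha10=0.0)
    kw.update(on)
    return KineticParameters(**kw)


class TestNetworkStructure:
    def test_channel_count(self):
        params, scaling = et.default_bistable(3)
        net = build_reaction_network(params, et.make_all_to_all(3, 0.5), scaling)
        assert net.n_channels == 3 * 12 + 2

    def test_dimension_mismatch_rejected(self, micro_network):
        x0 = initial_condition(micro_network)
        bad = et.build_reaction_network(
            *et.default_bistable(4)[:1], et.make_all_to_all(4, 0.3),
            et.default_bistable(4)[1],
        )
        with pytest.raises(ValueError, match="mismatch"):
            gillespie_simulate(bad, x0, t_end=0.1, seed=0)

    def test_sequestration_rates_derive_from_B(self):
        params, scaling = et.default_bistable(3)
        net = build_reaction_network(params, et.make_all_to_all(3, 0.5), scaling)
        # quasi-equilibrium capture/release ratio reproduces B exactly
        assert net.r_cap / net.r_rel == pytest.approx(
            params.B / (params.k11 + params.k12)
        )
        assert net.r_rel >= 10.0 * max(params.k3, params.k6, params.k9, params.k12)


class TestMeanField:
    def test_conservation_group_sums_vanish(self, bundle, rng):
        params, scaling, conn, _, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x = meanfield_initial(net, "hypoacetylated")
        # perturb into a generic admissible interior state
        x[0] *= rng.uniform(0.5, 1.0, size=x.shape[1])
        dx = micro_meanfield_rhs(x, net)
        eps = scaling.epsilon
        # per-region site conservation: slow rows + eps * complex rows
        site = dx[0] + dx[1] + dx[2] + eps * (dx[4] + dx[6] + dx[8] + dx[10])
        np.testing.assert_allclose(site, 0.0, atol=1e-12)
        for free_row, cplx_row in ((3, 4), (5, 6), (7, 8)):
            assert dx[free_row, 0] + dx[cplx_row].sum() == pytest.approx(0.0, abs=1e-12)
        assert dx[9, 0] + dx[10].sum() + dx[11, 0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_input_rejected(self, micro_network):
        x = meanfield_initial(micro_network)
        x[0, 0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            micro_meanfield_rhs(x, micro_network)

    def test_permutation_symmetry_on_all_to_all(self, bundle):
        params, scaling, conn, _, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x = meanfield_initial(net, "hyperacetylated")
        dx = micro_meanfield_rhs(x, net)
        for row in (0, 1, 2, 4, 6, 8, 10):
            assert np.ptp(dx[row]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_feedback_zeroes_methylation_binding(self):
        # alpha1 = 0 and no methylation anywhere: EZH2 binding flux vanishes,
        # so the only substrate drain is acetylation
        params = _zero_rate_params(k1=1.0, k7=1.0, alpha7=0.3)
        scaling = ScalingSettings(1000.0, 50.0)
        conn = et.make_all_to_all(4, 0.5)
        net = build_reaction_network(params, conn, scaling)
        x = meanfield_initial(net, "unmodified")
        dx = micro_meanfield_rhs(x, net)
        # complex formation only via the HAT channel
        assert np.all(dx[4] == 0.0)
        assert np.all(dx[8] > 0.0)

    def test_single_region_matches_hand_coded_michaelis_menten(self):
        # independent oracle: literal mass-action evaluation of the
        # two-substrate enzyme scheme for one region with self-contact w
        params, scaling = et.default_bistable(1)
        w = 0.8
        conn = ConnectivityMatrix(W=[[w]], pattern="user")
        net = build_reaction_network(params, conn, scaling)
        m, a, s = 0.3, 0.2, 0.5
        cE, cU, cH, cS = 0.02, 0.03, 0.04, 0.05
        e2 = params.e0 - cE
        eU = params.u0 - cU
        eH = params.h0 - cH
        cSD = 0.01
        eS = params.s0_enz - cS - cSD
        x = np.zeros((N_SPECIES, 1))
        x[:, 0] = [m, a, s, e2, cE, eU, cU, eH, cH, eS, cS, cSD]
        dx = micro_meanfield_rhs(x, net)
        p = params
        bind1 = p.k1 * (p.alpha1 + w * m) * s * e2
        bind4 = p.k4 * (p.alpha4 + w * a) * m * eU
        bind7 = p.k7 * (p.alpha7 + w * a) * s * eH
        bind10 = p.k10 * (p.alpha10 + w * m) * a * eS
        assert dx[0, 0] == pytest.approx(p.k3 * cE - bind4 + p.k5 * cU, rel=1e-12)
        assert dx[1, 0] == pytest.approx(p.k9 * cH - bind10 + p.k11 * cS, rel=1e-12)
        assert dx[2, 0] == pytest.approx(
            -bind1 - bind7 + p.k2 * cE + p.k8 * cH + p.k6 * cU + p.k12 * cS,
            rel=1e-12,
        )

    def test_steady_state_residual_and_conservation(self, bundle):
        params, scaling, conn, _, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x0 = meanfield_initial(net, "hypoacetylated")
        x, report = micro_steady_state(net, x0)
        assert report["converged"] and report["residual"] < 1e-9
        eps = scaling.epsilon
        site = x[0] + x[1] + x[2] + eps * (x[4] + x[6] + x[8] + x[10])
        np.testing.assert_allclose(site, params.s_sites, rtol=1e-8)
        assert x[3, 0] + x[4].sum() == pytest.approx(params.e0, rel=1e-8)

    def test_two_basins_in_bistable_window(self, bundle):
        params, scaling, conn, _, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x_hypo, _ = micro_steady_state(net, meanfield_initial(net, "hypoacetylated"))
        x_hyper, _ = micro_steady_state(net, meanfield_initial(net, "hyperacetylated"))
        m1, a1 = average_marks(x_hypo)
        m2, a2 = average_marks(x_hyper)
        assert a1 < m1  # hypoacetylated landscape retained
        assert a2 > m2  # hyperacetylated landscape retained
        assert abs(a1 - a2) > 0.1


class TestSSA:
    def test_all_rates_zero_state_constant(self):
        params = _zero_rate_params()
        scaling = ScalingSettings(100.0, 10.0)
        conn = et.make_all_to_all(3, 0.5)
        net = build_reaction_network(params, conn, scaling)
        x0 = initial_condition(net, "hypoacetylated")
        traj = gillespie_simulate(net, x0, t_end=5.0, seed=1, n_records=6)
        for k in range(6):
            np.testing.assert_array_equal(traj.states[k], x0.counts)

    def test_conservation_and_reproducibility(self, micro_network):
        x0 = initial_condition(micro_network, "hypoacetylated")
        traj1 = gillespie_simulate(micro_network, x0, t_end=0.2, seed=42, n_records=9)
        traj2 = gillespie_simulate(micro_network, x0, t_end=0.2, seed=42, n_records=9)
        np.testing.assert_array_equal(traj1.states, traj2.states)
        S0 = x0.site_totals()[0]
        enz0 = x0.enzyme_totals()
        for k in range(9):
            st = traj1.state_at(k)
            assert np.all(st.site_totals() == S0)
            assert st.enzyme_totals() == enz0
        # different seed gives a different path
        traj3 = gillespie_simulate(micro_network, x0, t_end=0.2, seed=43, n_records=9)
        assert not np.array_equal(traj1.states, traj3.states)

    def test_single_channel_binding_time_is_exponential(self):
        # one region, only HAT binding active (no unbinding/catalysis), a
        # single enzyme copy: the time to the first (and only) event is
        # exponential with the analytic propensity k7*alpha7*S0/Omega_E
        params = _zero_rate_params(k7=1.0, alpha7=0.4)
        scaling = ScalingSettings(omega27=200.0, omega_e=1.0)
        conn = ConnectivityMatrix(W=[[0.0]], pattern="user")
        net = build_reaction_network(params, conn, scaling)
        x0 = initial_condition(net, "unmodified")
        x0.counts[7, 0] = 1  # exactly one HAT copy
        S0 = x0.counts[2, 0]
        lam = params.k7 * params.alpha7 * S0 / scaling.omega_e
        t_probe = 0.8 / lam
        n_runs = 3000
        bound = 0
        for s in range(n_runs):
            traj = gillespie_simulate(net, x0, t_end=t_probe, seed=s, n_records=2)
            bound += int(traj.states[-1, 8, 0] > 0)
        p_emp = bound / n_runs
        p_theory = 1.0 - np.exp(-lam * t_probe)
        se = np.sqrt(p_theory * (1 - p_theory) / n_runs)
        assert abs(p_emp - p_theory) < 3.5 * se

    def test_ensemble_mean_tracks_meanfield(self, bundle):
        # small-scale law-of-large-numbers check (the full-size version runs
        # in the acceptance suite)
        from scipy.integrate import solve_ivp

        params, scaling, conn, _, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x0 = initial_condition(net, "hypoacetylated")
        n_reps, n_chk = 60, 6
        means = []
        for s in range(n_reps):
            tr = gillespie_simulate(net, x0, t_end=0.3, seed=1000 + s,
                                    n_records=n_chk)
            means.append(tr.states[:, :3, :].mean(axis=2) / scaling.omega27)
        means = np.array(means)
        mu = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(n_reps)
        x0c = concentrations(x0, scaling)
        sol = solve_ivp(
            lambda t, y: micro_meanfield_rhs(y.reshape(12, -1), net).ravel(),
            (0, 0.3), x0c.ravel(), method="LSODA", rtol=1e-8, atol=1e-10,
            t_eval=np.linspace(0, 0.3, n_chk),
        )
        ode = sol.y.T.reshape(n_chk, 12, -1)[:, :3, :].mean(axis=2)
        z = (mu - ode)[1:] / np.maximum(se[1:], 1e-12)
        assert np.abs(z).max() < 4.0


class TestObservables:
    def test_average_marks_constant_and_zero(self, micro_network):
        scaling = micro_network.scaling
        x0 = initial_condition(micro_network, meth_frac=0.5, acet_frac=0.25)
        mbar, abar = average_marks(x0, scaling)
        assert mbar == pytest.approx(0.5)
        assert abar == pytest.approx(0.25)
        z = initial_condition(micro_network, "unmodified")
        assert average_marks(z, scaling) == (0.0, 0.0)

    def test_average_marks_matches_brute_force(self, micro_network, rng):
        x = meanfield_initial(micro_network)
        x[0] = rng.uniform(0, 0.5, size=x.shape[1])
        x[1] = rng.uniform(0, 0.5, size=x.shape[1])
        mbar, abar = average_marks(x)
        assert mbar == pytest.approx(sum(x[0]) / x.shape[1])
        assert abar == pytest.approx(sum(x[1]) / x.shape[1])

    def test_collective_observables_uniform_weights(self, bundle):
        params, scaling, conn, spec, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x0 = initial_condition(net, meth_frac=0.4, acet_frac=0.2)
        c = collective_observables(x0, spec, scaling, s_sites=params.s_sites)
        n = conn.n_regions
        # uniform eigenvector: X1 = sqrt(N_C) * mean methylation
        assert c.X1 == pytest.approx(np.sqrt(n) * 0.4, rel=1e-6)
        assert c.X2 == pytest.approx(np.sqrt(n) * 0.2, rel=1e-6)
        assert c.X3 == pytest.approx(c.total - c.X1 - c.X2)

    def test_collective_observables_brute_force(self, bundle, rng):
        params, scaling, conn, spec, _ = bundle
        net = build_reaction_network(params, conn, scaling)
        x = meanfield_initial(net)
        x[0] = rng.uniform(0, 0.6, size=x.shape[1])
        c = collective_observables(x, spec, scaling, s_sites=params.s_sites)
        assert c.X1 == pytest.approx(float(np.dot(spec.u, x[0])))
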