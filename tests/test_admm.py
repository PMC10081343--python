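import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from tofsaa import admm as A
from tofsaa.forward import apply_data_scaling, normalize_counts


def brute_force_simplex(v, total):
    """Active-set enumeration oracle for the simplex QP (len(v) <= ~10)."""
    v = np.asarray(v, dtype=float)
    best, best_d = None, np.inf
    idx = range(len(v))
    for k in range(1, len(v) + 1):
        for S in itertools.combinations(idx, k):
            theta = (v[list(S)].sum() - total) / k
            x = np.zeros_like(v)
            x[list(S)] = v[list(S)] - theta
            if np.all(x[list(S)] >= -1e-12):
                d = np.sum((x - v) ** 2)
                if d < best_d:
                    best, best_d = x, d
    return best


class TestStepSizes:
    def test_plug_in_values(self):
        st = A.make_step_sizes(1.0, 1.0, 2.0, 4.0)
        assert st.sigma_lam == 0.5 and st.tau_lam == 0.5
        assert st.sigma_mu == 0.25 and st.tau_mu == 0.25

    @pytest.mark.parametrize("rho_l,rho_m,nT,nP",
                             [(1, 1, 2, 3), (0.3, 5, 17.2, 8.1), (10, 0.1, 1, 1)])
    def test_product_identities(self, rho_l, rho_m, nT, nP):
        st = A.make_step_sizes(rho_l, rho_m, nT, nP)
        assert st.sigma_lam * st.tau_lam * nT**2 == pytest.approx(1.0)
        assert st.sigma_mu * st.tau_mu * nP**2 == pytest.approx(1.0)

    def test_doubling_rho(self):
        a = A.make_step_sizes(1.0, 1.0, 2.0, 2.0)
        b = A.make_step_sizes(2.0, 1.0, 2.0, 2.0)
        assert b.sigma_lam == pytest.approx(2 * a.sigma_lam)
        assert b.tau_lam == pytest.approx(a.tau_lam / 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            A.make_step_sizes(0.0, 1.0, 1.0, 1.0)


class TestSimplexProject:
    def test_feasible_point_unchanged(self):
        v = np.array([0.25, 0.5, 0.25])
        assert np.allclose(A.simplex_project(v, 1.0), v)

    def test_nearest_vertex(self):
        out = A.simplex_project(np.array([2.0, 0.0, 0.0]), 1.0)
        assert np.allclose(out, [1.0, 0.0, 0.0])

    def test_sum_and_nonnegativity(self, rng):
        for _ in range(20):
            v = rng.standard_normal(rng.integers(2, 50)) * 10
            total = float(rng.random() * 5 + 0.1)
            x = A.simplex_project(v, total)
            assert np.all(x >= 0)
            assert x.sum() == pytest.approx(total, rel=1e-10)

    def test_against_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            v = rng.standard_normal(n) * 3
            total = float(rng.random() * 4 + 0.1)
            ours = A.simplex_project(v, total)
            ref = brute_force_simplex(v, total)
            assert np.allclose(ours, ref, atol=1e-8)

    def test_preserves_shape(self, rng):
        v = rng.standard_normal((4, 5))
        out = A.simplex_project(v, 2.0)
        assert out.shape == (4, 5)
        assert out.sum() == pytest.approx(2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            A.simplex_project(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            A.simplex_project(np.empty(0), 1.0)


class TestYLamClosedForm:
    def test_negative_root_clipped_when_no_counts(self):
        assert A.y_lam_closed_form(-3.0, 0.0, 1.0) == 0.0

    def test_pure_quadratic(self):
        assert A.y_lam_closed_form(0.0, 4.0, 1.0) == pytest.approx(2.0)

    def test_linear_case_matches_max_formula(self, rng):
        b = rng.standard_normal(100) * 5
        out = A.y_lam_closed_form(b, np.zeros(100), 0.7)
        assert np.allclose(out, np.maximum(b / 0.7, 0.0))

    def test_minimises_separable_objective(self, rng):
        # oracle: fine grid search on the 1D objective
        #   exp(-ymu) y - C log y - u y + (sigma/2)(y - t)^2
        n = 1000
        sigma = np.exp(rng.uniform(-2, 2))
        ymu = rng.uniform(0, 3, n)
        u = rng.standard_normal(n)
        tgt = rng.uniform(0, 5, n)
        C = np.where(rng.random(n) < 0.3, 0.0, rng.uniform(0, 20, n))
        b = u + sigma * tgt - np.exp(-ymu)
        y = A.y_lam_closed_form(b, C, sigma)
        grid = np.linspace(1e-9, 60.0, 30001)

        def obj(yv):
            yv = np.asarray(yv)
            with np.errstate(divide="ignore", invalid="ignore"):
                pen = np.where(C[:, None] > 0,
                               -C[:, None] * np.log(yv), 0.0)
                return (np.exp(-ymu)[:, None] * yv + pen - u[:, None] * yv
                        + sigma / 2 * (yv - tgt[:, None]) ** 2)

        vals = obj(grid[None, :]).min(axis=1)
        ours = obj(y[:, None])[:, 0]
        assert np.all(ours <= vals + 1e-6 * (1 + np.abs(vals)))

    def test_nonnegative_output(self, rng):
        b = rng.standard_normal(200) * 10
        C = rng.uniform(0, 5, 200)
        assert np.all(A.y_lam_closed_form(b, C, 0.3) >= 0)


class TestYMuNewton:
    @staticmethod
    def _psi_prime(y, yl, Cl, u, pmu, sigma):
        return -np.exp(-y) * yl + Cl - u + sigma * (y - pmu)

    def test_linear_case_one_step(self):
        # y_lam = 0 makes psi' linear: root = Pmu + (u - C)/sigma, clipped
        sigma, u, Cl, pmu = 2.0, 0.3, 1.0, 4.0
        out = A.y_mu_newton(np.zeros(1), np.zeros(1), np.array([Cl]),
                            np.array([u]), np.array([pmu]), sigma, n_newton=1)
        assert out[0] == pytest.approx(max(pmu + (u - Cl) / sigma, 0.0))

    def test_against_bisection_oracle(self, rng):
        n = 1000
        sigma = 0.8
        yl = rng.uniform(0, 50, n)
        Cl = rng.uniform(0, 30, n)
        u = rng.standard_normal(n)
        pmu = rng.uniform(0, 4, n)
        y = A.y_mu_newton(np.zeros(n), yl, Cl, u, pmu, sigma, n_newton=10)
        lo, hi = np.full(n, -50.0), np.full(n, 50.0)
        for _ in range(60):
            mid = (lo + hi) / 2
            gm = self._psi_prime(mid, yl, Cl, u, pmu, sigma)
            hi = np.where(gm > 0, mid, hi)
            lo = np.where(gm > 0, lo, mid)
        ref = np.maximum((lo + hi) / 2, 0.0)
        assert np.allclose(y, ref, atol=1e-6)

    def test_curvature_strictly_positive(self, rng):
        # curvature exp(-y) yl + sigma >= sigma > 0 everywhere
        y = rng.standard_normal(100) * 10
        yl = rng.uniform(0, 100, 100)
        curv = np.exp(-np.clip(y, -60, None)) * yl + 0.5
        assert np.all(curv >= 0.5)

    def test_output_nonnegative(self, rng):
        n = 50
        out = A.y_mu_newton(np.zeros(n),
                            rng.uniform(0, 5, n), rng.uniform(0, 5, n),
                            rng.standard_normal(n) * 10, rng.uniform(0, 3, n),
                            1.0, 10)
        assert np.all(out >= 0)


class TestYUpdateBiconvex:
    def _random_inputs(self, rng, n_win=3, n_lor=20):
        t_lam = rng.uniform(0, 5, (n_win, n_lor))
        p_mu = rng.uniform(0, 2, n_lor)
        u_lam = rng.standard_normal((n_win, n_lor)) * 0.1
        u_mu = rng.standard_normal(n_lor) * 0.1
        C = rng.poisson(3.0, (n_win, n_lor)).astype(float)
        return t_lam, p_mu, u_lam, u_mu, C

    def test_objective_nonincreasing_over_alternations(self, rng):
        st = A.make_step_sizes(1.0, 1.0, 2.0, 3.0)
        t_lam, p_mu, u_lam, u_mu, C = self._random_inputs(rng)
        y_lam = np.zeros_like(t_lam)
        y_mu = np.zeros_like(p_mu)
        vals = []
        for _ in range(12):
            y_lam, y_mu = A.y_update_biconvex(
                y_lam, y_mu, t_lam, p_mu, u_lam, u_mu, C, st,
                A.LoopParams(1, 15))
            vals.append(A.inner_objective(y_lam, y_mu, t_lam, p_mu, u_lam,
                                          u_mu, C, st))
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(vals, vals[1:]))

    def test_inner_convergence_doubling_ny(self, rng):
        st = A.make_step_sizes(1.0, 1.0, 2.0, 3.0)
        t_lam, p_mu, u_lam, u_mu, C = self._random_inputs(rng)
        out100 = A.y_update_biconvex(np.zeros_like(t_lam), np.zeros_like(p_mu),
                                     t_lam, p_mu, u_lam, u_mu, C, st,
                                     A.LoopParams(100, 10))
        out200 = A.y_update_biconvex(np.zeros_like(t_lam), np.zeros_like(p_mu),
                                     t_lam, p_mu, u_lam, u_mu, C, st,
                                     A.LoopParams(200, 10))
        for a, b in zip(out100, out200):
            assert np.allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_single_lor_against_2d_grid(self):
        # C = 0, u = 0, one window/LOR: joint minimiser of
        # exp(-ymu) yl + s/2 (yl - t)^2 + s/2 (ymu - p)^2 over a 2D grid
        st = A.make_step_sizes(1.0, 1.0, 1.0, 1.0)  # sigma = tau = 1
        t_lam = np.array([[2.0]])
        p_mu = np.array([1.0])
        zero = np.zeros((1, 1))
        y_lam, y_mu = A.y_update_biconvex(zero.copy(), np.zeros(1), t_lam,
                                          p_mu, zero.copy(), np.zeros(1),
                                          zero.copy(), st, A.LoopParams(200, 20))
        yl_g = np.linspace(0, 4, 801)
        ym_g = np.linspace(0, 4, 801)
        YL, YM = np.meshgrid(yl_g, ym_g, indexing="ij")
        obj = np.exp(-YM) * YL + 0.5 * (YL - 2.0) ** 2 + 0.5 * (YM - 1.0) ** 2
        k = np.unravel_index(obj.argmin(), obj.shape)
        assert y_lam[0, 0] == pytest.approx(yl_g[k[0]], abs=6e-3)
        assert y_mu[0] == pytest.approx(ym_g[k[1]], abs=6e-3)


class TestXUpdate:
    def _toy_ops(self):
        from tofsaa.projectors import SystemOperators

        T = sp.csr_matrix(np.array([[2.0]]))
        P = sp.csr_matrix(np.array([[1.5]]))
        return SystemOperators(P=P, T=T, norm_P=1.5, norm_T=2.0,
                               img_shape=(1, 1))

    def test_zero_gradient_direction_keeps_feasible_point(self, ops16):
        # u = 0 and y = Ax at a feasible (lam, mu): ubar = 0, x unchanged
        st = A.saa_init(ops16)
        lam = A.simplex_project(np.abs(np.sin(np.arange(256.0))).reshape(16, 16),
                                5.0)
        mu = np.abs(np.cos(np.arange(256.0))).reshape(16, 16) * 0.1
        st.lam, st.mu = lam, mu
        st.t_lam = ops16.forward_tof(lam)
        st.p_mu = ops16.forward_x(mu)
        st.y_lam = st.t_lam.copy()
        st.y_mu = st.p_mu.copy()
        steps = A.make_step_sizes(1.0, 1.0, ops16.norm_T, ops16.norm_P)
        out = A.x_update(st, steps, 5.0, ops16)
        assert np.allclose(out.lam, lam, atol=1e-12)
        assert np.allclose(out.mu, mu, atol=1e-12)

    def test_feasibility_after_update(self, ops16, rng):
        st = A.saa_init(ops16)
        st.lam = rng.random((16, 16))
        st.mu = rng.random((16, 16)) * 0.1
        st.t_lam = ops16.forward_tof(st.lam)
        st.p_mu = ops16.forward_x(st.mu)
        st.y_lam = rng.random(st.t_lam.shape)
        st.y_mu = rng.random(st.p_mu.shape)
        st.u_lam = rng.standard_normal(st.t_lam.shape)
        st.u_mu = rng.standard_normal(st.p_mu.shape)
        steps = A.make_step_sizes(1.0, 1.0, ops16.norm_T, ops16.norm_P)
        out = A.x_update(st, steps, 7.5, ops16)
        assert out.lam.sum() == pytest.approx(7.5, rel=1e-10)
        assert out.lam.min() >= 0 and out.mu.min() >= 0

    def test_scalar_problem_matches_hand_solve(self):
        # 1 pixel, 1 LOR: the mu update is mu <- pos(mu - tau P ubar) with
        # ubar = u + sigma (P mu - ymu); lam is pinned to Ntotal
        ops = self._toy_ops()
        st = A.saa_init(ops)
        st.lam[:] = 2.0
        st.mu[:] = 0.5
        st.t_lam = ops.forward_tof(st.lam)
        st.p_mu = ops.forward_x(st.mu)
        st.y_lam[:] = 1.0
        st.y_mu[:] = 0.3
        st.u_lam[:] = 0.2
        st.u_mu[:] = -0.1
        steps = A.make_step_sizes(1.3, 0.9, 2.0, 1.5)
        out = A.x_update(st, steps, 5.0, ops)
        ubar_mu = -0.1 + steps.sigma_mu * (1.5 * 0.5 - 0.3)
        assert out.mu[0, 0] == pytest.approx(max(0.5 - steps.tau_mu * 1.5 * ubar_mu, 0.0))
        assert out.lam[0, 0] == pytest.approx(5.0)


class TestSAAIteration:
    def test_feasibility_invariants(self, problem32):
        p = problem32
        ops = p["ops"]
        Cn, a = normalize_counts(p["c"])
        steps = A.make_step_sizes(1.0, 1.0, ops.norm_T, ops.norm_P)
        params = A.AlgoParams(steps=steps, Ntotal=p["Ntotal"] * a,
                              loops=A.LoopParams(10, 5))
        st = A.saa_init(ops)
        for _ in range(5):
            st = A.admm_saa_iterate(st, Cn, params, ops)
            assert st.lam.sum() == pytest.approx(params.Ntotal, rel=1e-10)
            assert st.lam.min() >= 0 and st.mu.min() >= 0
            assert st.y_lam.min() >= 0 and st.y_mu.min() >= 0

    def test_four_operator_products_per_iteration(self, problem32):
        p = problem32
        ops = p["ops"]
        Cn, a = normalize_counts(p["c"])
        steps = A.make_step_sizes(1.0, 1.0, ops.norm_T, ops.norm_P)
        params = A.AlgoParams(steps=steps, Ntotal=p["Ntotal"] * a,
                              loops=A.LoopParams(5, 3))
        st = A.saa_init(ops)
        st = A.admm_saa_iterate(st, Cn, params, ops)
        ops.reset_counts()
        st = A.admm_saa_iterate(st, Cn, params, ops)
        assert ops.counts == {"P": 1, "T": 1, "PT": 1, "TT": 1}
        ops.reset_counts()

    def test_inner_kkt_residual_small(self, problem32):
        # at the end of the y-update, y_lam solves its quadratic exactly and
        # y_mu has a small psi' residual (or sits at the boundary)
        p = problem32
        ops = p["ops"]
        Cn, a = normalize_counts(p["c"])
        steps = A.make_step_sizes(1.0, 1.0, ops.norm_T, ops.norm_P)
        params = A.AlgoParams(steps=steps, Ntotal=p["Ntotal"] * a,
                              loops=A.LoopParams(30, 10))
        st = A.saa_init(ops)
        for _ in range(3):
            st = A.admm_saa_iterate(st, Cn, params, ops)
        sig_l, sig_m = steps.sigma_lam, steps.sigma_mu
        # the y-update used the pre-dual-ascent multipliers
        u_lam = st.u_lam - sig_l * (st.t_lam - st.y_lam)
        u_mu = st.u_mu - sig_m * (st.p_mu - st.y_mu)
        b = u_lam + sig_l * st.t_lam - np.exp(-st.y_mu)[None, :]
        quad = sig_l * st.y_lam**2 - b * st.y_lam - Cn
        assert np.abs(quad).max() < 1e-6 * max(1.0, np.abs(Cn).max())
        yl = st.y_lam.sum(axis=0)
        Cl = Cn.sum(axis=0)
        gp = -np.exp(-st.y_mu) * yl + Cl - u_mu + sig_m * (st.y_mu - st.p_mu)
        at_bound = (st.y_mu <= 1e-12) & (gp > 0)
        tol = 1e-6 * (np.abs(Cl) + 1.0)
        assert np.all(at_bound | (np.abs(gp) <= tol))

    def test_toy_problem_reaches_constrained_mle(self):
        # 1 pixel, 1 LOR, 1 window: full iteration against the analytic
        # constrained maximum-likelihood solution
        from tofsaa.projectors import SystemOperators

        T = sp.csr_matrix(np.array([[2.0]]))
        P = sp.csr_matrix(np.array([[1.5]]))
        ops = SystemOperators(P=P, T=T, norm_P=1.5, norm_T=2.0, img_shape=(1, 1))
        C = np.array([[3.0]])
        Ntot = 2.5
        steps = A.make_step_sizes(1.0, 1.0, 2.0, 1.5)
        params = A.AlgoParams(steps=steps, Ntotal=Ntot, loops=A.LoopParams(60, 20))
        st = A.saa_init(ops)
        for _ in range(2000):
            st = A.admm_saa_iterate(st, C, params, ops)
        # lam pinned by the constraint; optimal mu solves c = C exactly:
        # exp(-1.5 mu) * 2 * 2.5 = 3
        assert st.lam[0, 0] == pytest.approx(2.5, rel=1e-10)
        assert st.mu[0, 0] == pytest.approx(-np.log(3.0 / 5.0) / 1.5, rel=1e-5)

    def test_noiseless_convergence_and_residual_decay(self):
        # desk-scale noiseless run of the unconstrained solver: activity
        # RMSE drops below 0.05 and the primal residuals ||T lam - y_lam||,
        # ||P mu - y_mu|| end below 1% of their initial values
        from tofsaa.experiments import StudyConfig, build_problem

        prob = build_problem(StudyConfig())
        Cn, a = normalize_counts(prob.c)
        steps = A.make_step_sizes(prob.cfg.rho_lam, prob.cfg.rho_mu,
                                  prob.ops.norm_T, prob.ops.norm_P)
        params = A.AlgoParams(steps=steps, Ntotal=prob.Ntotal * a,
                              loops=A.LoopParams(100, 10))
        st = A.admm_saa_iterate(A.saa_init(prob.ops), Cn, params, prob.ops)
        res0 = (np.linalg.norm(st.t_lam - st.y_lam),
                np.linalg.norm(st.p_mu - st.y_mu))
        for _ in range(1999):
            st = A.admm_saa_iterate(st, Cn, params, prob.ops)
        from tofsaa.metrics import normalized_rmse

        assert normalized_rmse(st.lam / a, prob.act) < 0.05
        assert np.linalg.norm(st.t_lam - st.y_lam) < 0.01 * res0[0]
        assert np.linalg.norm(st.p_mu - st.y_mu) < 0.01 * res0[1]

    def test_scaling_equivariance(self, problem32):
        # runs with (C, params) and (aC, transformed params) produce
        # iterates related by lam -> a lam, u_lam -> u_lam, mu -> mu,
        # u_mu -> a u_mu at every iteration
        p = problem32
        ops = p["ops"]
        a = 7.0
        C1 = p["c"]
        C2 = a * C1
        steps = A.make_step_sizes(1.0, 1.0, ops.norm_T, ops.norm_P)
        params1 = A.AlgoParams(steps=steps, Ntotal=p["Ntotal"],
                               loops=A.LoopParams(10, 5))
        params2 = apply_data_scaling(params1, a)
        s1 = A.saa_init(ops)
        s2 = A.saa_init(ops)
        for it in range(10):
            s1 = A.admm_saa_iterate(s1, C1, params1, ops)
            s2 = A.admm_saa_iterate(s2, C2, params2, ops)

        def rel(x, y):
            return np.abs(x - y).max() / max(np.abs(y).max(), 1e-300)

        assert rel(s2.lam, a * s1.lam) < 1e-8
        assert rel(s2.mu, s1.mu) < 1e-8
        assert rel(s2.y_lam, a * s1.y_lam) < 1e-8
        assert rel(s2.y_mu, s1.y_mu) < 1e-8
        assert rel(s2.u_lam, s1.u_lam) < 1e-8
        assert rel(s2.u_mu, a * s1.u_mu) < 1e-8
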