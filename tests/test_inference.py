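"""Unit tests for the block updates, each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import optimize

from vmpln import (
    CountData,
    MplnParams,
    PriorEdgeSet,
    VariationalState,
    elbo,
    fit,
    initialize,
    penalized_objective,
    simulate_mpln,
    generate_graph,
)
from vmpln.inference import (
    AdmmConfig,
    FitConfig,
    _solve_glasso,
    normalize_counts,
    update_M_admm,
    update_P,
    update_S,
    update_Theta,
    update_mu,
    update_pi,
    weighted_scatter,
)

from conftest import make_instance, random_spd


def dense_newton_m_oracle(y, l, S, mu, Theta, tol=1e-12, max_iter=200):
    """Full p-dimensional Newton solve of the joint M-subproblem for one cell:
    minimize (m-mu)^T Theta (m-mu)/2 + sum_j [-y_j m_j + l e^{m_j + S_j/2}]."""
    m = np.log1p(y / l)  # Poisson-MLE-ish start
    for _ in range(max_iter):
        e = l * np.exp(m + 0.5 * S)
        grad = Theta @ (m - mu) - y + e
        hess = Theta + np.diag(e)
        step = np.linalg.solve(hess, grad)
        # damped Newton: backtrack until the objective decreases
        t = 1.0
        def obj(x):
            return 0.5 * (x - mu) @ Theta @ (x - mu) + np.sum(
                -y * x + l * np.exp(x + 0.5 * S)
            )
        base = obj(m)
        while obj(m - t * step) > base and t > 1e-8:
            t /= 2
        m = m - t * step
        if np.max(np.abs(grad)) < tol:
            break
    return m


class TestInit:
    def test_initial_variances(self, rng):
        data, _, _ = make_instance(rng, n=12, p=4, G=2)
        _, state = initialize(data, G=2, seed=0)
        assert np.all(state.S == 1e-5)

    def test_single_group_hard_assignment_and_mean(self, rng):
        data, _, _ = make_instance(rng, n=8, p=4, G=1)
        params, state = initialize(data, G=1, seed=0)
        assert np.all(state.P == 1.0)
        Y_tilde, _ = normalize_counts(data.Y)
        assert np.allclose(params.mu[0], Y_tilde.mean(axis=0))
        assert np.allclose(state.M[0], Y_tilde)

    def test_separated_blobs_recovered(self):
        # two populations shifted by 5 in latent mean: initialization labels
        # must match the truth almost perfectly (up to label permutation)
        from vmpln import GraphSpec

        # unit-precision latent noise; shift half the genes by 5 (a uniform
        # shift over all genes would be absorbed by library-size normalization)
        graphs = [
            GraphSpec(kind="random", p=12, Theta=np.eye(12),
                      adjacency=np.zeros((12, 12), dtype=int))
            for _ in range(2)
        ]
        # baseline intercept 2 keeps per-cell depth high enough that the
        # compositional profiles of the two blobs do not overlap by chance
        mu2 = 2.0 + np.concatenate([np.full(6, 5.0), np.zeros(6)])
        mus = np.vstack([np.full(12, 2.0), mu2])
        ds = simulate_mpln(graphs, mus, [0.5, 0.5], 300, seed=7)
        _, state = initialize(ds.data, G=2, seed=0)
        lab = state.labels()
        agree = max(
            np.mean(lab == ds.true_labels), np.mean(lab == 1 - ds.true_labels)
        )
        assert agree >= 0.99


class TestUpdateP:
    def test_single_group_is_all_ones(self, rng):
        data, params, state = make_instance(rng, G=1)
        P = update_P(data, params, state)
        assert np.allclose(P, 1.0)

    def test_symmetric_groups_split_evenly(self, rng):
        data, params, state = make_instance(rng, G=2)
        # make both groups identical in every parameter
        params = MplnParams(
            pi=[0.5, 0.5],
            mu=np.tile(params.mu[:1], (2, 1)),
            Theta=np.tile(params.Theta[:1], (2, 1, 1)),
        )
        state = VariationalState(
            M=np.tile(state.M[:1], (2, 1, 1)),
            S=np.tile(state.S[:1], (2, 1, 1)),
            P=state.P,
        )
        P = update_P(data, params, state)
        assert np.allclose(P, 0.5)

    def test_matches_simplex_grid_search(self, rng):
        # the updated row must maximize the ELBO over the probability simplex
        data, params, state = make_instance(rng, n=2, p=2, G=2)
        P = update_P(data, params, state)
        for i in range(2):
            best_val, best_q = -np.inf, None
            for q in np.arange(0.0, 1.0 + 1e-9, 1e-3):
                cand = state.P.copy()
                cand[i] = [q, 1.0 - q]
                trial = VariationalState(M=state.M, S=state.S, P=cand)
                val, _ = elbo(data, params, trial)
                if val > best_val:
                    best_val, best_q = val, q
            assert P[i, 0] == pytest.approx(best_q, abs=2e-3)


class TestUpdatePiMu:
    def test_pi_from_hard_labels(self):
        P = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        assert np.allclose(update_pi(P), [2 / 3, 1 / 3])

    def test_pi_uniform_fixed_point(self):
        P = np.full((5, 4), 0.25)
        assert np.allclose(update_pi(P), 0.25)

    def test_pi_matches_column_means(self, rng):
        P = rng.dirichlet(np.ones(3), size=10)
        assert np.allclose(update_pi(P), P.mean(axis=0))

    def test_mu_hard_labels_are_cluster_means(self, rng):
        M = rng.normal(size=(2, 6, 3))
        P = np.zeros((6, 2))
        P[:4, 0] = 1
        P[4:, 1] = 1
        mu = update_mu(P, M)
        assert np.allclose(mu[0], M[0, :4].mean(axis=0))
        assert np.allclose(mu[1], M[1, 4:].mean(axis=0))

    def test_mu_constant_rows(self, rng):
        M = np.tile(np.array([1.0, -2.0, 0.3]), (1, 5, 1))
        P = np.ones((5, 1))
        assert np.allclose(update_mu(P, M)[0], [1.0, -2.0, 0.3])

    def test_mu_weighted_mean_oracle(self, rng):
        M = rng.normal(size=(2, 7, 3))
        P = rng.dirichlet(np.ones(2), size=7)
        mu = update_mu(P, M)
        for g in range(2):
            expected = np.average(M[g], axis=0, weights=P[:, g])
            assert np.allclose(mu[g], expected)

    def test_mu_empty_group_raises(self):
        P = np.column_stack([np.ones(3), np.zeros(3)])
        with pytest.raises(RuntimeError, match="group 1"):
            update_mu(P, np.zeros((2, 3, 2)))


class TestUpdateS:
    def test_stationarity_condition_holds(self, rng):
        data, params, state = make_instance(rng, n=3, p=3, G=2)
        S = update_S(data, params, state)
        for g in range(2):
            lhs = data.l[:, None] * np.exp(state.M[g] + 0.5 * S[g]) + np.diag(
                params.Theta[g]
            )
            assert np.allclose(lhs, 1.0 / S[g], rtol=1e-7)

    def test_vanishing_rate_limit(self, rng):
        # l e^M -> 0 makes the stationarity equation 1/S = Theta_jj
        data, params, state = make_instance(rng, n=2, p=2, G=1)
        state.M[:] = -40.0
        S = update_S(data, params, state)
        expected = 1.0 / np.diag(params.Theta[0])
        assert np.allclose(S[0], expected[None, :], rtol=1e-6)

    def test_matches_golden_section_minimizer(self):
        # M=0, l=1, Theta_jj=1: compare to a 1-D search on the objective
        # F1 - log(S)/2 + Theta_jj S / 2
        data = CountData(Y=[[0]], l=[1.0])
        params = MplnParams(pi=[1.0], mu=[[0.0]], Theta=[[[1.0]]])
        state = VariationalState(
            M=np.zeros((1, 1, 1)), S=np.full((1, 1, 1), 0.5), P=np.ones((1, 1))
        )
        S = update_S(data, params, state)
        res = optimize.minimize_scalar(
            lambda s: np.exp(0.5 * s) - 0.5 * np.log(s) + 0.5 * s,
            bounds=(1e-8, 10.0), method="bounded",
            options={"xatol": 1e-12},
        )
        # comparison-based 1-D searches resolve x only to ~sqrt(eps)*x
        assert S[0, 0, 0] == pytest.approx(res.x, abs=1e-7)

    def test_monotone_in_precision_diagonal(self):
        # larger Theta_jj must strictly shrink the optimal variance
        data = CountData(Y=[[1]], l=[1.0])
        prev = np.inf
        for theta in [0.2, 0.5, 1.0, 2.0, 5.0]:
            params = MplnParams(pi=[1.0], mu=[[0.0]], Theta=[[[theta]]])
            state = VariationalState(
                M=np.zeros((1, 1, 1)), S=np.full((1, 1, 1), 0.5), P=np.ones((1, 1))
            )
            s = update_S(data, params, state)[0, 0, 0]
            assert s < prev
            prev = s


class TestUpdateMAdmm:
    def _tight(self):
        return AdmmConfig(primal_tol=1e-9, dual_tol=1e-9, max_iter=2000)

    def test_diagonal_theta_decouples(self, rng):
        data, params, state = make_instance(rng, n=3, p=3, G=1)
        params = MplnParams(
            pi=params.pi, mu=params.mu,
            Theta=np.stack([np.diag(rng.uniform(0.5, 2.0, 3))]),
        )
        M = update_M_admm(data, params, state, self._tight())
        # oracle: p independent scalar solves via brentq on the gradient
        for i in range(3):
            for j in range(3):
                th = params.Theta[0, j, j]
                mu_j = params.mu[0, j]
                y = data.Y[i, j]
                lam = data.l[i] * np.exp(0.5 * state.S[0, i, j])

                def grad(m):
                    return th * (m - mu_j) - y + lam * np.exp(m)

                root = optimize.brentq(grad, -50, 30, xtol=1e-12)
                assert M[0, i, j] == pytest.approx(root, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_newton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data, params, state = make_instance(rng, n=4, p=3, G=2)
        M = update_M_admm(data, params, state, self._tight())
        for g in range(2):
            for i in range(4):
                oracle = dense_newton_m_oracle(
                    data.Y[i], data.l[i], state.S[g, i], params.mu[g],
                    params.Theta[g],
                )
                assert np.allclose(M[g, i], oracle, atol=1e-6)

    def test_poisson_mle_limit(self):
        # huge counts, l=1, S ~ 0, Theta -> 0: solution approaches log Y
        Y = np.array([[2000.0, 5000.0]])
        data = CountData(Y=Y, l=[1.0])
        params = MplnParams(pi=[1.0], mu=[[0.0, 0.0]], Theta=[np.eye(2) * 1e-8])
        state = VariationalState(
            M=np.zeros((1, 1, 2)), S=np.full((1, 1, 2), 1e-10), P=np.ones((1, 1))
        )
        M = update_M_admm(data, params, state, self._tight())
        assert np.allclose(M[0, 0], np.log(Y[0]), atol=1e-3)

    def test_one_factorization_per_group(self, rng):
        data, params, state = make_instance(rng, n=3, p=3, G=3)
        calls = []
        update_M_admm(data, params, state, AdmmConfig(), on_factorize=calls.append)
        assert calls == [0, 1, 2]


class TestUpdateTheta:
    def test_infinite_penalty_gives_diagonal_inverse_variances(self, rng):
        data, params, state = make_instance(rng, n=6, p=3, G=1)
        Theta = update_Theta(state.P, state.M, state.S, params.mu, 1e6)
        sigma = weighted_scatter(state.P[:, 0], state.M[0], state.S[0], params.mu[0])
        assert np.allclose(Theta[0], np.diag(1.0 / np.diag(sigma)), rtol=1e-4)

    def test_identity_scatter_zero_penalty(self):
        prec = _solve_glasso(np.eye(4), 0.0, None)
        assert np.allclose(prec, np.eye(4), atol=1e-8)

    def test_first_order_conditions(self, rng):
        # glasso KKT: |Sigma - Theta^{-1}| <= alpha off-diagonal, equality
        # with the right sign where Theta is nonzero, exact on the diagonal
        cov = random_spd(rng, 4)
        alpha = 0.1 * np.abs(cov - np.diag(np.diag(cov))).max()
        prec = _solve_glasso(cov, alpha, None, tol=1e-10)
        W = np.linalg.inv(prec)
        assert np.allclose(np.diag(W), np.diag(cov), atol=1e-4)
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                r = cov[a, b] - W[a, b]
                if abs(prec[a, b]) > 1e-8:
                    assert r == pytest.approx(
                        -np.sign(prec[a, b]) * alpha, abs=1e-4
                    )
                else:
                    assert abs(r) <= alpha + 1e-4

    def test_prior_zero_edges_are_respected(self, rng):
        data, params, state = make_instance(rng, n=8, p=4, G=1)
        prior = PriorEdgeSet(zero_edges=frozenset({(0, 3), (1, 2)}))
        Theta = update_Theta(
            state.P, state.M, state.S, params.mu, 0.5, prior_edges=prior
        )
        assert Theta[0, 0, 3] == 0.0 and Theta[0, 3, 0] == 0.0
        assert Theta[0, 1, 2] == 0.0 and Theta[0, 2, 1] == 0.0
        np.linalg.cholesky(Theta[0])  # still PD

    def test_constrained_solver_agrees_with_sklearn_when_unconstrained(self, rng):
        from vmpln.inference import _glasso_admm

        cov = random_spd(rng, 4)
        alpha = 0.05 * np.abs(cov).max()
        pen = np.full((4, 4), alpha)
        np.fill_diagonal(pen, 0.0)
        ours = _glasso_admm(cov, pen, tol=1e-10, max_iter=5000)
        from sklearn.covariance import graphical_lasso

        _, ref = graphical_lasso(cov, alpha=alpha, tol=1e-10, max_iter=500)
        assert np.allclose(ours, ref, atol=1e-4)


class TestFit:
    def test_single_gene_parameter_recovery(self):
        graphs = [generate_graph("random", 10, seed=0)]
        # p=1 version built directly: PLN with mu=1, Theta=1, l=1
        n = 2000
        rng = np.random.default_rng(5)
        X = rng.normal(1.0, 1.0, size=n)
        Y = rng.poisson(np.exp(X))[:, None]
        data = CountData(Y=Y, l=np.ones(n))
        res = fit(data, FitConfig(G=1, lambda_n=0.1, seed=0, max_outer_iter=60))
        se = 1.0 / np.sqrt(n)
        assert abs(res.params.mu[0, 0] - 1.0) < 3 * se

    def test_two_groups_recovered(self):
        graphs = [generate_graph("random", 12, seed=s) for s in (0, 1)]
        mus = np.vstack([np.zeros(12), np.full(12, 3.0)])
        ds = simulate_mpln(graphs, mus, [0.5, 0.5], 240, seed=3)
        res = fit(ds.data, FitConfig(G=2, lambda_n=2.0, seed=0, max_outer_iter=15))
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(ds.true_labels, res.cluster_labels) > 0.95
        assert np.all(np.diff(res.objective_trace) <= 1e-6)

    def test_deterministic_given_seed(self, rng):
        data, _, _ = make_instance(rng, n=30, p=5, G=2, rate=3.0)
        cfg = FitConfig(G=2, lambda_n=1.0, seed=11, max_outer_iter=5)
        r1 = fit(data, cfg)
        r2 = fit(data, cfg)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)
        assert np.array_equal(r1.params.Theta, r2.params.Theta)

    def test_blockwise_objective_monotone(self):
        # every individual block update must not increase the penalized
        # objective (beyond solver tolerance)
        rng = np.random.default_rng(0)
        data, params, state = make_instance(rng, n=10, p=4, G=2, rate=3.0)
        lam = 0.5
        admm = AdmmConfig(primal_tol=1e-8, dual_tol=1e-8, max_iter=1000)
        obj = penalized_objective(data, params, state, lam)
        for sweep in range(3):
            state.P = update_P(data, params, state)
            o = penalized_objective(data, params, state, lam)
            assert o <= obj + 1e-6
            obj = o
            params = MplnParams(pi=update_pi(state.P), mu=params.mu, Theta=params.Theta)
            o = penalized_objective(data, params, state, lam)
            assert o <= obj + 1e-6
            obj = o
            state.M = update_M_admm(data, params, state, admm)
            o = penalized_objective(data, params, state, lam)
            assert o <= obj + 1e-6
            obj = o
            state.S = update_S(data, params, state, admm)
            o = penalized_objective(data, params, state, lam)
            assert o <= obj + 1e-6
            obj = o
            params = MplnParams(pi=params.pi, mu=update_mu(state.P, state.M), Theta=params.Theta)
            o = penalized_objective(data, params, state, lam)
            assert o <= obj + 1e-6
            obj = o
            params = MplnParams(
                pi=params.pi, mu=params.mu,
                Theta=update_Theta(state.P, state.M, state.S, params.mu, lam, tol=1e-10),
            )
            o = penalized_objective(data, params, state, lam)
            assert o <= obj + 1e-6
            obj = o
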