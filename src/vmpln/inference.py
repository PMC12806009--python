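"""Block-wise variational descent for the mixture Poisson log-normal model.

The penalized negative ELBO is driven down by cycling through exact or
convex block updates:

* ``P`` (responsibilities), ``pi`` and ``mu`` have closed forms;
* each variance ``S_g,ij`` solves a scalar stationarity equation by
  safeguarded Newton iteration;
* the variational means ``M_g`` solve n coupled p-dimensional convex
  problems per group via ADMM, so that only one ``(rho I + Theta_g)``
  factorization is needed per group per sweep;
* each precision ``Theta_g`` solves a graphical-lasso problem on the
  responsibility-weighted scatter matrix.

Every accepted block update is a (near-)exact minimizer of its convex
subproblem, so the penalized objective is non-increasing along the run up
to solver tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.covariance import graphical_lasso
from sklearn.decomposition import PCA

from .core_model import (
    CountData,
    MplnParams,
    PriorEdgeSet,
    VariationalState,
    elbo,
    penalized_objective,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AdmmConfig",
    "FitConfig",
    "FitResult",
    "normalize_counts",
    "initialize",
    "update_P",
    "update_pi",
    "update_mu",
    "update_S",
    "update_M_admm",
    "update_Theta",
    "fit",
]


@dataclass
class AdmmConfig:
    """Settings for the ADMM solver of the M-subproblem.

    ``rho`` is the (fixed) ADMM step size; keeping it constant preserves
    the one-factorization-per-group guarantee.
    """

    rho: float | str = "auto"
    max_iter: int = 200
    primal_tol: float = 1e-6
    dual_tol: float = 1e-6
    newton_max_iter: int = 50
    newton_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not isinstance(self.rho, str) and self.rho <= 0:
            raise ValueError("rho must be positive")
        if isinstance(self.rho, str) and self.rho != "auto":
            raise ValueError(f"unknown rho spec {self.rho!r}")
        if min(self.primal_tol, self.dual_tol, self.newton_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1 or self.newton_max_iter < 1:
            raise ValueError("iteration limits must be >= 1")

    def resolve_rho(self, Theta: np.ndarray) -> float:
        """Step size for one group's sweep.

        'auto' uses the geometric mean of the extreme eigenvalues of
        Theta_g, the classical choice minimizing the ADMM contraction
        factor for a quadratic coupling.  Chosen once per group per sweep,
        so each sweep still needs exactly one factorization per group.
        """
        if isinstance(self.rho, str):
            ev = np.linalg.eigvalsh(Theta)
            return float(np.sqrt(max(ev[0], 1e-8) * max(ev[-1], 1e-8)))
        return float(self.rho)


@dataclass
class FitConfig:
    """Settings for the outer block-descent loop."""

    G: int = 1
    lambda_n: float | np.ndarray | str = "auto"
    max_outer_iter: int = 100
    elbo_rel_tol: float = 1e-6
    param_tol: float = 1e-4
    n_kmeans_starts: int = 3
    seed: int = 0
    prior_edges: PriorEdgeSet | None = None
    pca_dim: int = 50
    admm: AdmmConfig = field(default_factory=AdmmConfig)
    glasso_tol: float = 1e-8
    callback: Callable[["FitResult"], None] | None = None

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if min(self.elbo_rel_tol, self.param_tol) <= 0:
            raise ValueError("tolerances must be positive")

    def resolve_lambda(self, n: int, p: int) -> np.ndarray:
        """Per-group penalty vector; 'auto' uses a sqrt(log p / n) scaling."""
        if isinstance(self.lambda_n, str):
            if self.lambda_n != "auto":
                raise ValueError(f"unknown lambda_n spec {self.lambda_n!r}")
            lam = 0.25 * n * np.sqrt(np.log(max(p, 2)) / n)
            return np.full(self.G, lam)
        lam = np.broadcast_to(np.asarray(self.lambda_n, dtype=float), (self.G,)).copy()
        if np.any(lam < 0):
            raise ValueError("lambda_n must be non-negative")
        return lam


@dataclass
class FitResult:
    """Converged parameters, variational state and diagnostics of one fit."""

    params: MplnParams
    state: VariationalState
    elbo_trace: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    cluster_labels: np.ndarray
    lambda_n: np.ndarray
    per_group_elbo: np.ndarray
    icl: np.ndarray | None = None
    selected_lambda: np.ndarray | None = None


def normalize_counts(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log1p counts-per-10k normalization.

    Returns ``(Y_tilde, l_hat)`` with ``l_hat_i = sum_j Y_ij / 1e4`` and
    ``Y_tilde_ij = log(Y_ij / l_hat_i + 1)``.  All-zero cells get a zero
    normalized row (the limit of the formula for any positive size).
    """
    Y = np.asarray(Y, dtype=float)
    l_hat = Y.sum(axis=1) / 1e4
    safe = np.where(l_hat > 0, l_hat, 1.0)
    return np.log1p(Y / safe[:, None]), l_hat


def _init_theta_glasso(cov: np.ndarray, alpha: float = 1e-6) -> np.ndarray:
    """Near-unpenalized glasso solve used for the Theta starting value."""
    p = cov.shape[0]
    cov_r = cov + 1e-8 * np.eye(p)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = graphical_lasso(cov_r, alpha=alpha, max_iter=100)
        return 0.5 * (prec + prec.T)
    except (FloatingPointError, linalg.LinAlgError, ValueError):
        # alpha -> 0 limit of the glasso: ridge-regularized inverse
        return np.linalg.inv(cov + alpha * np.eye(p))


def initialize(
    data: CountData,
    G: int,
    seed: int,
    n_kmeans_starts: int = 3,
    pca_dim: int = 50,
) -> tuple[MplnParams, VariationalState]:
    """PCA + K-means initialization of parameters and variational state.

    Cells are clustered in PCA space of the log-normalized counts; the
    initial responsibilities are the hard K-means labels, ``M`` starts at
    the normalized matrix, ``S`` at 1e-5, and each ``Theta_g`` at a
    near-unpenalized glasso solve of the responsibility-weighted second
    moment of ``M``.
    """
    n, p = data.Y.shape
    if G > n:
        raise ValueError("G cannot exceed the number of cells")
    Y_tilde, _ = normalize_counts(data.Y)
    d = min(pca_dim, p - 1, n - 1)
    if d >= 1 and d < p:
        emb = PCA(n_components=d, svd_solver="full").fit_transform(Y_tilde)
    else:
        emb = Y_tilde
    labels = None
    for attempt in range(5):
        km = KMeans(
            n_clusters=G, n_init=n_kmeans_starts, random_state=seed + attempt
        ).fit(emb)
        cand = km.labels_
        if len(np.unique(cand)) == G:
            labels = cand
            break
    if labels is None:
        raise RuntimeError(f"K-means produced an empty cluster for G={G} after 5 reseeds")

    P0 = np.zeros((n, G))
    P0[np.arange(n), labels] = 1.0
    M0 = np.broadcast_to(Y_tilde, (G, n, p)).copy()
    S0 = np.full((G, n, p), 1e-5)
    pi0 = P0.mean(axis=0)
    ng = P0.sum(axis=0)
    mu0 = (P0.T @ Y_tilde) / ng[:, None]
    Theta0 = np.empty((G, p, p))
    for g in range(G):
        # second moment of M rows (plus the S diagonal), as the initializer
        # prescribes; uncentered on purpose — it only seeds the glasso
        sigma0 = (Y_tilde.T * P0[:, g]) @ Y_tilde / ng[g] + np.diag(
            np.full(p, 1e-5)
        )
        Theta0[g] = _init_theta_glasso(sigma0)
    params = MplnParams(pi=pi0, mu=mu0, Theta=Theta0)
    state = VariationalState(M=M0, S=S0, P=P0)
    return params, state


def update_P(data: CountData, params: MplnParams, state: VariationalState) -> np.ndarray:
    """Closed-form responsibility update (row-wise softmax of group scores)."""
    n, p = data.Y.shape
    G = params.G
    log_l = np.log(data.l)
    logits = np.empty((n, G))
    for g in range(G):
        Mg, Sg = state.M[g], state.S[g]
        mu_g, Theta_g = params.mu[g], params.Theta[g]
        sign, logdet = np.linalg.slogdet(Theta_g)
        if sign <= 0:
            raise np.linalg.LinAlgError(f"Theta of group {g} is not positive definite")
        cellwise = (
            data.Y * Mg - np.exp(Mg + 0.5 * Sg + log_l[:, None]) + 0.5 * np.log(Sg)
        ).sum(axis=1)
        D = Mg - mu_g[None, :]
        quad = np.einsum("ij,jk,ik->i", D, Theta_g, D)
        trace = quad + Sg @ np.diag(Theta_g)
        logits[:, g] = np.log(params.pi[g]) + cellwise + 0.5 * logdet - 0.5 * trace
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    return P


def update_pi(P: np.ndarray) -> np.ndarray:
    """Mixture proportions: column means of the responsibilities."""
    return np.asarray(P, dtype=float).mean(axis=0)


def update_mu(P: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Group means: responsibility-weighted means of the variational means."""
    P = np.asarray(P, dtype=float)
    M = np.asarray(M, dtype=float)
    ng = P.sum(axis=0)
    if np.any(ng <= 0):
        g = int(np.flatnonzero(ng <= 0)[0])
        raise RuntimeError(f"group {g} has zero total responsibility")
    G = P.shape[1]
    return np.stack([(P[:, g] @ M[g]) / ng[g] for g in range(G)])


def update_S(
    data: CountData,
    params: MplnParams,
    state: VariationalState,
    cfg: AdmmConfig | None = None,
) -> np.ndarray:
    """Variational variances via elementwise safeguarded Newton iteration.

    Each ``S_g,ij`` solves the stationarity condition

        l_i exp(M_g,ij + S/2) + Theta_g,jj = 1/S,

    whose left side is increasing and right side decreasing in ``S``, so
    the root is unique and lies in ``(0, 1/Theta_g,jj)``.  Newton runs in
    log(S); entries that fail to converge fall back to bisection.
    """
    cfg = cfg or AdmmConfig()
    G, n, p = state.M.shape
    log_l = np.log(data.l)
    S_new = np.empty_like(state.S)
    for g in range(G):
        theta_d = np.diag(params.Theta[g])[None, :]  # (1, p) broadcast over cells
        if np.any(theta_d <= 0):
            raise ValueError(f"Theta of group {g} has a non-positive diagonal")
        a = np.exp(state.M[g] + log_l[:, None])  # l_i exp(M)
        upper = 1.0 / theta_d
        s = np.minimum(state.S[g], 0.9 * upper)
        t = np.log(s)
        converged = np.zeros((n, p), dtype=bool)
        for _ in range(cfg.newton_max_iter):
            es = np.exp(t)
            g_val = a * np.exp(0.5 * es) + theta_d - np.exp(-t)
            g_prime = a * np.exp(0.5 * es) * 0.5 * es + np.exp(-t)
            step = np.clip(g_val / g_prime, -2.0, 2.0)
            t = t - step
            converged = np.abs(step) < cfg.newton_tol
            if converged.all():
                break
        if not converged.all():
            bad = ~converged
            lo = np.full(bad.sum(), -40.0)
            hi = np.log(np.broadcast_to(upper, (n, p))[bad])
            ab = a[bad]
            tb = np.broadcast_to(theta_d, (n, p))[bad]
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                val = ab * np.exp(0.5 * np.exp(mid)) + tb - np.exp(-mid)
                hi = np.where(val > 0, mid, hi)
                lo = np.where(val > 0, lo, mid)
            t[bad] = 0.5 * (lo + hi)
        S_new[g] = np.exp(t)
    return S_new


def _m_objective(
    M: np.ndarray,
    Y: np.ndarray,
    log_l: np.ndarray,
    S: np.ndarray,
    mu: np.ndarray,
    Theta: np.ndarray,
) -> np.ndarray:
    """Per-cell value of the M-subproblem objective L1 + sum_j L2."""
    D = M - mu[None, :]
    quad = 0.5 * np.einsum("ij,jk,ik->i", D, Theta, D)
    pois = (-Y * M + np.exp(M + 0.5 * S + log_l[:, None])).sum(axis=1)
    return quad + pois


def update_M_admm(
    data: CountData,
    params: MplnParams,
    state: VariationalState,
    cfg: AdmmConfig | None = None,
    on_factorize: Callable[[int], None] | None = None,
) -> np.ndarray:
    """Variational means via ADMM, one matrix factorization per group.

    For every cell the subproblem couples the p coordinates only through
    the quadratic ``(M - mu)^T Theta (M - mu) / 2``; splitting that term
    onto an auxiliary matrix ``N`` leaves a separable exponential part for
    ``M`` (p scalar Newton solves) and a linear solve in ``(rho I + Theta)``
    for ``N``, whose Cholesky factor is shared by all n cells of a group.
    """
    cfg = cfg or AdmmConfig()
    G, n, p = state.M.shape
    Y = data.Y
    log_l = np.log(data.l)
    M_out = np.empty_like(state.M)
    for g in range(G):
        Theta = params.Theta[g]
        mu = params.mu[g]
        S = state.S[g]
        rho = cfg.resolve_rho(Theta)
        factor = linalg.cho_factor(rho * np.eye(p) + Theta, lower=True)
        if on_factorize is not None:
            on_factorize(g)
        theta_mu = Theta @ mu  # (p,)

        M = state.M[g].copy()
        N = M.copy()
        # dual warm start: at the fixed point alpha = Theta (N - mu), so the
        # previous M (usually close to the new solution) seeds alpha well
        alpha = (M - mu[None, :]) @ Theta
        a = np.exp(0.5 * S + log_l[:, None])  # l_i exp(S/2), fixed in the sweep
        converged = False
        for _ in range(cfg.max_iter):
            # step 1: elementwise Newton on -Y m + a e^m + alpha m + rho/2 (m-N)^2
            for _ in range(cfg.newton_max_iter):
                e = a * np.exp(np.clip(M, -700.0, 60.0))
                grad = -Y + e + alpha + rho * (M - N)
                hess = e + rho
                step = np.clip(grad / hess, -4.0, 4.0)
                M = M - step
                if np.max(np.abs(step)) < cfg.newton_tol:
                    break
            # step 2: (rho I + Theta) N = rho M + alpha + Theta mu
            rhs = rho * M + alpha + theta_mu[None, :]
            N_old = N
            N = linalg.cho_solve(factor, rhs.T).T
            # step 3: dual ascent
            alpha = alpha + rho * (M - N)
            primal = np.max(np.abs(M - N))
            dual = rho * np.max(np.abs(N - N_old))
            if primal < cfg.primal_tol and dual < cfg.dual_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"ADMM for group {g} did not reach tolerance in {cfg.max_iter} "
                "iterations; keeping best iterate",
                RuntimeWarning,
            )
        # never accept a row that worsens its own objective
        obj_new = _m_objective(M, Y, log_l, S, mu, Theta)
        obj_old = _m_objective(state.M[g], Y, log_l, S, mu, Theta)
        worse = obj_new > obj_old
        if np.any(worse):
            M = np.where(worse[:, None], state.M[g], M)
        M_out[g] = M
    return M_out


def _soft_threshold(x: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _glasso_admm(
    cov: np.ndarray,
    penalty: np.ndarray,
    rho: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> np.ndarray:
    """Graphical lasso with an elementwise penalty matrix, solved by ADMM.

    Minimizes ``-log det(Theta) + tr(cov Theta) + sum |penalty * Theta|``.
    Used when some entries carry an (effectively infinite) prior-zero
    penalty, which scalar-penalty solvers cannot express.
    """
    p = cov.shape[0]
    Theta = np.linalg.inv(cov + 1e-3 * np.eye(p))
    W = Theta.copy()
    U = np.zeros((p, p))
    for _ in range(max_iter):
        # Theta-step: eigen decomposition of rho (W - U) - cov
        A = rho * (W - U) - cov
        A = 0.5 * (A + A.T)
        d, V = np.linalg.eigh(A)
        theta_d = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        Theta = (V * theta_d) @ V.T
        W_old = W
        W = _soft_threshold(Theta + U, penalty / rho)
        W = 0.5 * (W + W.T)
        U = U + Theta - W
        primal = np.max(np.abs(Theta - W))
        dual = rho * np.max(np.abs(W - W_old))
        if primal < tol and dual < tol:
            break
    return W


def _solve_glasso(
    cov: np.ndarray,
    alpha: float,
    prior_mask: np.ndarray | None,
    tol: float = 1e-8,
) -> np.ndarray:
    """One group's precision subproblem, with up to 3 diagonal-repair retries."""
    p = cov.shape[0]
    if p == 1:  # no off-diagonal: the subproblem is plain inversion
        return np.array([[1.0 / max(cov[0, 0], 1e-12)]])
    for attempt in range(4):
        cov_try = cov + attempt * 1e-6 * np.eye(p)
        try:
            if prior_mask is not None and prior_mask.any():
                penalty = np.full((p, p), alpha)
                np.fill_diagonal(penalty, 0.0)
                penalty[prior_mask] = 1e12 * max(alpha, 1.0)
                prec = _glasso_admm(cov_try, penalty, tol=tol)
                prec[prior_mask] = 0.0  # exact zeroing of constrained entries
                np.linalg.cholesky(prec)  # PD check
            elif alpha <= 1e-10:
                prec = np.linalg.inv(cov_try + 1e-10 * np.eye(p))
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, prec = graphical_lasso(
                        cov_try, alpha=alpha, max_iter=200, tol=tol, enet_tol=tol
                    )
            return 0.5 * (prec + prec.T)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise RuntimeError(f"glasso failed after diagonal-repair retries: {last}")


def weighted_scatter(
    P_col: np.ndarray, M: np.ndarray, S: np.ndarray, mu: np.ndarray
) -> np.ndarray:
    """Responsibility-weighted average of per-cell scatter matrices.

    ``Sigma_bar_g = sum_i P_ig [(M_i - mu)(M_i - mu)^T + D(S_i)] / sum_i P_ig``.
    """
    ng = P_col.sum()
    if ng <= 0:
        raise RuntimeError("group has zero total responsibility")
    D = M - mu[None, :]
    sig = (D.T * P_col) @ D + np.diag(P_col @ S)
    return sig / ng


def update_Theta(
    P: np.ndarray,
    M: np.ndarray,
    S: np.ndarray,
    mu: np.ndarray,
    lambda_n: float | np.ndarray,
    prior_edges: PriorEdgeSet | None = None,
    tol: float = 1e-8,
) -> np.ndarray:
    """Precision matrices via G independent graphical-lasso solves.

    Matching the ELBO terms of group g gives the subproblem

        min_Theta -log det Theta + tr(Sigma_bar_g Theta)
                  + (2 lambda_g / n_g) ||Theta||_{1,off}

    with ``n_g = sum_i P_ig``, optionally with prior-zero constraints.
    """
    G = P.shape[1]
    p = M.shape[2]
    lam = np.broadcast_to(np.asarray(lambda_n, dtype=float), (G,))
    mask = prior_edges.mask(p) if prior_edges is not None else None
    Theta = np.empty((G, p, p))
    for g in range(G):
        ng = P[:, g].sum()
        sigma = weighted_scatter(P[:, g], M[g], S[g], mu[g])
        Theta[g] = _solve_glasso(sigma, 2.0 * lam[g] / ng, mask, tol=tol)
    return Theta


def fit(
    data: CountData,
    cfg: FitConfig,
    init: tuple[MplnParams, VariationalState] | None = None,
) -> FitResult:
    """Run the full block-descent until the penalized objective stabilizes.

    Updates follow the fixed order P, pi, M, S, mu, Theta.  Terminates when
    the relative objective change drops below ``elbo_rel_tol`` and the
    largest parameter change below ``param_tol``, or at ``max_outer_iter``.
    Deterministic given ``cfg.seed``.  ``init`` warm-starts from an earlier
    solution (e.g. the previous point of a penalty path) instead of the
    PCA + K-means initialization.
    """
    n, p = data.Y.shape
    lam = cfg.resolve_lambda(n, p)
    if init is not None:
        prev_params, prev_state = init
        params = MplnParams(
            pi=prev_params.pi.copy(),
            mu=prev_params.mu.copy(),
            Theta=prev_params.Theta.copy(),
        )
        state = VariationalState(
            M=prev_state.M.copy(), S=prev_state.S.copy(), P=prev_state.P.copy()
        )
    else:
        params, state = initialize(
            data, cfg.G, cfg.seed, n_kmeans_starts=cfg.n_kmeans_starts,
            pca_dim=cfg.pca_dim,
        )
    obj = penalized_objective(data, params, state, lam)
    elbo_trace = []
    obj_trace = [obj]
    converged = False
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        pi_old, mu_old, Theta_old = params.pi, params.mu, params.Theta

        state.P = update_P(data, params, state)
        ng = state.P.sum(axis=0)
        if np.any(ng < 1e-8):
            g = int(np.argmin(ng))
            raise RuntimeError(
                f"cluster {g} collapsed at iteration {it} "
                f"(group masses {np.round(ng, 4)}); consider smaller G"
            )
        params = MplnParams(pi=update_pi(state.P), mu=params.mu, Theta=params.Theta)
        state.M = update_M_admm(data, params, state, cfg.admm)
        state.S = update_S(data, params, state, cfg.admm)
        params = MplnParams(
            pi=params.pi, mu=update_mu(state.P, state.M), Theta=params.Theta
        )
        params = MplnParams(
            pi=params.pi,
            mu=params.mu,
            Theta=update_Theta(
                state.P, state.M, state.S, params.mu, lam, cfg.prior_edges,
                tol=cfg.glasso_tol,
            ),
        )

        total, per_group = elbo(data, params, state)
        obj_new = penalized_objective(data, params, state, lam)
        elbo_trace.append(total)
        obj_trace.append(obj_new)
        rel = abs(obj_new - obj) / max(1.0, abs(obj))
        dparam = max(
            np.max(np.abs(params.pi - pi_old)),
            np.max(np.abs(params.mu - mu_old)),
            np.max(np.abs(params.Theta - Theta_old)),
        )
        if cfg.callback is not None:
            cfg.callback(
                FitResult(
                    params=params,
                    state=state,
                    elbo_trace=np.asarray(elbo_trace),
                    objective_trace=np.asarray(obj_trace),
                    converged=False,
                    n_iter=it,
                    cluster_labels=state.labels(),
                    lambda_n=lam,
                    per_group_elbo=per_group,
                )
            )
        obj = obj_new
        if rel < cfg.elbo_rel_tol and dparam < cfg.param_tol:
            converged = True
            break
    total, per_group = elbo(data, params, state)
    return FitResult(
        params=params,
        state=state,
        elbo_trace=np.asarray(elbo_trace),
        objective_trace=np.asarray(obj_trace),
        converged=converged,
        n_iter=it,
        cluster_labels=state.labels(),
        lambda_n=lam,
        per_group_elbo=per_group,
    )
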