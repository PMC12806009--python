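"""Core mixture Poisson log-normal (MPLN) model: containers and the ELBO.

The generative model for a count matrix ``Y`` (n cells x p genes) is

    Z_i ~ Multinomial(1, pi)                       (cell type)
    X_i | Z_i = g ~ N(mu_g, Theta_g^{-1})          (latent log-expression)
    Y_ij | X_ij ~ Poisson(l_i * exp(X_ij))         (observed count)

where ``l_i`` is the library size of cell ``i`` and ``Theta_g`` is the
precision matrix of cell type ``g`` — its off-diagonal support is the gene
regulatory network of that population.

The marginal likelihood is intractable, so inference goes through a
variational family in which, conditional on ``Z_i = g``, the latent
``X_ij`` are independent normals ``N(M_g,ij, S_g,ij)`` and ``Z_i`` is
multinomial with cell-level responsibilities ``P_i``.  This module holds
the parameter/state containers and evaluates the evidence lower bound
(ELBO) and its penalized version; the optimizer lives in
:mod:`vmpln.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CountData",
    "MplnParams",
    "VariationalState",
    "PriorEdgeSet",
    "per_cell_scatter",
    "elbo",
    "partial_correlations",
    "penalized_objective",
]

#: floor used inside log(P) so that P*log(P) -> 0 as P -> 0 (entropy convention)
_P_FLOOR = 1e-12


def default_library_sizes(Y: np.ndarray) -> np.ndarray:
    """Counts-per-10k library sizes: ``l_i = sum_j Y_ij / 1e4``."""
    return np.asarray(Y, dtype=float).sum(axis=1) / 1e4


@dataclass
class CountData:
    """Observed scRNA-seq counts with per-cell library sizes.

    Parameters
    ----------
    Y
        ``(n, p)`` matrix of non-negative integer counts.
    l
        Length-``n`` vector of positive library sizes.  If omitted,
        computed as counts-per-10k: ``l_i = sum_j Y_ij / 1e4``.
    cell_ids, gene_ids
        Optional identifier lists; defaults are positional names.
    """

    Y: np.ndarray
    l: np.ndarray | None = None
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D cell x gene matrix")
        if np.any(self.Y < 0) or np.any(self.Y != np.floor(self.Y)):
            raise ValueError("Y must contain non-negative integers")
        self.Y = self.Y.astype(float)
        n, p = self.Y.shape
        if self.l is None:
            self.l = default_library_sizes(self.Y)
        self.l = np.asarray(self.l, dtype=float).ravel()
        if self.l.shape != (n,):
            raise ValueError(f"l has shape {self.l.shape}, expected ({n},)")
        if np.any(self.l <= 0):
            bad = int(np.flatnonzero(self.l <= 0)[0])
            raise ValueError(f"library size of cell {bad} is not positive")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(p)]
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lists inconsistent with Y")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass
class MplnParams:
    """Model parameters ``theta = (pi, {mu_g}, {Theta_g})`` for G populations."""

    pi: np.ndarray  # (G,), on the simplex
    mu: np.ndarray  # (G, p)
    Theta: np.ndarray  # (G, p, p), each symmetric positive definite

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.Theta = np.asarray(self.Theta, dtype=float)
        if self.Theta.ndim == 2:
            self.Theta = self.Theta[None]
        G, p = self.mu.shape
        if self.pi.shape != (G,) or self.Theta.shape != (G, p, p):
            raise ValueError("inconsistent shapes for pi, mu, Theta")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must lie on the probability simplex")

    @property
    def G(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.mu.shape[1]


@dataclass
class VariationalState:
    """Variational parameters ``eta = ({M_g}, {S_g}, P)``.

    ``M`` and ``S`` are ``(G, n, p)`` stacks of per-group normal means and
    variances for the latent log-expression; ``P`` is the ``(n, G)`` matrix
    of cell-type responsibilities (each row on the simplex).
    """

    M: np.ndarray
    S: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.M.ndim == 2:
            self.M = self.M[None]
        if self.S.ndim == 2:
            self.S = self.S[None]
        if self.P.ndim == 1:
            self.P = self.P[:, None]
        if self.M.shape != self.S.shape:
            raise ValueError("M and S must have identical shapes")
        G, n, p = self.M.shape
        if self.P.shape != (n, G):
            raise ValueError(f"P has shape {self.P.shape}, expected ({n}, {G})")
        if np.any(self.S <= 0):
            raise ValueError("all variational variances S must be positive")
        if np.any(self.P < -1e-12) or np.max(np.abs(self.P.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("rows of P must lie on the probability simplex")

    @property
    def G(self) -> int:
        return self.M.shape[0]

    def labels(self) -> np.ndarray:
        """Hard cluster labels: argmax responsibility, lowest index on ties."""
        return np.argmax(self.P, axis=1)


@dataclass
class PriorEdgeSet:
    """Gene pairs known a priori to carry no edge (forced zeros in Theta)."""

    zero_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        closed = set()
        for l, m in self.zero_edges:
            if l == m:
                raise ValueError("prior zero edges must be off-diagonal (l != m)")
            closed.add((int(l), int(m)))
            closed.add((int(m), int(l)))
        self.zero_edges = frozenset(closed)

    def mask(self, p: int) -> np.ndarray:
        """Boolean ``(p, p)`` matrix, True where Theta is constrained to zero."""
        out = np.zeros((p, p), dtype=bool)
        for l, m in self.zero_edges:
            if l >= p or m >= p:
                raise ValueError(f"prior edge ({l},{m}) out of range for p={p}")
            out[l, m] = True
        return out

    def __len__(self) -> int:
        return len(self.zero_edges) // 2


def per_cell_scatter(M_row: np.ndarray, S_row: np.ndarray, mu_g: np.ndarray) -> np.ndarray:
    """Per-cell second-moment matrix of the variational posterior.

    ``Sigma_{g,i} = (M_{g,i.} - mu_g)(M_{g,i.} - mu_g)^T + D(S_{g,i.})`` —
    the rank-one-plus-diagonal matrix through which ``Theta_g`` enters the
    ELBO via ``tr(Theta_g Sigma_{g,i})``.
    """
    M_row = np.asarray(M_row, dtype=float).ravel()
    S_row = np.asarray(S_row, dtype=float).ravel()
    mu_g = np.asarray(mu_g, dtype=float).ravel()
    if not (M_row.shape == S_row.shape == mu_g.shape):
        raise ValueError("M_row, S_row and mu_g must have equal length")
    if np.any(S_row <= 0):
        raise ValueError("variational variances S must be strictly positive")
    d = M_row - mu_g
    return np.outer(d, d) + np.diag(S_row)


def _logdet_spd(Theta: np.ndarray, group: int | None = None) -> float:
    """log det of an SPD matrix via Cholesky; explicit error if not PD."""
    try:
        L = np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError as exc:
        where = "" if group is None else f" for group {group}"
        raise np.linalg.LinAlgError(
            f"precision matrix{where} is not positive definite"
        ) from exc
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def elbo(
    data: CountData, params: MplnParams, state: VariationalState
) -> tuple[float, np.ndarray]:
    """Evidence lower bound of the MPLN model under the variational family.

    Returns ``(total, per_group)`` where ``per_group[g]`` is

        P_{.g}^T (L1 - L2 + L3) 1_p + P_{.g}^T L4 + P_{.g}^T L5 + K_g(Y)

    with elementwise pieces ``L1 = Y .* M_g``,
    ``L2_ij = exp(M_g,ij + S_g,ij/2 + log l_i)``, ``L3 = (1/2) log S_g``,
    cell-level ``L4 = log pi_g - log P_{.g}`` and
    ``L5_i = (1/2) log det Theta_g - (1/2) tr(Theta_g Sigma_{g,i})``, and the
    data constant ``K_g(Y) = sum_ij P_ig (-log Y_ij! + Y_ij log l_i)``.
    Additive constants independent of all parameters are dropped.
    """
    Y, l = data.Y, data.l
    G = params.G
    log_l = np.log(l)
    # -log Y! + Y log l, shared across groups
    const_ij = -gammaln(Y + 1.0) + Y * log_l[:, None]
    per_group = np.empty(G)
    for g in range(G):
        Mg, Sg = state.M[g], state.S[g]
        Pg = state.P[:, g]
        mu_g, Theta_g = params.mu[g], params.Theta[g]
        logdet = _logdet_spd(Theta_g, group=g)

        lam1 = Y * Mg
        lam2 = np.exp(Mg + 0.5 * Sg + log_l[:, None])
        lam3 = 0.5 * np.log(Sg)
        cellwise = (lam1 - lam2 + lam3).sum(axis=1)

        lam4 = np.log(params.pi[g]) - np.log(np.maximum(Pg, _P_FLOOR))

        # tr(Theta Sigma_i) = (M_i - mu)^T Theta (M_i - mu) + sum_j Theta_jj S_ij
        D = Mg - mu_g[None, :]
        quad = np.einsum("ij,jk,ik->i", D, Theta_g, D)
        trace = quad + Sg @ np.diag(Theta_g)
        lam5 = 0.5 * logdet - 0.5 * trace

        Kg = float(Pg @ const_ij.sum(axis=1))
        per_group[g] = float(Pg @ (cellwise + lam4 + lam5)) + Kg
    return float(per_group.sum()), per_group


def partial_correlations(Theta: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix.

    Off-diagonal ``(l, m)`` entries are ``-Theta_lm / sqrt(Theta_ll Theta_mm)``;
    the diagonal is 1.  Invariant to positive rescaling of ``Theta``.
    """
    Theta = np.asarray(Theta, dtype=float)
    d = np.diag(Theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have a strictly positive diagonal")
    scale = 1.0 / np.sqrt(d)
    pc = -Theta * np.outer(scale, scale)
    np.fill_diagonal(pc, 1.0)
    return pc


def offdiag_l1(Theta: np.ndarray) -> float:
    """Off-diagonal l1 norm ``sum_{l != m} |Theta_lm|``."""
    Theta = np.asarray(Theta, dtype=float)
    return float(np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum())


def penalized_objective(
    data: CountData,
    params: MplnParams,
    state: VariationalState,
    lambda_n: float | np.ndarray,
) -> float:
    """Penalized negative ELBO: ``-ELBO + sum_g lambda_g * ||Theta_g||_{1,off}``.

    ``lambda_n`` may be a scalar (shared across groups) or a length-G vector.
    This is the loss the block-descent optimizer drives downward.
    """
    lam = np.broadcast_to(np.asarray(lambda_n, dtype=float), (params.G,))
    if np.any(lam < 0):
        raise ValueError("lambda_n must be non-negative")
    total, _ = elbo(data, params, state)
    penalty = sum(lam[g] * offdiag_l1(params.Theta[g]) for g in range(params.G))
    return -total + penalty
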