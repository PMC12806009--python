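"""Shared fixtures: random small MPLN instances built from scratch."""

from __future__ import annotations

import numpy as np
import pytest

from vmpln import CountData, MplnParams, VariationalState


def random_spd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random symmetric positive-definite matrix."""
    A = rng.standard_normal((p, p))
    return scale * (A @ A.T / p + 0.5 * np.eye(p))


def make_instance(
    rng: np.random.Generator, n: int = 4, p: int = 3, G: int = 2, rate: float = 2.0
) -> tuple[CountData, MplnParams, VariationalState]:
    """A random, fully valid (data, params, state) triple for small tests."""
    Y = rng.poisson(rate, size=(n, p))
    l = rng.uniform(0.5, 2.0, size=n)
    data = CountData(Y=Y, l=l)
    pi = rng.dirichlet(np.ones(G))
    mu = rng.normal(0.0, 1.0, size=(G, p))
    Theta = np.stack([random_spd(rng, p) for _ in range(G)])
    params = MplnParams(pi=pi, mu=mu, Theta=Theta)
    M = rng.normal(0.0, 1.0, size=(G, n, p))
    S = rng.uniform(0.1, 1.0, size=(G, n, p))
    P = rng.dirichlet(np.ones(G), size=n)
    state = VariationalState(M=M, S=S, P=P)
    return data, params, state


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
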