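"""Shared fixtures and independent dense-matrix oracles.

The oracles here deliberately work with explicit n-by-n matrices
(V = I + Z D Z' formed and inverted directly) so they share no code path
with the product-form implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg

from fslmm.model import CovarianceParams, LMMDesign, build_design

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_spd(rng: np.random.Generator, q: int, scale: float = 1.0) -> np.ndarray:
    A = rng.standard_normal((q, q))
    return scale * (A @ A.T / q + 0.1 * np.eye(q))


def make_design(
    rng: np.random.Generator,
    n: int,
    p: int,
    factor_spec: list[tuple[int, int]],
    exact_y: np.ndarray | None = None,
) -> LMMDesign:
    """Random small design; factor_spec is a list of (q_k, l_k) pairs.

    The first l_k observations of each factor are pinned to distinct levels
    so that every level is occupied even at tiny n.
    """
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))]) if p > 1 else np.ones((n, 1))
    tables = []
    for qk, lk in factor_spec:
        assert n >= lk
        lev = np.concatenate([np.arange(lk), rng.integers(0, lk, n - lk)])
        covs = np.column_stack([np.ones(n), rng.standard_normal((n, qk - 1))]) if qk > 1 else np.ones((n, 1))
        tables.append((lev, covs))
    Y = exact_y if exact_y is not None else rng.standard_normal(n)
    return build_design(Y, X, tables)


def random_params(
    rng: np.random.Generator, design: LMMDesign, sigma2: float | None = None
) -> CovarianceParams:
    s2 = sigma2 if sigma2 is not None else float(0.5 + rng.random())
    Dk = [random_spd(rng, qk, 0.8) for qk in design.fs.q]
    return CovarianceParams(s2, Dk)


# ---------------------------------------------------------------------------
# dense-matrix oracle
# ---------------------------------------------------------------------------


class DenseOracle:
    """All model quantities via the explicit (n x n) covariance matrix."""

    def __init__(self, design: LMMDesign, params: CovarianceParams):
        self.design = design
        self.params = params
        self.Z = design.Z()
        fs = design.fs
        self.D = scipy.linalg.block_diag(
            *[np.kron(np.eye(fs.l[k]), params.Dk_list[k]) for k in range(fs.r)]
        )
        self.V = np.eye(design.n) + self.Z @ self.D @ self.Z.T
        self.Vinv = np.linalg.inv(self.V)

    def loglik(self, beta: np.ndarray, reml: bool = False) -> float:
        X, Y = self.design.X, self.design.Y
        e = Y - X @ beta
        s2 = self.params.sigma2
        n = self.design.n
        ll = -0.5 * (
            n * np.log(s2)
            + e @ self.Vinv @ e / s2
            + np.linalg.slogdet(self.V)[1]
        )
        if reml:
            p = X.shape[1]
            ll -= 0.5 * (
                -p * np.log(s2) + np.linalg.slogdet(X.T @ self.Vinv @ X)[1]
            )
        return float(ll)

    def gls(self, reml: bool = False) -> tuple[np.ndarray, float]:
        X, Y = self.design.X, self.design.Y
        XtVX = X.T @ self.Vinv @ X
        beta = np.linalg.solve(XtVX, X.T @ self.Vinv @ Y)
        e = Y - X @ beta
        denom = self.design.n - X.shape[1] if reml else self.design.n
        return beta, float(e @ self.Vinv @ e / denom)


@pytest.fixture
def small_crossed_design():
    """n=25, two crossed factors (q=(2,1), l=(3,2))."""
    rng = rng_for(42)
    return make_design(rng, 25, 2, [(2, 3), (1, 2)])


@pytest.fixture
def medium_crossed_design():
    """n=40, p=3, factors (q=(2,2), l=(5,4))."""
    rng = rng_for(7)
    return make_design(rng, 40, 3, [(2, 5), (2, 4)])
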