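"""Closed-form score vectors and Fisher information matrices.

Scores and expected-information blocks are available in the three
covariance flattenings (half ``vech(D_k)``, full ``vec(D_k)``, Cholesky
``vech(Lambda_k)``) under both the ML and restricted (ReML) criteria.  The
key closed forms, with ``V = I + Z D Z'`` and ``e = Y - X beta``:

- ``dl/dbeta        = s2^{-1} X'V^{-1}e``
- ``dl/ds2          = -n/(2 s2) + e'V^{-1}e / (2 s2^2)``
- ``dl/dvech(D_k)   = 1/2 Dup' vec( sum_j Z_(k,j)'V^{-1}(ee'/s2 - V)V^{-1}Z_(k,j) )``
- ``I_beta          = s2^{-1} X'V^{-1}X``; the beta/s2 and beta/covariance
  blocks vanish exactly.
- ``I_vech(Dk1),vech(Dk2) = 1/2 Dup' [sum_ij B_ij (x) B_ij] Dup`` with
  ``B_ij = Z_(k1,i)'V^{-1}Z_(k2,j)``; the double Kronecker sums are
  evaluated by the permuted-reshape primitive, never by looping over
  levels.

The full representation treats symmetric elements of ``D_k`` as distinct
(partial derivatives).  Its expected information is rank-deficient by
construction; the invertible scoring-matrix surrogate ``F`` (the same
blocks without the symmetrizer factor) is returned on request and drives
the full-representation update rules.

ReML adds ``p/(2 s2)`` to the ``s2`` score and, per covariance block,
``1/2 Dup' vec( sum_j Z_(k,j)'V^{-1}X (X'V^{-1}X)^{-1} X'V^{-1}Z_(k,j) )``.
The expected information is kept at its ML form except for the ``s2``
diagonal, which under ReML is ``(n - p)/(2 s2^2)`` — the restricted
likelihood's own curvature in the residual variance, consistent with the
adjusted score's stationarity point ``s2 = e'V^{-1}e/(n - p)``.

The residual outer product ``ee'`` is never formed: the summand expands
into ``(Z'V^{-1}e)(Z'V^{-1}e)'/s2 - Z'V^{-1}Z`` sub-blocks available from
the product-form solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matcalc import (
    commutation_matrix,
    duplication_matrix,
    elimination_matrix,
    kron_sum_vectorized,
    symmetrizer_matrix,
    vec,
)
from .model import CoreSolves, CovarianceParams, ProductForms, core_solves

__all__ = [
    "ScoreVector",
    "InformationMatrix",
    "score",
    "fisher_information",
    "chol_jacobian",
]

_REPS = ("half", "full", "chol")


@dataclass
class ScoreVector:
    """Gradient of the (restricted) log-likelihood at a parameter point."""

    d_beta: np.ndarray
    d_sigma2: float
    d_cov: list[np.ndarray]  # one block per factor, layout per `rep`
    rep: str
    reml: bool

    def stack(self) -> np.ndarray:
        return np.concatenate(
            [self.d_beta, [self.d_sigma2], *[b for b in self.d_cov]]
        )


@dataclass
class InformationMatrix:
    """Blocked expected information (or scoring-matrix surrogate).

    ``beta_block`` is ``s2^{-1} X'V^{-1}X``; all beta cross-blocks are
    exactly zero.  ``cov_blocks[(k1, k2)]`` holds the covariance-pair block
    in the requested representation; ``sigma2_cov[k]`` the ``s2`` cross row.
    """

    beta_block: np.ndarray
    sigma2_entry: float
    sigma2_cov: list[np.ndarray]
    cov_blocks: dict[tuple[int, int], np.ndarray]
    rep: str
    is_scoring_matrix: bool

    def cov_matrix(self) -> np.ndarray:
        """Assemble the (sigma2, covariance-blocks) sub-matrix."""
        r = len(self.sigma2_cov)
        sizes = [1] + [self.cov_blocks[(k, k)].shape[0] for k in range(r)]
        m = sum(sizes)
        out = np.zeros((m, m))
        out[0, 0] = self.sigma2_entry
        starts = np.cumsum(sizes)[:-1].tolist()
        for k in range(r):
            s = slice(starts[k], starts[k] + sizes[k + 1])
            out[0, s] = self.sigma2_cov[k]
            out[s, 0] = self.sigma2_cov[k]
            for k2 in range(r):
                s2 = slice(starts[k2], starts[k2] + sizes[k2 + 1])
                out[s, s2] = self.cov_blocks[(k, k2)]
        return out

    def full_matrix(self) -> np.ndarray:
        p = self.beta_block.shape[0]
        covm = self.cov_matrix()
        out = np.zeros((p + covm.shape[0],) * 2)
        out[:p, :p] = self.beta_block
        out[p:, p:] = covm
        return out


def chol_jacobian(lam: np.ndarray) -> np.ndarray:
    """Jacobian d vech(D)/d vech(Lambda) for D = Lambda Lambda'.

    Returned as ``Elim (Lambda' (x) I)(I + K_{q,q}) Elim'``, the transpose
    of the standard Jacobian of ``vech(Lambda) -> vech(Lambda Lambda')``,
    so that the chain rule composes directly with the total-derivative
    half scores used throughout: ``dl/dvech(Lambda) = J . dl/dvech(D)``
    and ``I^c = J I^h J'``.  (The equivalent form with a trailing
    duplication matrix pairs with lower-triangle *partial* scores instead;
    both yield identical gradients.)
    """
    lam = np.asarray(lam, dtype=float)
    qk = lam.shape[0]
    if lam.shape != (qk, qk) or not np.allclose(lam, np.tril(lam)):
        raise ValueError("Lambda must be square lower triangular")
    elim = elimination_matrix(qk)
    return (
        elim
        @ np.kron(lam.T, np.eye(qk))
        @ (np.eye(qk * qk) + commutation_matrix(qk, qk))
        @ elim.T
    )


def _cov_score_matrices(
    cs: CoreSolves, sigma2: float, beta: np.ndarray, reml: bool
) -> list[np.ndarray]:
    """Per factor: M_k = sum_j Z_(k,j)'V^{-1}(ee'/s2 - V)V^{-1}Z_(k,j) (+ReML)."""
    fs = cs.fs
    zve = cs.Zt_Vinv_e(beta)
    mats = []
    if reml:
        Cfac = cs.XtVinvZ.T @ np.linalg.solve(cs.XtVinvX, cs.XtVinvZ)
    for k in range(fs.r):
        a = cs.level_rows(zve, k)  # (l_k, q_k)
        M = np.einsum("ja,jb->ab", a, a) / sigma2 - cs.diag_block_sum(cs.ZtVinvZ, k)
        if reml:
            M = M + cs.diag_block_sum(Cfac, k)
        mats.append(M)
    return mats


def score(
    pf: ProductForms,
    params: CovarianceParams,
    beta: np.ndarray,
    rep: str = "half",
    reml: bool = False,
    cs: CoreSolves | None = None,
    lambdas: list[np.ndarray] | None = None,
) -> ScoreVector:
    """Score vector in the requested representation and criterion.

    For ``rep='chol'`` the per-factor Cholesky factors may be supplied; by
    default they are computed from ``params`` (requires PSD blocks).
    """
    if rep not in _REPS:
        raise ValueError(f"unknown representation {rep!r}")
    if cs is None:
        cs = core_solves(pf, params)
    beta = np.asarray(beta, dtype=float).reshape(-1)
    s2 = params.sigma2
    d_beta = cs.Xt_Vinv_e(beta) / s2
    d_s2 = -0.5 * pf.n / s2 + 0.5 * cs.et_Vinv_e(beta) / s2**2
    if reml:
        d_s2 += 0.5 * pf.p / s2
    mats = _cov_score_matrices(cs, s2, beta, reml)
    d_cov = []
    for k, M in enumerate(mats):
        qk = pf.fs.q[k]
        if rep == "full":
            d_cov.append(0.5 * vec(M))
        else:
            half = 0.5 * duplication_matrix(qk).T @ vec(M)
            if rep == "half":
                d_cov.append(half)
            else:
                from .model import chol_factor

                lam = lambdas[k] if lambdas is not None else chol_factor(params.Dk_list[k])
                d_cov.append(chol_jacobian(lam) @ half)
    return ScoreVector(d_beta, float(d_s2), d_cov, rep, reml)


def fisher_information(
    pf: ProductForms,
    params: CovarianceParams,
    rep: str = "half",
    scoring_matrix: bool = False,
    reml: bool = False,
    cs: CoreSolves | None = None,
    lambdas: list[np.ndarray] | None = None,
) -> InformationMatrix:
    """Expected information (or the F surrogate for the full representation).

    ``scoring_matrix=True`` is only meaningful with ``rep='full'`` and
    drops the rank-deficient symmetrizer factor, yielding the invertible
    matrix whose plain inverse reproduces the pseudo-inverse scoring
    update.
    """
    if rep not in _REPS:
        raise ValueError(f"unknown representation {rep!r}")
    if scoring_matrix and rep != "full":
        raise ValueError("the scoring matrix variant exists for rep='full' only")
    if cs is None:
        cs = core_solves(pf, params)
    fs = pf.fs
    s2 = params.sigma2
    beta_block = cs.XtVinvX / s2
    dof_n = pf.n - pf.p if reml else pf.n
    sigma2_entry = 0.5 * dof_n / s2**2

    if rep == "chol" and lambdas is None:
        from .model import chol_factor

        lambdas = [chol_factor(D) for D in params.Dk_list]
    jacs = [chol_jacobian(lam) for lam in lambdas] if rep == "chol" else None

    sigma2_cov = []
    for k in range(fs.r):
        row_full = 0.5 / s2 * vec(cs.diag_block_sum(cs.ZtVinvZ, k))
        if rep == "full":
            sigma2_cov.append(row_full)
        else:
            row = duplication_matrix(fs.q[k]).T @ row_full
            sigma2_cov.append(jacs[k] @ row if rep == "chol" else row)

    cov_blocks: dict[tuple[int, int], np.ndarray] = {}
    for k1 in range(fs.r):
        for k2 in range(k1, fs.r):
            grid = cs.cross_factor_block(cs.ZtVinvZ, k1, k2)
            F = 0.5 * kron_sum_vectorized(grid, grid, fs.q[k1], fs.q[k2])
            if rep == "full":
                blk = F if scoring_matrix else symmetrizer_matrix(fs.q[k1]) @ F
            else:
                blk = (
                    duplication_matrix(fs.q[k1]).T @ F @ duplication_matrix(fs.q[k2])
                )
                if rep == "chol":
                    blk = jacs[k1] @ blk @ jacs[k2].T
            cov_blocks[(k1, k2)] = blk
            if k2 != k1:
                if rep == "full" and not scoring_matrix:
                    # transpose of N_{q_k1} F is F' N_{q_k1}; rebuild from the
                    # swapped grid so the (k2,k1) block is exact
                    grid_t = cs.cross_factor_block(cs.ZtVinvZ, k2, k1)
                    Ft = 0.5 * kron_sum_vectorized(grid_t, grid_t, fs.q[k2], fs.q[k1])
                    cov_blocks[(k2, k1)] = symmetrizer_matrix(fs.q[k2]) @ Ft
                else:
                    cov_blocks[(k2, k1)] = blk.T
    return InformationMatrix(
        beta_block=beta_block,
        sigma2_entry=float(sigma2_entry),
        sigma2_cov=sigma2_cov,
        cov_blocks=cov_blocks,
        rep=rep,
        is_scoring_matrix=scoring_matrix,
    )
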