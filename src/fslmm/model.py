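"""Model representation for the crossed-factor linear mixed model.

The model is

.. math::

    Y = X\\beta + Zb + \\epsilon, \\qquad
    \\epsilon \\sim N(0, \\sigma^2 I_n), \\qquad
    b \\sim N(0, \\sigma^2 D),

with ``r`` crossed random factors.  Factor ``k`` groups ``q_k`` random
effects over ``l_k`` levels, and contributes a block
``Z_(k) = [Z_(k,1), ..., Z_(k,l_k)]`` to ``Z``; ``D`` is block diagonal with
per-factor blocks ``I_{l_k} (x) D_k``.  After the six cross-products

    P = X'X,  Q = X'Y,  R = X'Z,  S = Y'Y,  T = Y'Z,  U = Z'Z

have been formed (the "product forms"), every quantity needed for
estimation and inference — including all appearances of
``V = I_n + Z D Z'`` — is computed from matrices whose dimensions scale
with ``p`` and ``q = sum_k q_k l_k`` only, never with ``n``.  The only
inversion is of the ``q x q`` matrix ``I_q + D U``; ``log|V|`` is obtained
as ``log det(I_q + D U)`` via the Weinstein-Aronszajn identity.

Log-likelihoods follow the convention of dropping additive constants:
``l = -1/2 (n log s2 + s2^{-1} e'V^{-1}e + log|V|)`` and, for the
restricted criterion, ``l_R = l + 1/2 (p log s2 - log|X'V^{-1}X|)``.
Reported values therefore differ from fully normalized log-densities by
``n log(2 pi)/2``-type constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .matcalc import unvech, vec, vech

__all__ = [
    "SIGMA2_FLOOR",
    "FactorStructure",
    "LMMDesign",
    "ProductForms",
    "CovarianceParams",
    "ParamVector",
    "CoreSolves",
    "build_design",
    "product_forms",
    "core_solves",
    "log_likelihood",
    "convert",
]

# Evaluation floor for the residual variance; fits that hit it are flagged.
SIGMA2_FLOOR = 1e-10


@dataclass(frozen=True)
class FactorStructure:
    """Crossed-factor layout: effect counts, level counts, level assignments.

    Parameters
    ----------
    q : per-factor number of random effects ``q_k`` (>= 1).
    l : per-factor number of levels ``l_k`` (>= 2).
    levels : per factor, a length-``n`` integer array assigning each
        observation to a 0-based level index.  Every level of every factor
        must be occupied, otherwise the corresponding ``D_k`` block is
        unidentifiable and the structure is rejected.
    """

    q: tuple[int, ...]
    l: tuple[int, ...]
    levels: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.q) < 1 or len(self.q) != len(self.l):
            raise ValueError("need at least one factor with matching q and l")
        if len(self.q) != len(self.levels):
            raise ValueError("levels must be given for every factor")
        object.__setattr__(self, "q", tuple(int(x) for x in self.q))
        object.__setattr__(self, "l", tuple(int(x) for x in self.l))
        n = len(self.levels[0])
        lv = []
        for k, (qk, lk, lev) in enumerate(zip(self.q, self.l, self.levels)):
            if qk < 1:
                raise ValueError(f"factor {k}: q_k must be >= 1")
            if lk < 2:
                raise ValueError(f"factor {k}: l_k must be >= 2")
            lev = np.asarray(lev, dtype=np.intp)
            if lev.shape != (n,):
                raise ValueError("level assignments must share a common length")
            if lev.min() < 0 or lev.max() >= lk:
                raise ValueError(f"factor {k}: level index out of range [0, {lk})")
            if len(np.unique(lev)) != lk:
                raise ValueError(f"factor {k}: every level needs >= 1 observation")
            lv.append(lev)
        object.__setattr__(self, "levels", tuple(lv))

    @property
    def r(self) -> int:
        return len(self.q)

    @property
    def n(self) -> int:
        return len(self.levels[0])

    @property
    def q_total(self) -> int:
        return int(sum(qk * lk for qk, lk in zip(self.q, self.l)))

    @property
    def factor_offsets(self) -> tuple[int, ...]:
        offs, pos = [], 0
        for qk, lk in zip(self.q, self.l):
            offs.append(pos)
            pos += qk * lk
        return tuple(offs)

    def factor_slice(self, k: int) -> slice:
        off = self.factor_offsets[k]
        return slice(off, off + self.q[k] * self.l[k])

    def level_slice(self, k: int, j: int) -> slice:
        """Columns of Z for level ``j`` of factor ``k``."""
        off = self.factor_offsets[k] + j * self.q[k]
        return slice(off, off + self.q[k])


@dataclass(frozen=True)
class LMMDesign:
    """Response, fixed design and per-factor raw random-effect covariates.

    ``Z`` columns are ordered factor-by-factor (declaration order), within
    factor by level, within level by effect.  ``Z_(k,j)`` is zero on every
    row whose observation does not belong to level ``j`` of factor ``k``.
    """

    Y: np.ndarray
    X: np.ndarray
    fs: FactorStructure
    raw_covariates: tuple[np.ndarray, ...]  # per factor, (n, q_k)

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=float).reshape(-1)
        X = np.asarray(self.X, dtype=float)
        n = Y.shape[0]
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError("X must be (n x p) with n matching Y")
        if self.fs.n != n:
            raise ValueError("factor structure length does not match Y")
        rc = []
        for k, c in enumerate(self.raw_covariates):
            c = np.asarray(c, dtype=float)
            if c.shape != (n, self.fs.q[k]):
                raise ValueError(f"factor {k}: covariates must be (n x q_k)")
            rc.append(c)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "raw_covariates", tuple(rc))

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def Z(self) -> np.ndarray:
        """Assemble the dense (n x q_total) random-effects design matrix."""
        fs = self.fs
        Z = np.zeros((self.n, fs.q_total))
        rows = np.arange(self.n)
        for k in range(fs.r):
            base = fs.factor_offsets[k] + fs.levels[k] * fs.q[k]
            for e in range(fs.q[k]):
                Z[rows, base + e] = self.raw_covariates[k][:, e]
        return Z


def build_design(
    Y: np.ndarray,
    X: np.ndarray,
    factor_tables: Sequence[tuple[np.ndarray, np.ndarray]],
) -> LMMDesign:
    """Build an :class:`LMMDesign` from per-factor (levels, covariates) pairs.

    Each entry of ``factor_tables`` gives the observation-to-level
    assignment (length ``n``, 0-based) and the ``(n, q_k)`` covariate values
    of the random effects grouped by that factor.
    """
    if not factor_tables:
        raise ValueError("at least one random factor is required")
    lev_list, cov_list, q, l = [], [], [], []
    for levels, covs in factor_tables:
        levels = np.asarray(levels, dtype=np.intp)
        covs = np.asarray(covs, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
        if covs.shape[1] < 1:
            raise ValueError("each factor needs at least one random effect")
        lev_list.append(levels)
        cov_list.append(covs)
        q.append(covs.shape[1])
        l.append(int(levels.max()) + 1)
    fs = FactorStructure(tuple(q), tuple(l), tuple(lev_list))
    return LMMDesign(Y=Y, X=X, fs=fs, raw_covariates=tuple(cov_list))


@dataclass(frozen=True)
class ProductForms:
    """The six cross-products; all later computation is free of ``n``."""

    P: np.ndarray  # X'X (p x p)
    Q: np.ndarray  # X'Y (p,)
    R: np.ndarray  # X'Z (p x q)
    S: float  # Y'Y
    T: np.ndarray  # Z'Y (q,)  (stored transposed: a vector, not a 1 x q row)
    U: np.ndarray  # Z'Z (q x q)
    n: int
    fs: FactorStructure

    @property
    def p(self) -> int:
        return self.P.shape[0]


def product_forms(design: LMMDesign) -> ProductForms:
    """Compute P, Q, R, S, T, U; X, Y, Z may be discarded afterwards."""
    Z = design.Z()
    X, Y = design.X, design.Y
    return ProductForms(
        P=X.T @ X,
        Q=X.T @ Y,
        R=X.T @ Z,
        S=float(Y @ Y),
        T=Z.T @ Y,
        U=Z.T @ Z,
        n=design.n,
        fs=design.fs,
    )


@dataclass
class CovarianceParams:
    """Residual variance and per-factor within-factor covariance blocks.

    ``D = direct-sum_k (I_{l_k} (x) D_k)`` is only ever applied blockwise;
    ``V = I_n + Z D Z'`` is never materialized.
    """

    sigma2: float
    Dk_list: list[np.ndarray]

    def __post_init__(self):
        self.sigma2 = float(self.sigma2)
        self.Dk_list = [np.asarray(D, dtype=float) for D in self.Dk_list]

    def validate(self, fs: FactorStructure) -> None:
        if len(self.Dk_list) != fs.r:
            raise ValueError("one covariance block per factor is required")
        for k, D in enumerate(self.Dk_list):
            if D.shape != (fs.q[k], fs.q[k]):
                raise ValueError(f"factor {k}: D_k must be ({fs.q[k]} x {fs.q[k]})")
            if not np.allclose(D, D.T, atol=1e-10):
                raise ValueError(f"factor {k}: D_k must be symmetric")


def apply_D(fs: FactorStructure, Dk_list: Sequence[np.ndarray], M: np.ndarray) -> np.ndarray:
    """Blockwise product D @ M without materializing the q x q matrix D."""
    M2 = M[:, None] if M.ndim == 1 else M
    out = np.empty_like(M2, dtype=float)
    for k in range(fs.r):
        sl = fs.factor_slice(k)
        blk = M2[sl].reshape(fs.l[k], fs.q[k], M2.shape[1])
        out[sl] = np.einsum("ab,jbc->jac", Dk_list[k], blk).reshape(-1, M2.shape[1])
    return out[:, 0] if M.ndim == 1 else out


def dense_D(fs: FactorStructure, Dk_list: Sequence[np.ndarray]) -> np.ndarray:
    """Materialize D (q_total x q_total); used only for q-sized solves/tests."""
    return scipy.linalg.block_diag(
        *[np.kron(np.eye(fs.l[k]), Dk_list[k]) for k in range(fs.r)]
    )


class CoreSolves:
    """Every V-involving quantity, computed solely from the product forms.

    One LU factorization of ``A = I_q + DU`` serves everything.  With
    ``W = D (I_q + U D)^{-1} = A^{-1} D`` the Woodbury identities give

    - ``Z'V^{-1}Z = U - U W U = U A^{-1}``  (since ``W U = I - A^{-1}``)
    - ``X'V^{-1}Z = R - R W U = R A^{-1}``
    - ``X'V^{-1}X = P - R W R'``
    - ``Z'V^{-1}Y = T - U W T``, ``X'V^{-1}Y = Q - R W T``
    - ``log|V| = log det(I_q + D U)``

    plus beta-dependent contractions (``e = Y - X beta``):
    ``Z'V^{-1}e``, ``X'V^{-1}e`` and ``e'V^{-1}e``.  The single ``q``-sized
    right-hand-side solve (for ``Z'V^{-1}Z``) is performed lazily, so
    likelihood-only evaluations touch just the LU factorization and a few
    thin solves.
    """

    def __init__(self, pf: ProductForms, params: CovarianceParams):
        params.validate(pf.fs)
        fs = pf.fs
        self.pf = pf
        self.fs = fs
        self.params = params
        q = fs.q_total
        DU = apply_D(fs, params.Dk_list, pf.U)
        A = np.eye(q) + DU
        sign, logabsdet = np.linalg.slogdet(A)
        if sign <= 0 or not np.isfinite(logabsdet):
            raise np.linalg.LinAlgError(
                "I_q + DU has non-positive determinant; covariance blow-up"
            )
        self.logdetV = float(logabsdet)
        try:
            self._lu = scipy.linalg.lu_factor(A)
        except (scipy.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
            raise np.linalg.LinAlgError(str(err)) from err
        # thin solves (p- and 1-column right-hand sides)
        R, U, T, Q = pf.R, pf.U, pf.T, pf.Q
        WT = scipy.linalg.lu_solve(self._lu, apply_D(fs, params.Dk_list, T))
        WRt = scipy.linalg.lu_solve(self._lu, apply_D(fs, params.Dk_list, R.T))
        XtVinvX = pf.P - R @ WRt
        self.XtVinvX = 0.5 * (XtVinvX + XtVinvX.T)
        # R A^{-1} via the transposed system (p right-hand sides)
        self.XtVinvZ = scipy.linalg.lu_solve(self._lu, R.T, trans=1).T
        self.ZtVinvY = T - U @ WT
        self.XtVinvY = Q - R @ WT
        self.YtVinvY = float(pf.S - T @ WT)
        self._ZtVinvZ: np.ndarray | None = None

    @property
    def ZtVinvZ(self) -> np.ndarray:
        if self._ZtVinvZ is None:
            # U A^{-1} = (A^{-T} U)' with U symmetric
            M = scipy.linalg.lu_solve(self._lu, self.pf.U, trans=1).T
            self._ZtVinvZ = 0.5 * (M + M.T)
        return self._ZtVinvZ

    # ----- beta-dependent contractions -------------------------------------
    def Zt_Vinv_e(self, beta: np.ndarray) -> np.ndarray:
        return self.ZtVinvY - self.XtVinvZ.T @ beta

    def Xt_Vinv_e(self, beta: np.ndarray) -> np.ndarray:
        return self.XtVinvY - self.XtVinvX @ beta

    def et_Vinv_e(self, beta: np.ndarray) -> float:
        return float(
            self.YtVinvY - 2.0 * beta @ self.XtVinvY + beta @ self.XtVinvX @ beta
        )

    # ----- per-level block helpers -----------------------------------------
    def diag_block_sum(self, M: np.ndarray, k: int) -> np.ndarray:
        """sum_j of the (k,j),(k,j) diagonal blocks of a q x q matrix."""
        fs = self.fs
        sl = fs.factor_slice(k)
        sub = M[sl, sl].reshape(fs.l[k], fs.q[k], fs.l[k], fs.q[k])
        return np.einsum("jajb->ab", sub)

    def level_rows(self, Mq: np.ndarray, k: int) -> np.ndarray:
        """Reshape factor-k rows of a q-vector/matrix to (l_k, q_k, ...)."""
        fs = self.fs
        sub = Mq[fs.factor_slice(k)]
        if sub.ndim == 1:
            return sub.reshape(fs.l[k], fs.q[k])
        return sub.reshape(fs.l[k], fs.q[k], sub.shape[1])

    def cross_factor_block(self, M: np.ndarray, k1: int, k2: int) -> np.ndarray:
        return M[self.fs.factor_slice(k1), self.fs.factor_slice(k2)]


def core_solves(pf: ProductForms, params: CovarianceParams) -> CoreSolves:
    """Factor the ``(I_q + DU)`` system once and expose all V-quantities."""
    return CoreSolves(pf, params)


def log_likelihood(
    pf: ProductForms,
    params: CovarianceParams,
    beta: np.ndarray,
    reml: bool = False,
    cs: CoreSolves | None = None,
) -> float:
    """ML or ReML log-likelihood (additive constants dropped)."""
    sigma2 = max(params.sigma2, SIGMA2_FLOOR)
    if params.sigma2 <= 0:
        warnings.warn("sigma2 at or below 0 floored for evaluation", RuntimeWarning)
    if cs is None:
        cs = core_solves(pf, params)
    beta = np.asarray(beta, dtype=float).reshape(-1)
    ll = -0.5 * (
        pf.n * np.log(sigma2) + cs.et_Vinv_e(beta) / sigma2 + cs.logdetV
    )
    if reml:
        sign, logdet_xvx = np.linalg.slogdet(cs.XtVinvX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^{-1}X is not positive definite")
        ll -= 0.5 * (-pf.p * np.log(sigma2) + logdet_xvx)
    return float(ll)


# ---------------------------------------------------------------------------
# Parameter representations
# ---------------------------------------------------------------------------

_REPS = ("half", "full", "chol")


@dataclass
class ParamVector:
    """(beta, sigma2, covariance blocks) in one of three flattenings.

    ``half`` stores ``vech(D_k)``, ``full`` stores ``vec(D_k)`` and ``chol``
    stores ``vech(Lambda_k)`` with ``D_k = Lambda_k Lambda_k'`` and
    ``Lambda_k`` lower triangular.
    """

    beta: np.ndarray
    sigma2: float
    blocks: list[np.ndarray]
    rep: str
    q: tuple[int, ...]

    def __post_init__(self):
        if self.rep not in _REPS:
            raise ValueError(f"unknown representation {self.rep!r}")
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.blocks = [np.asarray(b, dtype=float).reshape(-1) for b in self.blocks]

    def Dk_list(self) -> list[np.ndarray]:
        out = []
        for qk, b in zip(self.q, self.blocks):
            if self.rep == "half":
                out.append(unvech(b, qk))
            elif self.rep == "full":
                M = b.reshape(qk, qk, order="F")
                out.append(0.5 * (M + M.T))
            else:
                lam = unvech(b, qk, symmetric=False)
                out.append(lam @ lam.T)
        return out

    def cov_params(self) -> CovarianceParams:
        return CovarianceParams(self.sigma2, self.Dk_list())


def chol_factor(D: np.ndarray) -> np.ndarray:
    """Lower-triangular factor with D = L L', tolerating PSD-singular D."""
    D = 0.5 * (D + D.T)
    try:
        return np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(D)
        if w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise np.linalg.LinAlgError("matrix is not positive semi-definite")
        root = v * np.sqrt(np.clip(w, 0.0, None))
        # re-triangularize the eigendecomposition square root via QR (RQ form)
        _, rt = np.linalg.qr(root.T)
        lam = rt.T
        # fix column signs so the diagonal is non-negative
        signs = np.sign(np.diag(lam))
        signs[signs == 0] = 1.0
        return lam * signs


def from_cov_params(
    beta: np.ndarray, params: CovarianceParams, rep: str = "half"
) -> ParamVector:
    q = tuple(D.shape[0] for D in params.Dk_list)
    if rep == "half":
        blocks = [vech(0.5 * (D + D.T)) for D in params.Dk_list]
    elif rep == "full":
        blocks = [vec(0.5 * (D + D.T)) for D in params.Dk_list]
    elif rep == "chol":
        blocks = [vech(chol_factor(D)) for D in params.Dk_list]
    else:
        raise ValueError(f"unknown representation {rep!r}")
    return ParamVector(beta, params.sigma2, blocks, rep, q)


def convert(theta: ParamVector, to: str) -> ParamVector:
    """Convert between half/full/chol representations.

    Round trips are consistent: full -> half -> full is the identity on
    symmetric blocks (asymmetric full input is symmetrized first), and
    chol -> half reconstructs ``Lambda_k Lambda_k'`` exactly.  Conversion to
    ``chol`` requires every block to be positive semi-definite.
    """
    if to not in _REPS:
        raise ValueError(f"unknown representation {to!r}")
    return from_cov_params(theta.beta, theta.cov_params(), to)
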