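"""Constrained random-effects covariance structures.

A constraint expresses each within-factor covariance block as a smooth
function of a smaller parameter vector ``vecu(D_k)`` — or, in "shared"
mode, expresses all blocks through one common vector ``rho_D``.  The
machinery only needs the constraint (Jacobian) matrix

    C_k = d vec(D_k) / d vecu(D_k)     (rows indexed by vecu),

through which the full-representation partial score and information map as

    score_vecu = C_k . dl/dvec(D_k),
    I_con[(k1, k2)] = C_k1 . I^f_vec(Dk1),vec(Dk2) . C_k2',
    I_con[s2, k]   = I^f_s2,vec(Dk) . C_k'.

Because every reconstruction is a symmetric matrix, ``C_k`` is invariant
under the commutation matrix and the symmetrizer in ``I^f`` drops out, so
the scoring-matrix form ``F`` can be used directly.

Built-in per-factor structures: ``diagonal``, ``compound_symmetry``
(common variance + common covariance) and ``identity_scaled``.  The shared
mode implements the ACE twin model, where observations are family members
(``Z = I_n``), factors are family-structure types, and

    D_k = tau_a^2 K^a_k + tau_c^2 K^c_k,
    tau_a = sigma_a / sigma_e,  tau_c = sigma_c / sigma_e,

with known kinship (``K^a``) and shared-environment (``K^c``) matrices.
The Jacobian of ``tau = [tau_a, tau_c]'`` is

    C = (1_(1,r) (x) diag(2 tau_a, 2 tau_c)) . direct-sum_k [vec(K^a_k)'; vec(K^c_k)'].

Fitting alternates GLS updates for ``(beta, s2)`` with Fisher-scoring
updates on the constrained parameters, with the same step-halving and
convergence control as the unconstrained simplified algorithms; ReML is
supported by mapping the adjusted full-representation score through C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .derivatives import InformationMatrix, ScoreVector, fisher_information, score
from .estimators import (
    SIGMA2_FLOOR,
    FitConfig,
    FitResult,
    _safe_loglik,
    _solve_direction,
    gls_update,
    initial_values,
)
from .matcalc import duplication_matrix, vec, vech_indices
from .model import (
    CovarianceParams,
    LMMDesign,
    ProductForms,
    core_solves,
    log_likelihood,
    product_forms,
)

__all__ = [
    "FactorConstraint",
    "SharedConstraint",
    "ConstraintSpec",
    "builtin_constraints",
    "unconstrained_equivalent",
    "explicit_linear_constraint",
    "ace_constraint_matrix",
    "ace_constraint",
    "constrained_score_fim",
    "fit_constrained",
]


@dataclass
class FactorConstraint:
    """Constraint for one factor: reconstruction map and its Jacobian.

    ``reconstruct(u) -> D_k`` must return a symmetric (q_k x q_k) matrix;
    ``jacobian(u)`` returns C_k with shape (n_params, q_k^2); ``initial``
    extracts a starting vecu from an unconstrained D_k estimate.
    """

    name: str
    n_params: int
    q_k: int
    reconstruct: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    initial: Callable[[np.ndarray], np.ndarray]


@dataclass
class SharedConstraint:
    """One parameter vector rho_D driving every covariance block jointly."""

    name: str
    n_params: int
    q: tuple[int, ...]
    reconstruct: Callable[[np.ndarray], list[np.ndarray]]
    jacobian: Callable[[np.ndarray], np.ndarray]  # (n_params, sum q_k^2)
    initial: Callable[[Sequence[np.ndarray]], np.ndarray]


@dataclass
class ConstraintSpec:
    """Either one :class:`FactorConstraint` per factor or a shared vector."""

    mode: str  # "per_factor" | "shared"
    per_factor: list[FactorConstraint] | None = None
    shared: SharedConstraint | None = None

    def __post_init__(self):
        if self.mode not in ("per_factor", "shared"):
            raise ValueError("mode must be 'per_factor' or 'shared'")
        if self.mode == "per_factor" and not self.per_factor:
            raise ValueError("per_factor constraints missing")
        if self.mode == "shared" and self.shared is None:
            raise ValueError("shared constraint missing")


# ---------------------------------------------------------------------------
# built-in per-factor structures
# ---------------------------------------------------------------------------


def _diag_constraint(q_k: int) -> FactorConstraint:
    C = np.zeros((q_k, q_k * q_k))
    for i in range(q_k):
        C[i, i * q_k + i] = 1.0
    return FactorConstraint(
        name="diagonal",
        n_params=q_k,
        q_k=q_k,
        reconstruct=lambda u: np.diag(np.asarray(u, dtype=float)),
        jacobian=lambda u, C=C: C,
        initial=lambda D: np.diag(D).copy(),
    )


def _cs_constraint(q_k: int) -> FactorConstraint:
    # vecu = (common variance v, common covariance c)
    C = np.zeros((2, q_k * q_k))
    for i in range(q_k):
        for j in range(q_k):
            C[0 if i == j else 1, j * q_k + i] = 1.0

    def rec(u):
        v, c = u
        return c * np.ones((q_k, q_k)) + (v - c) * np.eye(q_k)

    def init(D):
        off = D[~np.eye(q_k, dtype=bool)]
        return np.array([np.diag(D).mean(), off.mean() if off.size else 0.0])

    return FactorConstraint("compound_symmetry", 2, q_k, rec, lambda u, C=C: C, init)


def _identity_constraint(q_k: int) -> FactorConstraint:
    C = vec(np.eye(q_k))[None, :]
    return FactorConstraint(
        name="identity_scaled",
        n_params=1,
        q_k=q_k,
        reconstruct=lambda u: float(u[0]) * np.eye(q_k),
        jacobian=lambda u, C=C: C,
        initial=lambda D: np.array([np.diag(D).mean()]),
    )


def builtin_constraints(name: str, q_k: int) -> FactorConstraint:
    """Return a built-in per-factor constraint by name."""
    if q_k < 1:
        raise ValueError("q_k must be >= 1")
    builders = {
        "diagonal": _diag_constraint,
        "compound_symmetry": _cs_constraint,
        "identity_scaled": _identity_constraint,
    }
    try:
        return builders[name](q_k)
    except KeyError:
        raise ValueError(
            f"unknown constraint {name!r}; choose from {sorted(builders)}"
        ) from None


def unconstrained_equivalent(q_k: int) -> FactorConstraint:
    """vecu = vech(D_k): reduces exactly to the half representation."""
    C = duplication_matrix(q_k).T
    r, c = vech_indices(q_k)

    def rec(u):
        from .matcalc import unvech

        return unvech(np.asarray(u, dtype=float), q_k)

    return FactorConstraint(
        name="unconstrained",
        n_params=q_k * (q_k + 1) // 2,
        q_k=q_k,
        reconstruct=rec,
        jacobian=lambda u, C=C: C,
        initial=lambda D: D[r, c].copy(),
    )


def explicit_linear_constraint(C: np.ndarray, q_k: int, name: str = "explicit") -> FactorConstraint:
    """Linear structure vec(D_k) = C' vecu, with user-supplied C_k."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] != q_k * q_k:
        raise ValueError("C_k must have q_k^2 columns")

    def rec(u):
        M = (C.T @ np.asarray(u, dtype=float)).reshape(q_k, q_k, order="F")
        return 0.5 * (M + M.T)

    def init(D):
        return np.linalg.lstsq(C.T, vec(0.5 * (D + D.T)), rcond=None)[0]

    return FactorConstraint(name, C.shape[0], q_k, rec, lambda u, C=C: C, init)


# ---------------------------------------------------------------------------
# ACE twin model
# ---------------------------------------------------------------------------


def ace_constraint_matrix(
    tau_a: float,
    tau_c: float,
    Ka_list: Sequence[np.ndarray],
    Kc_list: Sequence[np.ndarray],
) -> np.ndarray:
    """Jacobian of tau = [tau_a, tau_c]' onto the stacked vec(D_k)."""
    if len(Ka_list) != len(Kc_list) or not Ka_list:
        raise ValueError("one K^a and one K^c matrix per family-structure type")
    blocks = [
        np.vstack([vec(np.asarray(Ka, dtype=float)), vec(np.asarray(Kc, dtype=float))])
        for Ka, Kc in zip(Ka_list, Kc_list)
    ]
    r = len(blocks)
    scale = np.kron(np.ones((1, r)), np.diag([2.0 * tau_a, 2.0 * tau_c]))
    return scale @ scipy.linalg.block_diag(*blocks)


def ace_constraint(
    Ka_list: Sequence[np.ndarray], Kc_list: Sequence[np.ndarray]
) -> SharedConstraint:
    """Shared-mode constraint for the ACE model, rho_D = [tau_a, tau_c]'."""
    Ka = [np.asarray(K, dtype=float) for K in Ka_list]
    Kc = [np.asarray(K, dtype=float) for K in Kc_list]
    q = tuple(K.shape[0] for K in Ka)
    for k, (a, c) in enumerate(zip(Ka, Kc)):
        if a.shape != c.shape or a.shape[0] != a.shape[1]:
            raise ValueError(f"type {k}: K matrices must be square and matching")

    def rec(tau):
        ta, tc = tau
        return [ta**2 * a + tc**2 * c for a, c in zip(Ka, Kc)]

    def jac(tau):
        return ace_constraint_matrix(tau[0], tau[1], Ka, Kc)

    def init(Dk_list):
        # least-squares fit of (tau_a^2, tau_c^2) to the stacked blocks
        A = np.column_stack(
            [np.concatenate([vec(a) for a in Ka]), np.concatenate([vec(c) for c in Kc])]
        )
        b = np.concatenate([vec(0.5 * (D + D.T)) for D in Dk_list])
        sq = np.linalg.lstsq(A, b, rcond=None)[0]
        return np.sqrt(np.clip(sq, 1e-6, None))

    return SharedConstraint("ace", 2, q, rec, jac, init)


# ---------------------------------------------------------------------------
# constrained score / information and fitting
# ---------------------------------------------------------------------------


def _jacobians(spec: ConstraintSpec, u) -> list[np.ndarray]:
    if spec.mode == "per_factor":
        return [fc.jacobian(uk) for fc, uk in zip(spec.per_factor, u)]
    return [spec.shared.jacobian(u)]


def constrained_score_fim(
    pf: ProductForms,
    params: CovarianceParams,
    beta: np.ndarray,
    spec: ConstraintSpec,
    u,
    reml: bool = False,
    cs=None,
) -> tuple[ScoreVector, InformationMatrix]:
    """Score and expected information over (s2, vecu/rho_D) at ``u``.

    ``u`` is a list of per-factor vecu vectors (per_factor mode) or the
    shared rho_D vector.  The beta blocks are unchanged from the
    unconstrained model and zero off-diagonal, as in the full
    representation.
    """
    if cs is None:
        cs = core_solves(pf, params)
    sv_full = score(pf, params, beta, rep="full", reml=reml, cs=cs)
    im_full = fisher_information(
        pf, params, rep="full", scoring_matrix=True, reml=reml, cs=cs
    )
    r = pf.fs.r
    if spec.mode == "per_factor":
        if len(spec.per_factor) != r:
            raise ValueError("one FactorConstraint per factor is required")
        Cs = _jacobians(spec, u)
        d_cov = [C @ sv_full.d_cov[k] for k, C in enumerate(Cs)]
        s2_cov = [im_full.sigma2_cov[k] @ C.T for k, C in enumerate(Cs)]
        blocks = {
            (k1, k2): Cs[k1] @ im_full.cov_blocks[(k1, k2)] @ Cs[k2].T
            for k1 in range(r)
            for k2 in range(r)
        }
    else:
        C = _jacobians(spec, u)[0]
        if C.shape[1] != sum(qk * qk for qk in pf.fs.q):
            raise ValueError("shared constraint Jacobian has wrong width")
        full_cov = np.concatenate(sv_full.d_cov)
        sizes = [qk * qk for qk in pf.fs.q]
        starts = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        big = np.zeros((starts[-1], starts[-1]))
        s2row = np.zeros(starts[-1])
        for k1 in range(r):
            s2row[starts[k1] : starts[k1 + 1]] = im_full.sigma2_cov[k1]
            for k2 in range(r):
                big[starts[k1] : starts[k1 + 1], starts[k2] : starts[k2 + 1]] = (
                    im_full.cov_blocks[(k1, k2)]
                )
        d_cov = [C @ full_cov]
        s2_cov = [s2row @ C.T]
        blocks = {(0, 0): C @ big @ C.T}
    sv = ScoreVector(sv_full.d_beta, sv_full.d_sigma2, d_cov, "constrained", reml)
    im = InformationMatrix(
        beta_block=im_full.beta_block,
        sigma2_entry=im_full.sigma2_entry,
        sigma2_cov=s2_cov,
        cov_blocks=blocks,
        rep="constrained",
        is_scoring_matrix=True,
    )
    return sv, im


@dataclass
class ConstrainedFitResult(FitResult):
    """Fit result carrying the constrained parameter estimates."""

    u_hat: list[np.ndarray] | np.ndarray | None = None
    spec: ConstraintSpec | None = None


def fit_constrained(
    data: LMMDesign | ProductForms,
    spec: ConstraintSpec,
    config: FitConfig | None = None,
    **kwargs,
) -> ConstrainedFitResult:
    """GLS + constrained Fisher-scoring fit under a covariance constraint."""
    if config is None:
        config = FitConfig(**kwargs)
    pf = product_forms(data) if isinstance(data, LMMDesign) else data
    fs = pf.fs
    beta, sigma2, Dk0, warns = initial_values(pf)
    if spec.mode == "per_factor":
        u = [fc.initial(Dk0[k]) for k, fc in enumerate(spec.per_factor)]
        Dk = [fc.reconstruct(u[k]) for k, fc in enumerate(spec.per_factor)]
    else:
        u = spec.shared.initial(Dk0)
        Dk = spec.shared.reconstruct(u)
    ll = _safe_loglik(pf, sigma2, Dk, beta, config.reml)
    trace = [ll]
    converged = False
    n_iter = 0
    for _ in range(config.max_iter):
        n_iter += 1
        params = CovarianceParams(sigma2, Dk)
        cs = core_solves(pf, params)
        beta, sigma2 = gls_update(pf, params, reml=config.reml, cs=cs)
        if sigma2 <= SIGMA2_FLOOR:
            sigma2 = SIGMA2_FLOOR
            warns.append("sigma2 at the evaluation floor")
        params = CovarianceParams(sigma2, Dk)
        sv, im = constrained_score_fim(
            pf, params, beta, spec, u, reml=config.reml, cs=cs
        )
        if spec.mode == "per_factor":
            dirs = [
                _solve_direction(im.cov_blocks[(k, k)], sv.d_cov[k], warns, f"vecu_{k}")
                for k in range(fs.r)
            ]
        else:
            dirs = [_solve_direction(im.cov_blocks[(0, 0)], sv.d_cov[0], warns, "rho_D")]
        ll_ref = log_likelihood(pf, params, beta, reml=config.reml, cs=cs)
        u, Dk, ll_new = _try_step_constrained(
            pf, config, sigma2, beta, spec, u, dirs, ll_ref, warns
        )
        trace.append(ll_new)
        if abs(ll_new - ll) < config.tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if not converged:
        warns.append("maximum number of iterations reached")
    params = CovarianceParams(sigma2, Dk)
    beta, sigma2 = gls_update(pf, params, reml=config.reml)
    trace.append(_safe_loglik(pf, sigma2, Dk, beta, config.reml))
    return ConstrainedFitResult(
        beta=beta, sigma2=sigma2, Dk_list=Dk, loglik_trace=trace,
        n_iter=n_iter, converged=converged, method="constrained",
        reml=config.reml, warnings=warns, u_hat=u, spec=spec,
    )


def _try_step_constrained(pf, config, sigma2, beta, spec, u, dirs, ll, warns):
    alpha = 1.0
    for _ in range(config.max_halvings + 1):
        if spec.mode == "per_factor":
            u_new = [uk + alpha * d for uk, d in zip(u, dirs)]
            Dk_new = [
                fc.reconstruct(u_new[k]) for k, fc in enumerate(spec.per_factor)
            ]
        else:
            u_new = u + alpha * dirs[0]
            Dk_new = spec.shared.reconstruct(u_new)
        ll_new = _safe_loglik(pf, sigma2, Dk_new, beta, config.reml)
        if ll_new >= ll:
            return u_new, Dk_new, ll_new
        alpha *= 0.5
    warns.append("step halving exhausted; zero step accepted")
    if spec.mode == "per_factor":
        Dk = [fc.reconstruct(u[k]) for k, fc in enumerate(spec.per_factor)]
    else:
        Dk = spec.shared.reconstruct(u)
    return u, Dk, ll
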