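"""Synthetic-data generation and benchmarking harnesses.

Data are generated from the model ``Y = X beta + Z b + eps`` with
``b ~ N(0, s2 D)`` and ``eps ~ N(0, s2 I)``.  The first column of ``X``
and the first random effect of every factor are intercepts (constant 1);
all remaining fixed and random covariates are i.i.d. standard normal, and
observations are assigned to levels uniformly at random (redrawn in the
rare event a level ends up empty, which would make its covariance block
unidentifiable).

Three preset study designs are provided, all with ``n = 1000``:

======== === ============ ================
 preset    r    q (effects)   l (levels)
======== === ============ ================
 1          1   (2,)          (50,)
 2          2   (3, 2)        (100, 50)
 3          3   (4, 3, 2)     (100, 50, 10)
======== === ============ ================

True parameter values default to documented stand-ins (fixed effects in
[-1, 1] with the last one exactly zero so that null-contrast inference can
be exercised, unit residual variance, covariance blocks with a mixture of
zero and nonzero off-diagonal entries); callers may substitute any other
truth.

Benchmark harnesses:

- :func:`estimation_benchmark` runs a set of fitting methods on identical
  replicated datasets and reports iteration counts, convergence failures
  and MAE/MRD of ``beta`` and of the variance product ``s2 D`` against the
  truth (and between methods).  MAE is ``mean_i |a_i - b_i|`` and MRD is
  ``mean_i |a_i - b_i| / mean_i ((|a_i| + |b_i|)/2)``.
- :func:`dof_benchmark` fixes one randomly drawn design, redraws ``(b,
  eps)`` per replicate, ReML-fits each replicate and records the direct
  Satterthwaite degrees of freedom for a truly-zero fixed effect, together
  with a moment-matching truth: the ``2 (S^2)^2`` numerators from the main
  run averaged over an empirical ``Var(S^2)`` estimated from a separate,
  larger run.

Randomness is governed by ``numpy.random.SeedSequence``: one parent seed
per harness spawns independent child streams per replicate, so methods
within a replicate always see identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import FitConfig, FitResult, fit
from .inference import Contrast, approx_t
from .model import LMMDesign, build_design, product_forms

__all__ = [
    "SimulationSetting",
    "preset_setting",
    "generate_dataset",
    "generate_twin_dataset",
    "mae",
    "mrd",
    "BenchmarkReport",
    "estimation_benchmark",
    "dof_benchmark",
]

_DEFAULT_BETA = np.array([0.5, -0.3, 0.8, 0.0])
_DEFAULT_SIGMA2 = 1.0

_DEFAULT_D = {
    2: np.array([[1.0, 0.5], [0.5, 0.8]]),
    3: np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 0.75]]),
    4: np.array(
        [
            [1.0, 0.4, 0.0, 0.0],
            [0.4, 0.8, 0.3, 0.0],
            [0.0, 0.3, 0.9, 0.0],
            [0.0, 0.0, 0.0, 0.6],
        ]
    ),
}


@dataclass
class SimulationSetting:
    """A study design plus the true generating parameters."""

    q: tuple[int, ...]
    l: tuple[int, ...]
    n: int = 1000
    beta_true: np.ndarray = field(default_factory=lambda: _DEFAULT_BETA.copy())
    sigma2_true: float = _DEFAULT_SIGMA2
    Dk_true: list[np.ndarray] | None = None

    def __post_init__(self):
        self.q = tuple(int(x) for x in self.q)
        self.l = tuple(int(x) for x in self.l)
        self.beta_true = np.asarray(self.beta_true, dtype=float).reshape(-1)
        if self.Dk_true is None:
            self.Dk_true = [_DEFAULT_D[qk].copy() for qk in self.q]
        self.Dk_true = [np.asarray(D, dtype=float) for D in self.Dk_true]
        for qk, D in zip(self.q, self.Dk_true):
            if D.shape != (qk, qk) or not np.allclose(D, D.T):
                raise ValueError("each true D_k must be symmetric (q_k x q_k)")
        w = [np.linalg.eigvalsh(D).min() for D in self.Dk_true]
        if min(w) < -1e-10:
            raise ValueError("true covariance blocks must be PSD")

    @property
    def r(self) -> int:
        return len(self.q)

    @property
    def p(self) -> int:
        return self.beta_true.size


def preset_setting(number: int, **overrides) -> SimulationSetting:
    """The three preset crossed designs (n = 1000)."""
    presets = {
        1: dict(q=(2,), l=(50,)),
        2: dict(q=(3, 2), l=(100, 50)),
        3: dict(q=(4, 3, 2), l=(100, 50, 10)),
    }
    if number not in presets:
        raise ValueError("preset number must be 1, 2 or 3")
    kw = dict(presets[number])
    kw.update(overrides)
    return SimulationSetting(**kw)


def _draw_levels(rng: np.random.Generator, n: int, lk: int) -> np.ndarray:
    for _ in range(100):
        lev = rng.integers(0, lk, size=n)
        if len(np.unique(lev)) == lk:
            return lev
    raise RuntimeError(
        f"could not occupy all {lk} levels with {n} observations; "
        "reduce the level count"
    )


def generate_dataset(
    setting: SimulationSetting, seed: int | np.random.Generator = 0
) -> tuple[LMMDesign, dict]:
    """Draw one dataset; returns the design and the generating truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = setting.n, setting.p
    X = np.concatenate([np.ones((n, 1)), rng.standard_normal((n, p - 1))], axis=1)
    tables = []
    b_parts = []
    for k, (qk, lk) in enumerate(zip(setting.q, setting.l)):
        lev = _draw_levels(rng, n, lk)
        covs = np.concatenate(
            [np.ones((n, 1)), rng.standard_normal((n, qk - 1))], axis=1
        )
        tables.append((lev, covs))
        cov_b = setting.sigma2_true * setting.Dk_true[k]
        Lb = np.linalg.cholesky(cov_b + 1e-12 * np.eye(qk))
        b_parts.append((rng.standard_normal((lk, qk)) @ Lb.T).reshape(-1))
    b = np.concatenate(b_parts)
    eps = np.sqrt(setting.sigma2_true) * rng.standard_normal(n)
    design = build_design(np.zeros(n), X, tables)
    Y = X @ setting.beta_true + design.Z() @ b + eps
    design = LMMDesign(Y=Y, X=X, fs=design.fs, raw_covariates=design.raw_covariates)
    truth = {
        "beta": setting.beta_true.copy(),
        "sigma2": setting.sigma2_true,
        "Dk_list": [D.copy() for D in setting.Dk_true],
        "b": b,
    }
    return design, truth


def generate_twin_dataset(
    n_families: Sequence[int],
    Ka_list: Sequence[np.ndarray],
    Kc_list: Sequence[np.ndarray],
    beta_true: np.ndarray,
    tau_a: float,
    tau_c: float,
    sigma2_e: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[LMMDesign, dict]:
    """Synthetic twin-study data for the ACE model.

    Factor ``k`` is a family-structure type with kinship/shared-environment
    matrices ``K^a_k``, ``K^c_k`` (size ``q_k`` = family size) and
    ``n_families[k]`` families.  Every subject is one observation with its
    own unit random effect, so ``Z`` restricted to each family is an
    identity block and ``D_k = tau_a^2 K^a_k + tau_c^2 K^c_k``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta_true = np.asarray(beta_true, dtype=float).reshape(-1)
    p = beta_true.size
    sizes = [np.asarray(K).shape[0] for K in Ka_list]
    n = int(sum(lf * qk for lf, qk in zip(n_families, sizes)))
    X = np.concatenate([np.ones((n, 1)), rng.standard_normal((n, p - 1))], axis=1)
    gamma = np.zeros(n)
    row = 0
    for k, (lf, qk) in enumerate(zip(n_families, sizes)):
        Dk = tau_a**2 * np.asarray(Ka_list[k], float) + tau_c**2 * np.asarray(
            Kc_list[k], float
        )
        Lb = np.linalg.cholesky(sigma2_e * Dk + 1e-12 * np.eye(qk))
        for j in range(lf):
            gamma[row : row + qk] = Lb @ rng.standard_normal(qk)
            row += qk
    # rows outside factor k's own families sit in level 0 with zero covariates
    tables = _twin_tables(n_families, sizes)
    design0 = build_design(np.zeros(n), X, tables)
    eps = np.sqrt(sigma2_e) * rng.standard_normal(n)
    Y = X @ beta_true + gamma + eps
    design = LMMDesign(Y=Y, X=X, fs=design0.fs, raw_covariates=design0.raw_covariates)
    truth = {
        "beta": beta_true.copy(),
        "tau_a": tau_a,
        "tau_c": tau_c,
        "sigma2_e": sigma2_e,
        "sigma2_a": tau_a**2 * sigma2_e,
        "sigma2_c": tau_c**2 * sigma2_e,
    }
    return design, truth


def _twin_tables(n_families, sizes):
    n = int(sum(lf * qk for lf, qk in zip(n_families, sizes)))
    tables = []
    start = 0
    for lf, qk in zip(n_families, sizes):
        block = lf * qk
        lev = np.zeros(n, dtype=np.intp)
        covs = np.zeros((n, qk))
        rows = np.arange(start, start + block)
        lev[rows] = np.repeat(np.arange(lf), qk)
        covs[rows, np.tile(np.arange(qk), lf)] = 1.0
        tables.append((lev, covs))
        start += block
    return tables


# ---------------------------------------------------------------------------
# metrics and benchmarks
# ---------------------------------------------------------------------------


def mae(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    return float(np.mean(np.abs(a - b)))


def mrd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    denom = np.mean((np.abs(a) + np.abs(b)) / 2.0)
    return float(np.mean(np.abs(a - b)) / denom) if denom > 0 else 0.0


def _sigma2D_vector(result_or_truth) -> np.ndarray:
    if isinstance(result_or_truth, FitResult):
        s2, Dk = result_or_truth.sigma2, result_or_truth.Dk_list
    else:
        s2, Dk = result_or_truth["sigma2"], result_or_truth["Dk_list"]
    return np.concatenate([(s2 * D).ravel() for D in Dk])


@dataclass
class BenchmarkReport:
    """Per-method summary of an estimation benchmark."""

    summary: pd.DataFrame  # indexed by method
    per_replicate: pd.DataFrame
    setting: SimulationSetting
    reml: bool

    def to_json_dict(self) -> dict:
        return {
            "reml": self.reml,
            "summary": self.summary.to_dict(orient="index"),
        }


def estimation_benchmark(
    setting: SimulationSetting,
    methods: Sequence[str] = ("fs", "ffs", "sfs", "fsfs", "csfs"),
    reml: bool = False,
    n_reps: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
    reference: str | None = None,
) -> BenchmarkReport:
    """Run every method on identical replicated datasets and summarize."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        design, truth = generate_dataset(setting, rng)
        pf = product_forms(design)
        fits = {}
        for m in methods:
            try:
                res = fit(pf, FitConfig(method=m, reml=reml, tol=tol))
            except np.linalg.LinAlgError:
                res = None
            fits[m] = res
        ref = fits.get(reference) if reference else None
        for m, res in fits.items():
            if res is None:
                rows.append(
                    dict(rep=rep, method=m, converged=False, n_iter=np.nan,
                         llf=np.nan, mae_beta=np.nan, mrd_beta=np.nan,
                         mae_s2D=np.nan, mrd_s2D=np.nan)
                )
                continue
            row = dict(
                rep=rep, method=m, converged=res.converged, n_iter=res.n_iter,
                llf=res.llf,
                mae_beta=mae(res.beta, truth["beta"]),
                mrd_beta=mrd(res.beta, truth["beta"]),
                mae_s2D=mae(_sigma2D_vector(res), _sigma2D_vector(truth)),
                mrd_s2D=mrd(_sigma2D_vector(res), _sigma2D_vector(truth)),
            )
            if ref is not None and ref is not res:
                row["mae_beta_ref"] = mae(res.beta, ref.beta)
                row["mrd_beta_ref"] = mrd(res.beta, ref.beta)
                row["mae_s2D_ref"] = mae(_sigma2D_vector(res), _sigma2D_vector(ref))
                row["mrd_s2D_ref"] = mrd(_sigma2D_vector(res), _sigma2D_vector(ref))
            rows.append(row)
    per_rep = pd.DataFrame(rows)
    agg = {
        "n_iter": ["mean", "std"],
        "mae_beta": "mean",
        "mrd_beta": "mean",
        "mae_s2D": "mean",
        "mrd_s2D": "mean",
    }
    summary = per_rep.groupby("method").agg(agg)
    summary.columns = ["_".join(c).rstrip("_") if c[1] else c[0] for c in summary.columns]
    summary["failure_rate"] = 1.0 - per_rep.groupby("method")["converged"].mean()
    return BenchmarkReport(summary=summary, per_replicate=per_rep, setting=setting, reml=reml)


def dof_benchmark(
    setting: SimulationSetting,
    n_reps: int = 1000,
    n_truth_reps: int = 0,
    seed: int = 0,
    method: str = "fsfs",
) -> dict:
    """Direct Satterthwaite dof for a truly-zero fixed effect on one design.

    Draws a single (X, Z) design, then redraws ``(b, eps)`` per replicate,
    ReML-fits and records the direct-SW degrees of freedom.  When
    ``n_truth_reps > 0`` an additional run estimates ``Var(S^2)``
    empirically; the harness truth is the average of the per-replicate
    numerators ``2 (S^2)^2`` divided by that variance.
    """
    zero_idx = np.flatnonzero(setting.beta_true == 0.0)
    if zero_idx.size == 0:
        raise ValueError("the setting's true beta must contain a zero entry")
    ci = int(zero_idx[-1])
    L = np.zeros(setting.p)
    L[ci] = 1.0

    parent = np.random.SeedSequence(seed)
    children = parent.spawn(1 + n_reps + n_truth_reps)
    design_rng = np.random.default_rng(children[0])
    base_design, _ = generate_dataset(setting, design_rng)
    X, fs, raw = base_design.X, base_design.fs, base_design.raw_covariates
    Z = base_design.Z()

    def one_rep(rng):
        b_parts = []
        for k, (qk, lk) in enumerate(zip(setting.q, setting.l)):
            Lb = np.linalg.cholesky(
                setting.sigma2_true * setting.Dk_true[k] + 1e-12 * np.eye(qk)
            )
            b_parts.append((rng.standard_normal((lk, qk)) @ Lb.T).reshape(-1))
        eps = np.sqrt(setting.sigma2_true) * rng.standard_normal(setting.n)
        Y = X @ setting.beta_true + Z @ np.concatenate(b_parts) + eps
        design = LMMDesign(Y=Y, X=X, fs=fs, raw_covariates=raw)
        pf = product_forms(design)
        res = fit(pf, FitConfig(method=method, reml=True))
        if not res.converged:
            return None
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            dr = approx_t(res, pf, Contrast(L))
        return dr.dof, dr.s2

    dofs, s2s, dropped = [], [], 0
    for child in children[1 : 1 + n_reps]:
        out = one_rep(np.random.default_rng(child))
        if out is None:
            dropped += 1
            continue
        dofs.append(out[0])
        s2s.append(out[1])
    result = {
        "mean_dof": float(np.mean(dofs)),
        "sd_dof": float(np.std(dofs, ddof=1)) if len(dofs) > 1 else 0.0,
        "n_used": len(dofs),
        "n_dropped": dropped,
        "contrast_index": ci,
    }
    if n_truth_reps > 0:
        truth_s2 = []
        for child in children[1 + n_reps :]:
            out = one_rep(np.random.default_rng(child))
            if out is not None:
                truth_s2.append(out[1])
        var_s2 = float(np.var(truth_s2, ddof=1))
        result["truth_dof"] = float(np.mean([2.0 * s**2 for s in s2s]) / var_s2)
        result["truth_n"] = len(truth_s2)
    return result
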