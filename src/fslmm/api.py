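"""Model/Results interface for crossed-factor linear mixed models.

`CrossedLMM` is constructed from a response, a fixed-effects design and a
random-effects specification (per factor: level assignment plus the
per-level covariate columns), either from arrays or from a DataFrame.
``fit()`` runs one of the five Fisher-scoring variants and returns a
`CrossedLMMResults` carrying estimates, standard errors, the
log-likelihood trace and Satterthwaite-based t-tests.

Example
-------
>>> import numpy as np, pandas as pd
>>> from fslmm import CrossedLMM
>>> df = ...  # columns: y, x1, subject, location
>>> model = CrossedLMM.from_dataframe(
...     df, response="y", fixed=["x1"],
...     factors={"subject": ([], True), "location": ([], True)})
>>> res = model.fit(method="fsfs", reml=True)
>>> print(res.summary())
>>> res.t_test([0, 1])
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constrained import ConstraintSpec, fit_constrained
from .estimators import FitConfig, FitResult, fit
from .inference import Contrast, DoFResult, approx_t
from .model import LMMDesign, ProductForms, build_design, product_forms

__all__ = ["CrossedLMM", "CrossedLMMResults"]


class CrossedLMM:
    """Linear mixed model with crossed random factors.

    Parameters
    ----------
    endog : response vector (n,).
    exog : fixed-effects design (n, p); include the intercept column
        explicitly.
    factors : sequence of ``(levels, covariates)`` pairs, one per random
        factor: a length-n integer level assignment and the (n, q_k)
        random-effect covariate values.
    names : optional fixed-effect names for reporting.
    """

    def __init__(self, endog, exog, factors, names=None, factor_names=None):
        self.design: LMMDesign = build_design(endog, exog, list(factors))
        p = self.design.p
        self.exog_names = list(names) if names else [f"x{i}" for i in range(p)]
        r = self.design.fs.r
        self.factor_names = (
            list(factor_names) if factor_names else [f"factor{k}" for k in range(r)]
        )
        self._pf: ProductForms | None = None

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed: Sequence[str],
        factors: Mapping[str, tuple[Sequence[str], bool]],
        add_intercept: bool = True,
    ) -> "CrossedLMM":
        """Build the model from named columns of a DataFrame.

        ``factors`` maps a level column name to ``(effect_columns,
        random_intercept)``; level columns may hold arbitrary labels and
        are factorized in order of first appearance.
        """
        for col in [response, *fixed]:
            if col not in data.columns:
                raise KeyError(f"column {col!r} not found in the data")
        y = data[response].to_numpy(dtype=float)
        X = data[list(fixed)].to_numpy(dtype=float) if fixed else np.empty((len(data), 0))
        names = list(fixed)
        if add_intercept:
            X = np.concatenate([np.ones((len(data), 1)), X], axis=1)
            names = ["const", *names]
        fac, fac_names = [], []
        for level_col, (effect_cols, intercept) in factors.items():
            if level_col not in data.columns:
                raise KeyError(f"level column {level_col!r} not found in the data")
            codes, _ = pd.factorize(data[level_col], sort=True)
            covs = [np.ones(len(data))] if intercept else []
            for c in effect_cols:
                if c not in data.columns:
                    raise KeyError(f"effect column {c!r} not found in the data")
                covs.append(data[c].to_numpy(dtype=float))
            if not covs:
                raise ValueError(f"factor {level_col!r} has no random effects")
            fac.append((codes, np.column_stack(covs)))
            fac_names.append(level_col)
        return cls(y, X, fac, names=names, factor_names=fac_names)

    @property
    def product_forms(self) -> ProductForms:
        if self._pf is None:
            self._pf = product_forms(self.design)
        return self._pf

    def fit(
        self,
        method: str = "fsfs",
        reml: bool = False,
        tol: float = 1e-6,
        max_iter: int = 200,
        constraints: ConstraintSpec | None = None,
    ) -> "CrossedLMMResults":
        config = FitConfig(method=method, reml=reml, tol=tol, max_iter=max_iter)
        if constraints is not None:
            raw = fit_constrained(self.product_forms, constraints, config=None,
                                  reml=reml, tol=tol, max_iter=max_iter)
        else:
            raw = fit(self.product_forms, config)
        return CrossedLMMResults(self, raw)


class CrossedLMMResults:
    """Estimates, uncertainties and tests from a fitted :class:`CrossedLMM`."""

    def __init__(self, model: CrossedLMM, raw: FitResult):
        self.model = model
        self.raw = raw

    # ----- estimates -------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.raw.beta, index=self.model.exog_names)

    @property
    def sigma2(self) -> float:
        return self.raw.sigma2

    @property
    def cov_re(self) -> list[np.ndarray]:
        """Random-effect covariance blocks on the response scale, s2 * D_k."""
        return [self.raw.sigma2 * D for D in self.raw.Dk_list]

    @property
    def Dk_list(self) -> list[np.ndarray]:
        return self.raw.Dk_list

    @property
    def llf(self) -> float:
        return self.raw.llf

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def n_iter(self) -> int:
        return self.raw.n_iter

    @property
    def bse(self) -> pd.Series:
        """Standard errors of the fixed effects, sqrt diag (s2 (X'V^-1 X)^-1)."""
        from .model import core_solves

        cs = core_solves(self.model.product_forms, self.raw.cov_params())
        cov = self.raw.sigma2 * np.linalg.inv(cs.XtVinvX)
        return pd.Series(np.sqrt(np.diag(cov)), index=self.model.exog_names)

    # ----- inference -------------------------------------------------------
    def t_test(self, L) -> DoFResult:
        """Approximate t-test of ``L beta = 0`` with direct-SW dof."""
        return approx_t(self.raw, self.model.product_forms, Contrast(np.asarray(L, float)))

    def t_table(self) -> pd.DataFrame:
        rows = []
        p = len(self.model.exog_names)
        for i, name in enumerate(self.model.exog_names):
            L = np.zeros(p)
            L[i] = 1.0
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dr = self.t_test(L)
            rows.append(
                dict(name=name, coef=self.raw.beta[i], t=dr.t_stat, dof=dr.dof,
                     p_value=dr.p_value)
            )
        return pd.DataFrame(rows).set_index("name")

    # ----- reporting -------------------------------------------------------
    def summary(self) -> str:
        raw = self.raw
        crit = "ReML" if raw.reml else "ML"
        lines = [
            "Crossed-factor linear mixed model",
            "=" * 64,
            f"Method: {raw.method.upper():<8} Criterion: {crit:<6} "
            f"Converged: {raw.converged} (iter {raw.n_iter})",
            f"Log-likelihood ({crit}, constants dropped): {raw.llf:.6f}",
            f"Residual variance sigma2: {raw.sigma2:.6f}",
            "",
            "Fixed effects",
            "-" * 64,
        ]
        tab = self.t_table()
        bse = self.bse
        for name, row in tab.iterrows():
            lines.append(
                f"{name:<12} coef {row.coef:>10.4f}  se {bse[name]:>8.4f}  "
                f"t {row.t:>8.3f}  dof {row.dof:>8.1f}  p {row.p_value:>8.4f}"
            )
        lines += ["", "Random-effect covariances (sigma2 * D_k)", "-" * 64]
        for name, G in zip(self.model.factor_names, self.cov_re):
            lines.append(f"{name}:")
            for r_ in G:
                lines.append("    " + "  ".join(f"{v:>9.4f}" for v in r_))
        if raw.warnings:
            lines += ["", "Warnings: " + "; ".join(sorted(set(raw.warnings)))]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<CrossedLMMResults method={self.raw.method} "
            f"reml={self.raw.reml} llf={self.raw.llf:.4f} "
            f"converged={self.raw.converged}>"
        )
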