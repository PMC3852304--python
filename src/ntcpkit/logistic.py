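"""Multivariate logistic NTCP model.

The normal tissue complication probability is modelled as

    NTCP = exp(g) / (1 + exp(g)),    g(x) = b0 + b1*x1 + ... + bn*xn,

where the x_i are patient covariates (binary factors coded yes=1/no=0 and
dose-volume covariates on the raw percent scale 0-100) and the b_i are
logistic regression coefficients.  ``LogisticNTCP`` is the model class;
``LogisticNTCP(...).fit()`` returns a ``LogisticNTCPResults`` object carrying
maximum-likelihood estimates, Wald standard errors/p-values and odds ratios.
A fitted (or externally supplied) coefficient set travels as the lightweight
``LogisticNTCPModel``, which predicts NTCP for new covariate vectors and
serialises to flat JSON text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "LogisticNTCPModel",
    "LogisticNTCP",
    "LogisticNTCPResults",
    "PerfectSeparationError",
]


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded: a covariate separates the outcome."""


@dataclass
class LogisticNTCPModel:
    """A logistic NTCP coefficient set.

    Parameters
    ----------
    variable_names : list of str
        Ordered covariate names (e.g. ``["v65", "ahac", "acute_gi"]``).
    beta0 : float
        Intercept of the linear predictor.
    betas : array-like
        Coefficients aligned with ``variable_names``.
    standard_errors, pvalues : array-like, optional
        Per-coefficient Wald standard errors and p-values (no intercept).
    """

    variable_names: list[str]
    beta0: float
    betas: np.ndarray
    standard_errors: np.ndarray | None = None
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variable_names = list(self.variable_names)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.variable_names),):
            raise ValueError("betas must align with variable_names")
        if not np.all(np.isfinite(self.betas)) or not np.isfinite(self.beta0):
            raise ValueError("coefficients must be finite")
        for attr in ("standard_errors", "pvalues"):
            val = getattr(self, attr)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != self.betas.shape:
                    raise ValueError(f"{attr} must align with betas")
                setattr(self, attr, val)

    # -- prediction ---------------------------------------------------------

    def _design(self, x) -> np.ndarray:
        """Covariate matrix (n, p) aligned to ``variable_names``."""
        if isinstance(x, pd.DataFrame):
            missing = [v for v in self.variable_names if v not in x.columns]
            if missing:
                raise KeyError(f"missing covariate(s): {missing}")
            return x[self.variable_names].to_numpy(dtype=float)
        if isinstance(x, (Mapping, pd.Series)):
            missing = [v for v in self.variable_names if v not in x]
            if missing:
                raise KeyError(f"missing covariate(s): {missing}")
            return np.array([[float(x[v]) for v in self.variable_names]])
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[1] != len(self.variable_names):
            raise ValueError(
                f"expected {len(self.variable_names)} covariates, got {arr.shape[1]}"
            )
        return arr

    def linear_predictor(self, x):
        """g(x) = beta0 + sum_i beta_i x_i for one or many covariate vectors."""
        g = self.beta0 + self._design(x) @ self.betas
        return float(g[0]) if g.size == 1 else g

    def ntcp(self, x):
        """Complication probability exp(g)/(1+exp(g)); overflow-safe."""
        g = self.beta0 + self._design(x) @ self.betas
        p = expit(g)
        return float(p[0]) if p.size == 1 else p

    def odds_ratios(self) -> dict[str, float]:
        """Odds ratio exp(beta_i) per covariate."""
        return {v: float(np.exp(b)) for v, b in zip(self.variable_names, self.betas)}

    # -- serialisation ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "variable_names": self.variable_names,
            "beta0": self.beta0,
            "betas": self.betas.tolist(),
            "standard_errors": None
            if self.standard_errors is None
            else self.standard_errors.tolist(),
            "pvalues": None if self.pvalues is None else self.pvalues.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "LogisticNTCPModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            variable_names=payload["variable_names"],
            beta0=payload["beta0"],
            betas=np.asarray(payload["betas"], dtype=float),
            standard_errors=None
            if payload.get("standard_errors") is None
            else np.asarray(payload["standard_errors"], dtype=float),
            pvalues=None
            if payload.get("pvalues") is None
            else np.asarray(payload["pvalues"], dtype=float),
        )


class LogisticNTCP:
    """Maximum-likelihood logistic NTCP model builder.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Binary toxicity outcome, one per patient.
    exog : array-like, shape (n, p)
        Covariate matrix *without* intercept column (added internally).
    var_names : sequence of str, optional
        Covariate names; defaults to ``x1..xp``.

    Examples
    --------
    >>> model = LogisticNTCP.from_dataframe(cohort, outcome="late_gi",
    ...                                     variables=["v65", "ahac", "acute_gi"])
    >>> res = model.fit()
    >>> res.params, res.bse, res.odds_ratios()
    """

    def __init__(self, endog, exog=None, var_names: Sequence[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        if exog is None:
            exog = np.empty((self.endog.size, 0))
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog lengths differ")
        p = self.exog.shape[1]
        self.var_names = list(var_names) if var_names is not None else [f"x{i+1}" for i in range(p)]
        if len(self.var_names) != p:
            raise ValueError("var_names must match number of covariates")
        self._validate()

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str = "late_gi", variables: Sequence[str] | None = None
    ) -> "LogisticNTCP":
        """Build the model from a cohort table (one row per patient)."""
        if outcome not in data.columns:
            raise KeyError(f"outcome column {outcome!r} not in data")
        variables = list(variables) if variables is not None else []
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise KeyError(f"missing covariate(s): {missing}")
        return cls(
            data[outcome].to_numpy(dtype=float),
            data[variables].to_numpy(dtype=float) if variables else None,
            var_names=variables,
        )

    def _validate(self) -> None:
        y = self.endog
        if y.size < 10:
            raise ValueError(f"need at least 10 records, got {y.size}")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("outcome must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome has a single class; cannot fit")
        X = np.column_stack([np.ones(y.size), self.exog])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("design matrix is singular (collinear covariates)")
        # cheap exact-separation pre-check on binary covariates
        for j, name in enumerate(self.var_names):
            col = self.exog[:, j]
            if np.all(np.isin(col, (0.0, 1.0))) and (
                np.array_equal(col, y) or np.array_equal(col, 1.0 - y)
            ):
                raise PerfectSeparationError(
                    f"covariate {name!r} perfectly separates the outcome"
                )

    def loglike(self, params: np.ndarray) -> float:
        X = np.column_stack([np.ones(self.endog.size), self.exog])
        eta = X @ params
        # log L = sum y*eta - log(1+e^eta), written overflow-safe
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def fit(self, maxiter: int = 100, score_tol: float = 1e-8) -> "LogisticNTCPResults":
        """Newton-Raphson ML fit; converged when max |score| < ``score_tol``.

        The log-likelihood is kept non-decreasing by step halving.  Diverging
        coefficients (|beta| > 40) raise :class:`PerfectSeparationError`.
        """
        y = self.endog
        X = np.column_stack([np.ones(y.size), self.exog])
        beta = np.zeros(X.shape[1])
        llf = self.loglike(beta)
        converged = False
        for _ in range(maxiter):
            mu = expit(X @ beta)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < score_tol:
                converged = True
                break
            w = mu * (1.0 - mu)
            hess = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(hess, score)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError("singular information matrix") from exc
            # step halving keeps the log-likelihood monotone
            for _ in range(30):
                candidate = beta + step
                new_llf = self.loglike(candidate)
                if new_llf >= llf - 1e-12:
                    break
                step = 0.5 * step
            beta, llf = candidate, new_llf
            if np.max(np.abs(beta)) > 40.0:
                worst = self.var_names[int(np.argmax(np.abs(beta[1:])))] if beta.size > 1 else "intercept"
                raise PerfectSeparationError(
                    f"coefficients diverging; covariate {worst!r} appears to separate the outcome"
                )
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        hess = (X * w[:, None]).T @ X
        cov = np.linalg.inv(hess)
        return LogisticNTCPResults(self, beta, cov, llf, converged)


class LogisticNTCPResults:
    """Fitted logistic NTCP model.

    Attributes
    ----------
    params : pandas.Series
        ML estimates indexed by ``const`` then the covariate names.
    bse : pandas.Series
        Wald standard errors (inverse observed information).
    pvalues : pandas.Series
        Two-sided Wald p-values.
    llf : float
        Maximised log-likelihood.
    converged : bool
    """

    def __init__(self, model: LogisticNTCP, params, cov_params, llf, converged):
        self.model = model
        index = ["const"] + model.var_names
        self.params = pd.Series(params, index=index)
        self.cov_params = pd.DataFrame(cov_params, index=index, columns=index)
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)), index=index)
        self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * norm.sf(np.abs(self.zvalues.to_numpy())), index=index
        )
        self.llf = float(llf)
        self.converged = bool(converged)
        self.nobs = model.endog.size

    @property
    def model_spec(self) -> LogisticNTCPModel:
        """Portable coefficient set for prediction/serialisation."""
        return LogisticNTCPModel(
            variable_names=self.model.var_names,
            beta0=float(self.params.iloc[0]),
            betas=self.params.iloc[1:].to_numpy(),
            standard_errors=self.bse.iloc[1:].to_numpy(),
            pvalues=self.pvalues.iloc[1:].to_numpy(),
        )

    def predict(self, x=None):
        """NTCP for new covariate vectors (default: the fitting cohort)."""
        if x is None:
            eta = self.params.iloc[0] + self.model.exog @ self.params.iloc[1:].to_numpy()
            return expit(eta)
        return self.model_spec.ntcp(x)

    def odds_ratios(self) -> dict[str, float]:
        return self.model_spec.odds_ratios()

    def summary(self) -> str:
        lines = [
            "Logistic NTCP model (maximum likelihood)",
            f"n = {self.nobs}, events = {int(self.model.endog.sum())}, "
            f"log-likelihood = {self.llf:.4f}, converged = {self.converged}",
            "p-values are two-sided Wald tests.",
            f"{'parameter':<18}{'coef':>10}{'SE':>10}{'p':>10}{'OR':>8}",
        ]
        ors = {"const": None, **self.odds_ratios()}
        for name in self.params.index:
            or_txt = f"{ors[name]:8.2f}" if ors.get(name) is not None else " " * 8
            lines.append(
                f"{name:<18}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}"
                f"{self.pvalues[name]:>10.3f}{or_txt}"
            )
        return "\n".join(lines)
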