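"""Variable screening and bootstrap model-order/variable selection.

The workflow mirrors data-driven NTCP model building: (1) univariate
screening of every candidate covariate by Spearman rank correlation with the
late-toxicity outcome; (2) pruning of highly inter-correlated covariates
(pairwise |Spearman| > 0.75 keeps the member with the stronger outcome
correlation, guarding against overfitting with collinear dose-volume
metrics); (3) bootstrap model selection: on each of ``n_boot`` resamples
drawn with replacement, every k-subset of the pruned pool (k = 1..max_order)
is fitted by logistic regression and the subset maximising the Spearman Rs
between predicted NTCP and the resample outcome is recorded.  Variable sets
are ranked by how often they win, and the model order is chosen where the
mean bootstrap Rs stops improving (plateau heuristic).

For speed, all subsets of one order are fitted simultaneously by a batched
Newton solver; it is numerically equivalent to the public single-model fit
(cross-checked in the test suite).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateResult",
    "SelectionReport",
    "spearman_screen",
    "spearman_matrix",
    "prune_correlated",
    "bootstrap_select",
]


@dataclass
class UnivariateResult:
    """Spearman correlation of one covariate with the outcome."""

    variable: str
    rs: float
    pvalue: float
    degenerate: bool = False


@dataclass
class SelectionReport:
    """Outcome of bootstrap model selection.

    ``model_frequencies[k]`` lists, for model order k, tuples of
    ``(variable_set, count, mean_rs)`` sorted by count (ties: higher mean
    Rs, then lexicographic names); counts over valid bootstraps sum to
    ``n_valid[k]``.  ``order_mean_rs[k]`` is the mean best-subset Rs at
    order k across bootstraps; ``order_frequencies[k]`` the fraction of
    bootstraps whose per-resample plateau rule prefers order k.
    """

    candidate_pool: list[str]
    n_bootstraps: int
    n_valid: dict[int, int]
    order_mean_rs: dict[int, float]
    order_frequencies: dict[int, float]
    model_frequencies: dict[int, list[tuple[tuple[str, ...], int, float]]]
    chosen_order: int
    chosen_model: tuple[str, ...]
    evaluation: str = "in-sample"

    def top_models(self, order: int | None = None, k: int = 5):
        order = self.chosen_order if order is None else order
        return self.model_frequencies[order][:k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for order, entries in sorted(self.model_frequencies.items()):
            for subset, count, mean_rs in entries:
                rows.append(
                    {
                        "order": order,
                        "variable_set": "+".join(subset),
                        "frequency": count,
                        "mean_rs": mean_rs,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Bootstrap model selection "
            f"({self.n_bootstraps} resamples, {self.evaluation} Rs)",
            f"candidate pool ({len(self.candidate_pool)}): {', '.join(self.candidate_pool)}",
            "mean best-subset Rs by order: "
            + ", ".join(f"{k}: {v:.3f}" for k, v in sorted(self.order_mean_rs.items())),
            f"chosen order: {self.chosen_order}",
            f"chosen model: {' + '.join(self.chosen_model)}",
            "top models at chosen order:",
        ]
        for subset, count, mean_rs in self.top_models():
            lines.append(f"  {'+'.join(subset):<40} {count:>5}  mean Rs {mean_rs:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# univariate screening and pruning
# ---------------------------------------------------------------------------

def spearman_screen(
    data: pd.DataFrame, variables, outcome: str = "late_gi"
) -> list[UnivariateResult]:
    """Spearman rank correlation of each covariate with the binary outcome.

    Average ranks are used for ties; the p-value comes from the usual
    t-distribution approximation.  A constant covariate has undefined rank
    correlation and is reported as rs = 0 with ``degenerate=True``.
    """
    y = data[outcome].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 records")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    results = []
    for var in variables:
        x = data[var].to_numpy(dtype=float)
        if x.min() == x.max() or y.min() == y.max():
            results.append(UnivariateResult(var, 0.0, 1.0, degenerate=True))
            continue
        res = stats.spearmanr(x, y)
        results.append(UnivariateResult(var, float(res.statistic), float(res.pvalue)))
    return results


def spearman_matrix(data: pd.DataFrame, variables) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix of the candidate covariates."""
    variables = list(variables)
    return data[variables].astype(float).corr(method="spearman")


def prune_correlated(
    data: pd.DataFrame,
    variables,
    screen: list[UnivariateResult],
    threshold: float = 0.75,
) -> list[str]:
    """Drop the weaker member of every covariate pair with |rho| > threshold.

    Covariates are visited in decreasing |rs| with the outcome (ties broken
    by name, so the result is independent of the input ordering); each is
    kept only if its pairwise |Spearman| with every already-kept covariate
    is <= ``threshold``.  Of three mutually correlated covariates exactly
    the max-|rs| one survives.
    """
    variables = list(variables)
    rs_by_var = {r.variable: abs(r.rs) for r in screen}
    missing = [v for v in variables if v not in rs_by_var]
    if missing:
        raise ValueError(f"screen does not cover variable(s): {missing}")
    corr = spearman_matrix(data, variables).to_numpy()
    np.nan_to_num(corr, copy=False)  # constant columns -> 0 correlation
    order = sorted(range(len(variables)), key=lambda i: (-rs_by_var[variables[i]], variables[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(corr[i, j]) <= threshold for j in kept):
            kept.append(i)
        else:
            logger.info("pruning %s (correlated with a stronger covariate)", variables[i])
    return [variables[i] for i in kept]


# ---------------------------------------------------------------------------
# batched logistic machinery (internal)
# ---------------------------------------------------------------------------

def _fit_subsets(X: np.ndarray, y: np.ndarray, subsets: np.ndarray,
                 maxiter: int = 25, tol: float = 1e-6):
    """Newton-fit logistic models for many column subsets at once.

    Parameters
    ----------
    X : (n, p) covariate matrix (no intercept).
    y : (n,) binary outcome.
    subsets : (S, k) integer column indices.

    Returns
    -------
    eta : (S, n) linear predictors of each fitted subset model.
    beta : (S, k+1) coefficients (intercept first); zeroed where invalid.
    ok : (S,) bool, False where the fit diverged (separation) or went
        numerically singular.
    """
    n = X.shape[0]
    S, k = subsets.shape
    # design tensor (S, n, k+1) with intercept column
    Xs = np.empty((S, n, k + 1))
    Xs[:, :, 0] = 1.0
    Xs[:, :, 1:] = X[:, subsets].transpose(1, 0, 2)
    beta = np.zeros((S, k + 1))
    eye = np.eye(k + 1)
    ok = np.ones(S, dtype=bool)
    Xt = np.ascontiguousarray(Xs.transpose(0, 2, 1))
    for _ in range(maxiter):
        eta = (Xs @ beta[:, :, None])[:, :, 0]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = (Xt @ (y - mu)[:, :, None])[:, :, 0]
        hess = Xt @ (Xs * w[:, :, None]) + 1e-8 * eye
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            ok[:] = False
            break
        beta += step
        diverged = np.abs(beta).max(axis=1) > 40.0
        if diverged.any():
            ok &= ~diverged
            beta[diverged] = 0.0  # freeze; flagged invalid
        if np.abs(step[ok]).max(initial=0.0) < tol:
            break
    eta = (Xs @ beta[:, :, None])[:, :, 0]
    return eta, beta, ok


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (vectorised)."""
    return stats.rankdata(a, axis=-1, method="average")


def _spearman_rows(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman Rs of each row of ``eta`` against ``y`` (may contain NaN -> 0)."""
    ry = stats.rankdata(y)
    ry = ry - ry.mean()
    re = _rank_rows(eta)
    re = re - re.mean(axis=1, keepdims=True)
    denom = np.sqrt((re**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (re @ ry) / denom
    return np.where(np.isfinite(rs), rs, 0.0)


# ---------------------------------------------------------------------------
# bootstrap selection
# ---------------------------------------------------------------------------

def bootstrap_select(
    data: pd.DataFrame,
    pool,
    outcome: str = "late_gi",
    n_boot: int = 500,
    max_order: int = 3,
    seed: int | None = 0,
    oob: bool = False,
    plateau_tol: float = 0.01,
) -> SelectionReport:
    """Bootstrap model-order and variable selection over a pruned pool.

    For each of ``n_boot`` resamples (n patients drawn with replacement) and
    each order k <= ``max_order``, every k-subset of ``pool`` is fitted by
    logistic regression; the subset with the highest Spearman Rs between
    predicted NTCP and outcome on the resample (or on the out-of-bag
    patients when ``oob=True``) wins that resample.  The same resamples are
    reused across orders.  The chosen order is the smallest k whose mean Rs
    gain at k+1 falls below ``plateau_tol`` (defaulting to the Rs-maximising
    order when the gain never saturates); the chosen model is the most
    frequent subset at that order.

    Randomness derives entirely from ``seed`` through per-bootstrap
    substreams, so reports are bit-stable across runs and under any
    parallel split of the resamples.
    """
    pool = list(pool)
    if max_order < 1 or max_order > len(pool):
        raise ValueError(f"max_order must be in [1, {len(pool)}]")
    y = data[outcome].to_numpy(dtype=float)
    X = data[pool].to_numpy(dtype=float)
    n = y.size
    subsets_by_order = {
        k: np.array(list(itertools.combinations(range(len(pool)), k)), dtype=np.intp)
        for k in range(1, max_order + 1)
    }
    streams = np.random.SeedSequence(seed).spawn(n_boot)

    win_counts = {k: np.zeros(len(subsets_by_order[k]), dtype=np.int64) for k in subsets_by_order}
    rs_sums = {k: np.zeros(len(subsets_by_order[k])) for k in subsets_by_order}
    n_valid = {k: 0 for k in subsets_by_order}
    best_rs_rows: list[dict[int, float]] = []

    for b in range(n_boot):
        rng = np.random.default_rng(streams[b])
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            logger.info("bootstrap %d: single-class resample skipped", b)
            continue
        Xb = X[idx]
        if oob:
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            if mask.sum() == 0 or y[mask].min() == y[mask].max():
                logger.info("bootstrap %d: unusable out-of-bag set skipped", b)
                continue
            X_eval, y_eval = X[mask], y[mask]
        best_per_order: dict[int, float] = {}
        for k, subsets in subsets_by_order.items():
            eta, beta, ok = _fit_subsets(Xb, yb, subsets)
            if not ok.all():
                logger.info(
                    "bootstrap %d order %d: %d non-convergent subset(s) skipped",
                    b, k, int((~ok).sum()),
                )
            if oob:
                # score the fitted coefficients on out-of-bag patients
                Es = np.empty((len(subsets), X_eval.shape[0], k + 1))
                Es[:, :, 0] = 1.0
                Es[:, :, 1:] = X_eval[:, subsets].transpose(1, 0, 2)
                eta_eval = np.einsum("snp,sp->sn", Es, beta)
                rs = _spearman_rows(eta_eval, y_eval)
            else:
                rs = _spearman_rows(eta, yb)
            rs = np.where(ok, rs, -np.inf)
            if not np.isfinite(rs).any():
                continue
            winner = int(np.argmax(rs))
            win_counts[k][winner] += 1
            finite = np.isfinite(rs)
            rs_sums[k][finite] += rs[finite]
            n_valid[k] += 1
            best_per_order[k] = float(rs[winner])
        if best_per_order:
            best_rs_rows.append(best_per_order)

    order_mean_rs = {
        k: float(np.mean([row[k] for row in best_rs_rows if k in row])) if n_valid[k] else 0.0
        for k in subsets_by_order
    }
    order_frequencies = _order_preferences(best_rs_rows, max_order, plateau_tol)
    chosen_order = _plateau_order(order_mean_rs, max_order, plateau_tol)

    model_frequencies: dict[int, list[tuple[tuple[str, ...], int, float]]] = {}
    for k, subsets in subsets_by_order.items():
        entries = []
        for s_idx, subset in enumerate(subsets):
            count = int(win_counts[k][s_idx])
            mean_rs = float(rs_sums[k][s_idx] / n_valid[k]) if n_valid[k] else 0.0
            names = tuple(pool[j] for j in subset)
            entries.append((names, count, mean_rs))
        entries.sort(key=lambda e: (-e[1], -e[2], e[0]))
        model_frequencies[k] = entries

    chosen_model = model_frequencies[chosen_order][0][0]
    return SelectionReport(
        candidate_pool=pool,
        n_bootstraps=n_boot,
        n_valid=n_valid,
        order_mean_rs=order_mean_rs,
        order_frequencies=order_frequencies,
        model_frequencies=model_frequencies,
        chosen_order=chosen_order,
        chosen_model=chosen_model,
        evaluation="out-of-bag" if oob else "in-sample",
    )


def _plateau_order(order_mean_rs: dict[int, float], max_order: int, tol: float) -> int:
    """Smallest order whose Rs gain at the next order is below ``tol``."""
    for k in range(1, max_order):
        if order_mean_rs[k + 1] - order_mean_rs[k] < tol:
            return k
    return max(order_mean_rs, key=lambda k: order_mean_rs[k])


def _order_preferences(best_rs_rows, max_order: int, tol: float) -> dict[int, float]:
    counts = {k: 0 for k in range(1, max_order + 1)}
    for row in best_rs_rows:
        if len(row) < max_order:
            continue
        counts[_plateau_order(row, max_order, tol)] += 1
    total = sum(counts.values())
    return {k: (c / total if total else 0.0) for k, c in counts.items()}
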