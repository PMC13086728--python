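"""Coded-variable response-surface regression and DoE diagnostics.

Models are ordinary least squares fits on the coded design matrix at one of
three polynomial orders:

* ``linear``    — intercept + main effects
* ``2FI``       — linear + all two-factor interactions
* ``quadratic`` — 2FI + pure quadratic terms

Diagnostics follow the conventions of DoE software: R-squared statistics use
the corrected (mean-centred) total sum of squares; predicted R-squared is
PRESS-based, PRESS = sum((e_i / (1 - h_ii))^2) over the leverages h_ii; and
adequate precision is the signal-to-noise ratio
(max fitted - min fitted) / sqrt(p * MSE / n).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .design import DesignTable

__all__ = [
    "ORDERS",
    "FitStats",
    "FittedModel",
    "model_terms",
    "term_matrix",
    "fit_model",
    "predict",
    "press_and_pred_r2",
    "adequate_precision",
    "select_model",
]

logger = logging.getLogger(__name__)

ORDERS = ("linear", "2FI", "quadratic")

INTERCEPT = "Intercept"


def model_terms(factor_names: list[str], order: str) -> list[str]:
    """Term names for a polynomial of the given order in the given factors."""
    if order not in ORDERS:
        raise ValueError(f"unknown model order {order!r}; expected one of {ORDERS}")
    terms = [INTERCEPT, *factor_names]
    if order in ("2FI", "quadratic"):
        terms += [f"{a}:{b}" for a, b in itertools.combinations(factor_names, 2)]
    if order == "quadratic":
        terms += [f"{name}^2" for name in factor_names]
    return terms


def _eval_term(term: str, coded: np.ndarray, factor_names: list[str]) -> np.ndarray:
    idx = {name: i for i, name in enumerate(factor_names)}
    if term == INTERCEPT:
        return np.ones(coded.shape[0])
    if term.endswith("^2"):
        return coded[:, idx[term[:-2]]] ** 2
    if ":" in term:
        a, b = term.split(":")
        return coded[:, idx[a]] * coded[:, idx[b]]
    return coded[:, idx[term]]


def term_matrix(coded: np.ndarray, factor_names: list[str], order: str) -> tuple[np.ndarray, list[str]]:
    """Build the coded model matrix (n runs x p terms) for an order."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    terms = model_terms(factor_names, order)
    X = np.column_stack([_eval_term(t, coded, factor_names) for t in terms])
    return X, terms


@dataclass
class FitStats:
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adequate_precision: float
    mse: float
    term_p_values: dict[str, float]


@dataclass
class FittedModel:
    """An OLS response-surface fit on the coded scale."""

    response_name: str
    order: str
    factor_names: list[str]
    coefficients: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    stats: FitStats
    n: int
    p: int

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def coef(self, term: str) -> float:
        return self.coefficients[term]


def fit_model(table: DesignTable, response: str, order: str = "quadratic") -> FittedModel:
    """Least-squares polynomial fit of a response on the coded design.

    Coefficients are reported on the coded (-1..+1) scale, so on a balanced
    Box-Behnken design each main effect is half the predicted change across
    the factor's full range and the intercept of a main-effects model equals
    the response grand mean.
    """
    y = table.response(response)
    if np.any(~np.isfinite(y)):
        bad = [table.run_ids[i] for i in np.where(~np.isfinite(y))[0]]
        raise ValueError(f"response {response!r} has missing/non-finite cells at runs {bad}")

    X, terms = term_matrix(table.coded.to_numpy(), table.factor_names, order)
    n, p = X.shape
    if n < p:
        raise ValueError(f"{order} model has {p} terms but only {n} runs")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns by checking rank drop per term
        collinear = [
            terms[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design for {order} model; collinear terms: {collinear}")

    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    resid = np.asarray(res.resid)
    hat = np.asarray(res.get_influence().hat_matrix_diag)

    df_resid = n - p
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    mse = sse / df_resid if df_resid > 0 else np.nan
    if df_resid > 0 and sst > 0:
        adj_r2 = 1.0 - (sse / df_resid) / (sst / (n - 1))
    else:
        adj_r2 = np.nan
    r2 = 1.0 - sse / sst if sst > 0 else 1.0

    press, pred_r2 = _press(resid, hat, sst) if df_resid > 0 else (np.nan, np.nan)
    adq = _adequate_precision(fitted, mse, n, p) if df_resid > 0 and mse > 0 else np.nan

    pvals = dict(zip(terms, np.asarray(res.pvalues, dtype=float)))
    stats = FitStats(
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        adequate_precision=adq,
        mse=mse,
        term_p_values=pvals,
    )
    return FittedModel(
        response_name=response,
        order=order,
        factor_names=list(table.factor_names),
        coefficients=dict(zip(terms, np.asarray(res.params, dtype=float))),
        fitted=fitted,
        residuals=resid,
        leverage=hat,
        stats=stats,
        n=n,
        p=p,
    )


def predict(model: FittedModel, coded_point) -> float | np.ndarray:
    """Evaluate the fitted polynomial at coded point(s)."""
    pts = np.atleast_2d(np.asarray(coded_point, dtype=float))
    k = len(model.factor_names)
    if pts.shape[1] != k:
        raise ValueError(f"expected {k} coded coordinates, got {pts.shape[1]}")
    if np.any(np.abs(pts) > 1 + 1e-12):
        warnings.warn(
            "prediction outside the coded [-1, +1] cube is an extrapolation",
            stacklevel=2,
        )
    X, terms = term_matrix(pts, model.factor_names, model.order)
    beta = np.array([model.coefficients[t] for t in terms])
    out = X @ beta
    return float(out[0]) if np.asarray(coded_point).ndim == 1 else out


def _press(resid: np.ndarray, hat: np.ndarray, sst: float) -> tuple[float, float]:
    if np.any(hat >= 1 - 1e-12):
        raise ValueError("a run has leverage 1 (exact-fit point); PRESS undefined")
    press = float(np.sum((resid / (1.0 - hat)) ** 2))
    pred_r2 = 1.0 - press / sst if sst > 0 else np.nan
    return press, pred_r2


def press_and_pred_r2(model: FittedModel) -> tuple[float, float]:
    """PRESS (leave-one-out prediction error SS) and predicted R-squared.

    PRESS = sum((e_i / (1 - h_ii))^2), algebraically identical to refitting
    without each run in turn; predicted R^2 = 1 - PRESS / SST(corrected).
    """
    if model.n - model.p <= 0:
        raise ValueError("no residual degrees of freedom")
    y = model.fitted + model.residuals
    sst = float(np.sum((y - y.mean()) ** 2))
    return _press(model.residuals, model.leverage, sst)


def _adequate_precision(fitted: np.ndarray, mse: float, n: int, p: int) -> float:
    return float((fitted.max() - fitted.min()) / np.sqrt(p * mse / n))


def adequate_precision(model: FittedModel) -> float:
    """Signal-to-noise ratio (max fitted - min fitted)/sqrt(p*MSE/n); > 4 is adequate."""
    if not model.stats.mse > 0:
        raise ValueError("MSE is zero; adequate precision undefined")
    return _adequate_precision(model.fitted, model.stats.mse, model.n, model.p)


def select_model(table: DesignTable, response: str, alpha: float = 0.05) -> str:
    """Pick the polynomial order by the sequential F-test ladder.

    Each rung's added block of terms (linear -> 2FI -> quadratic) is tested
    against the preceding rung by a partial F-test; the highest rung whose
    block is significant at ``alpha`` wins, ties broken toward the simpler
    model. Candidates without residual degrees of freedom are skipped.
    """
    y = table.response(response)
    results = {}
    for order in ORDERS:
        X, _ = term_matrix(table.coded.to_numpy(), table.factor_names, order)
        if X.shape[0] - X.shape[1] <= 0:
            logger.warning(
                "skipping %s model for %s: no residual degrees of freedom", order, response
            )
            continue
        results[order] = sm.OLS(y, X).fit()

    chosen = "linear"
    previous = "linear"
    for order in ("2FI", "quadratic"):
        if order not in results or previous not in results:
            break
        fstat, pval, _ = results[order].compare_f_test(results[previous])
        if np.isfinite(pval) and pval < alpha:
            chosen = order
        previous = order
    return chosen
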