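"""Diagnostics for the network centrality features.

Three procedures probe whether the eight centrality features carry signal
about binding / immunogenicity: bidirectional AIC-stepwise linear (binding,
response = transformed affinity) and logistic (immunogenic, response =
binary label) regression; two-sample Kolmogorov-Smirnov comparison of a
metric's distribution in positives vs negatives; and a chi-squared test of
association between a quantile-binned metric and the binary category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class RegressionReport:
    """Outcome of a stepwise-selected regression."""

    flavour: str  # "binding" (linear) or "immunogenic" (logistic)
    criterion: str
    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    selected: list[str]
    candidates: list[str]
    trace: list[dict] = field(default_factory=list)
    aic: float = float("nan")

    def to_table(self) -> pd.DataFrame:
        rows = [{"variable": "(intercept)", "coefficient": self.intercept}]
        rows += [
            {"variable": v, "coefficient": self.coefficients[v]} for v in self.selected
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "flavour": self.flavour,
            "criterion": self.criterion,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "selected": self.selected,
            "candidates": self.candidates,
            "aic": self.aic,
        }


def _fit(y, x_df, flavour):
    exog = sm.add_constant(x_df, has_constant="add")
    if flavour == "binding":
        return sm.OLS(y, exog).fit()
    model = sm.Logit(y, exog)
    try:
        res = model.fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise ValueError("non-finite standard errors")
        return res
    except Exception:
        # perfect separation or non-convergence: penalised fallback
        return model.fit_regularized(disp=0, alpha=1e-4, maxiter=500)


def _aic(res, n_params) -> float:
    try:
        aic = float(res.aic)
        if np.isfinite(aic):
            return aic
    except (AttributeError, TypeError):
        pass
    # regularized fits lack .aic; rebuild from llf
    return float(2 * n_params - 2 * res.model.loglike(res.params))


def stepwise_regress(
    features: pd.DataFrame,
    response,
    flavour: str = "binding",
    criterion: str = "aic",
) -> RegressionReport:
    """Bidirectional stepwise selection starting from the full model.

    At each step every single-variable drop and every single-variable add is
    scored by AIC (or BIC); the best improving move is applied until no move
    improves.  Deterministic for a fixed column/row order.  The final model
    is refit to report coefficients, standard errors and p-values.
    """
    if flavour not in ("binding", "immunogenic"):
        raise ValueError(f"unknown flavour {flavour!r}")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    y = np.asarray(response, dtype=float)
    candidates = list(features.columns)
    n = len(y)
    if candidates and n < 10:
        raise ValueError("too few observations for stepwise selection")

    def score(cols):
        if not cols:
            res = _fit(y, pd.DataFrame(index=features.index), flavour)
        else:
            res = _fit(y, features[cols], flavour)
        k = len(cols) + 1
        if criterion == "aic":
            return _aic(res, k), res
        llf = float(res.model.loglike(res.params)) if not hasattr(res, "llf") else float(res.llf)
        return k * np.log(n) - 2 * llf, res

    if np.ptp(y) == 0.0:
        # constant response: every fit is perfect, AIC degenerates to -inf;
        # the parsimonious answer is the intercept-only model
        return RegressionReport(
            flavour=flavour,
            criterion=criterion,
            intercept=float(y[0]),
            coefficients={},
            std_errors={},
            p_values={},
            selected=[],
            candidates=candidates,
            trace=[{"step": 0, "action": "constant_response", "score": float("-inf"), "k": 0}],
            aic=float("-inf"),
        )

    current = list(candidates)
    best_score, best_res = score(current)
    trace = [{"step": 0, "action": "start_full", "score": best_score, "k": len(current)}]
    improved = True
    step = 0
    while improved:
        improved = False
        moves = []
        for v in current:
            cols = [c for c in current if c != v]
            moves.append(("drop", v, cols))
        for v in candidates:
            if v not in current:
                moves.append(("add", v, current + [v]))
        best_move = None
        for action, v, cols in moves:
            s, res = score(cols)
            if s < best_score - 1e-9:
                if best_move is None or s < best_move[0]:
                    best_move = (s, action, v, cols, res)
        if best_move is not None:
            best_score, action, v, current, best_res = (
                best_move[0],
                best_move[1],
                best_move[2],
                best_move[3],
                best_move[4],
            )
            step += 1
            trace.append({"step": step, "action": f"{action}:{v}", "score": best_score,
                          "k": len(current)})
            improved = True

    # keep the original candidate ordering in the report
    selected = [c for c in candidates if c in current]
    params = best_res.params
    bse = getattr(best_res, "bse", pd.Series(np.nan, index=params.index))
    pvals = getattr(best_res, "pvalues", pd.Series(np.nan, index=params.index))
    return RegressionReport(
        flavour=flavour,
        criterion=criterion,
        intercept=float(params.get("const", 0.0)),
        coefficients={v: float(params[v]) for v in selected},
        std_errors={v: float(bse[v]) for v in selected},
        p_values={v: float(pvals[v]) for v in selected},
        selected=selected,
        candidates=candidates,
        trace=trace,
        aic=best_score if criterion == "aic" else float("nan"),
    )


def all_subsets_selection(
    features: pd.DataFrame, response, flavour: str = "binding"
) -> tuple[list[str], float]:
    """Brute-force AIC minimisation over every subset of the candidate
    variables.  Exponential in the number of columns; meant for <= 10."""
    from itertools import combinations

    y = np.asarray(response, dtype=float)
    cols = list(features.columns)
    best, best_aic = [], np.inf
    for r in range(len(cols) + 1):
        for combo in combinations(cols, r):
            res = _fit(y, features[list(combo)], flavour)
            aic = _aic(res, len(combo) + 1)
            if aic < best_aic - 1e-9:
                best_aic, best = aic, list(combo)
    return best, best_aic


def ks_compare(positives, negatives):
    """Two-sample KS test between a metric's values in the two classes.

    Returns (D statistic, asymptotic p-value).
    """
    a = np.asarray(positives, dtype=float)
    b = np.asarray(negatives, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chisq_metrics(values, categories, n_bins: int = 4):
    """Chi-squared association test between a binned metric and a category.

    The metric is discretised into ``n_bins`` quantile bins; bins with an
    expected count below 1 are merged into their neighbour.  Returns
    (statistic, p-value, contingency table) with no continuity correction.
    """
    values = np.asarray(values, dtype=float)
    categories = np.asarray(categories)
    if len(np.unique(categories)) < 2:
        raise ValueError("both categories must be present")
    bins = pd.qcut(values, q=n_bins, duplicates="drop", labels=False)
    table = pd.crosstab(bins, categories)

    # merge adjacent bins while any expected count < 1
    def expected(t):
        tot = t.to_numpy().sum()
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / tot

    while len(table) > 2 and (expected(table) < 1.0).any():
        sizes = table.sum(axis=1).to_numpy()
        i = int(np.argmin(sizes))
        j = i + 1 if i + 1 < len(table) else i - 1
        merged = table.iloc[i] + table.iloc[j]
        table = table.drop(table.index[[i, j]])
        table.loc[f"merged_{i}"] = merged
        table = table.sort_index()
    stat, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p), table
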