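"""Stepwise refinement of the tree biomass model around stem volume.

Step 1 augments stem volume with wood density,

    ln(TB) = a + b*ln(TV) + c*ln(WD)

and step 2 adds the biomass conversion and expansion factor,

    ln(TB) = a + b*ln(TV) + c*ln(WD) + d*ln(BCEF),

the package's headline tree model.  Both are linear in the parameters on the
log scale, so they are solved exactly by ordinary least squares; criteria are
reported on the natural kg scale like every other fit.  Because
BCEF = BEF * WD, ln(WD) and ln(BCEF) are close to affinely dependent whenever
BEF varies little; a rank-deficiency warning is raised in that case.

Coefficients are always labelled by predictor name (``intercept``,
``ln(TV)``, ``ln(WD)``, ``ln(BCEF)``) rather than by letter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult, _as_columns, _data_hash, compute_criteria, \
    information_criteria
from .metrics import DomainError

__all__ = [
    "CollinearityWarning",
    "loglinear_fit",
    "fit_tv_wd_model",
    "fit_tv_wd_bcef_model",
    "compare_models",
    "TV_WD_TERMS",
    "TV_WD_BCEF_TERMS",
]

TV_WD_TERMS = ("intercept", "ln(TV)", "ln(WD)")
TV_WD_BCEF_TERMS = ("intercept", "ln(TV)", "ln(WD)", "ln(BCEF)")

#: condition-number threshold above which a collinearity warning is raised
_COND_WARN = 1e8


class CollinearityWarning(UserWarning):
    pass


def _require_positive(cols: dict, names: Sequence[str]) -> dict:
    out = {}
    for name in names:
        key = "V" if name == "TV" else name
        if key not in cols:
            raise DomainError(f"data lacks required column {name}")
        arr = np.asarray(cols[key], dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError(f"{name} must be finite and strictly positive")
        out[name] = arr
    return out


def loglinear_fit(data, terms: Sequence[str], model_id: str) -> FitResult:
    """Exact OLS fit of ln(TB) on ln-transformed predictor columns.

    ``terms`` are predictor names without the intercept, e.g. ("TV", "WD").
    The returned :class:`FitResult` carries coefficient standard errors in
    ``criteria['se']`` (same order as the parameters) and natural-scale
    criteria.
    """
    cols = _as_columns(data)
    need = _require_positive(cols, list(terms) + ["TB"])
    tb = need.pop("TB")
    n = tb.size
    p = len(terms) + 1
    if n <= p:
        raise ValueError(f"need more trees ({n}) than parameters ({p})")
    X = np.column_stack([np.ones(n)] + [np.log(need[t]) for t in terms])
    y = np.log(tb)
    cond = np.linalg.cond(X)
    if cond > _COND_WARN:
        warnings.warn(
            f"design matrix nearly rank-deficient (cond={cond:.2e}); "
            "ln-predictors are close to affinely dependent", CollinearityWarning,
            stacklevel=2)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    # coefficient covariance (pseudo-inverse tolerates the collinear case)
    sigma2 = rss / max(n - p, 1)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    pred = np.exp(X @ beta)
    crit = compute_criteria(tb, pred, p)
    crit.update(information_criteria(rss, n, p))
    crit["se"] = se
    names = ("intercept",) + tuple(f"ln({t})" for t in terms)
    return FitResult(model_id=model_id, params=beta, converged=True, criteria=crit,
                     n=n, loss=rss, response_scale="log", param_names=names,
                     data_hash=_data_hash(cols), predictions=pred)


def fit_tv_wd_model(data) -> FitResult:
    """Step 1: ln(TB) = a + b*ln(TV) + c*ln(WD)."""
    return loglinear_fit(data, ("TV", "WD"), model_id="tv_wd")


def fit_tv_wd_bcef_model(data) -> FitResult:
    """Step 2 (headline model): ln(TB) = a + b*ln(TV) + c*ln(WD) + d*ln(BCEF)."""
    return loglinear_fit(data, ("TV", "WD", "BCEF"), model_id="tv_wd_bcef")


def compare_models(results: Sequence[FitResult]) -> pd.DataFrame:
    """Pairwise criterion deltas with a declared winner per criterion.

    All results must come from the same dataset (checked via n and a content
    hash).  Lower is better for MAB/RMSE/AIC/BIC, higher for R2.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least two fit results to compare")
    ref = results[0]
    for r in results[1:]:
        if r.n != ref.n or (r.data_hash is not None and ref.data_hash is not None
                            and r.data_hash != ref.data_hash):
            raise ValueError("fit results come from different datasets")
    crits = ("MAB", "RMSE", "R2", "AIC", "BIC")
    rows = []
    for crit in crits:
        vals = {str(r.model_id): r.criteria[crit] for r in results}
        best = (max if crit == "R2" else min)(vals, key=vals.get)
        row = {"criterion": crit, **vals, "winner": best}
        for a in vals:
            for b in vals:
                if a < b:
                    row[f"delta[{a}-{b}]"] = vals[a] - vals[b]
        rows.append(row)
    return pd.DataFrame(rows)
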