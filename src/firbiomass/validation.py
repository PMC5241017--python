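"""Jackknife (leave-one-out) validation of a fitted model form.

Each of the n trees is held out in turn, the model is refitted on the
remaining n-1 trees and the held-out tree is predicted.  The report carries

* held-out criteria (MAB/RMSE/ARE/R2 over the n out-of-sample predictions),
* the full-data fit and its AIC/BIC,
* the mean of the n leave-one-out coefficient vectors (the "jackknife
  coefficients"), and
* every per-fold estimate,

so both readings of a published jackknife coefficient vector — mean of folds
versus full-data refit — can be checked against it.  Folds that fail to
converge are flagged and excluded from the summaries with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult, MultistartConfig, _as_columns, compute_criteria, \
    fit_model
from .catalogue import ModelSpec, evaluate_model
from .refinement import loglinear_fit

__all__ = ["JackknifeReport", "jackknife", "jackknife_loglinear"]


@dataclass
class JackknifeReport:
    n: int
    heldout_criteria: dict
    full_fit: FitResult
    mean_coefficients: np.ndarray
    fold_coefficients: np.ndarray          # (n_converged, p)
    heldout_predictions: np.ndarray        # (n,), NaN for failed folds
    failed_folds: list = field(default_factory=list)
    param_names: tuple = ()

    def summary(self) -> dict:
        return {
            "n": self.n,
            "heldout": {k: v for k, v in self.heldout_criteria.items()},
            "mean_coefficients": dict(zip(self.param_names,
                                          map(float, self.mean_coefficients))),
            "full_coefficients": dict(zip(self.param_names,
                                          map(float, self.full_fit.params))),
            "full_criteria": {k: (v if np.isscalar(v) else list(map(float, v)))
                              for k, v in self.full_fit.criteria.items()},
            "failed_folds": list(self.failed_folds),
        }


def _subset(cols: dict, mask: np.ndarray) -> dict:
    return {k: np.asarray(v)[mask] for k, v in cols.items()}


def jackknife(fit: Callable[[dict], FitResult],
              predict: Callable[[FitResult, dict], np.ndarray],
              data) -> JackknifeReport:
    """Generic leave-one-out driver over arbitrary fit/predict callables."""
    cols = _as_columns(data)
    tb = np.asarray(cols["TB"], dtype=float)
    n = tb.size
    if n < 3:
        raise ValueError("jackknife needs at least 3 trees")
    full = fit(cols)
    preds = np.full(n, np.nan)
    coefs, failed = [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            res = fit(_subset(cols, mask))
        except Exception:
            res = None
        if res is None or not res.converged:
            failed.append(i)
            continue
        coefs.append(np.asarray(res.params, dtype=float))
        preds[i] = float(np.asarray(predict(res, _subset(cols, ~mask))).ravel()[0])
    if failed:
        warnings.warn(f"{len(failed)} jackknife fold(s) misconverged and were "
                      f"excluded: {failed}")
    ok = np.isfinite(preds)
    heldout = compute_criteria(tb[ok], preds[ok])
    heldout.update({k: full.criteria[k] for k in ("AIC", "BIC")})
    coefs = np.vstack(coefs) if coefs else np.empty((0, len(full.params)))
    return JackknifeReport(
        n=n, heldout_criteria=heldout, full_fit=full,
        mean_coefficients=coefs.mean(axis=0),
        fold_coefficients=coefs, heldout_predictions=preds,
        failed_folds=failed, param_names=tuple(full.param_names),
    )


def jackknife_loglinear(data, terms: Sequence[str] = ("TV", "WD", "BCEF"),
                        model_id: str = "tv_wd_bcef") -> JackknifeReport:
    """Leave-one-out validation of a log-linear refined model form."""
    def fit(cols):
        return loglinear_fit(cols, terms, model_id=model_id)

    def predict(res, cols):
        keys = ["V" if t == "TV" else t for t in terms]
        X = np.column_stack([np.ones(1)] +
                            [np.log(np.asarray(cols[k], dtype=float)) for k in keys])
        return np.exp(X @ res.params)

    return jackknife(fit, predict, data)


def jackknife_spec(spec: ModelSpec, data,
                   multistart: MultistartConfig | None = None,
                   seed: int = 0) -> JackknifeReport:
    """Leave-one-out validation of a catalogued nonlinear model form."""
    def fit(cols):
        return fit_model(spec, cols, multistart=multistart, seed=seed)

    def predict(res, cols):
        return evaluate_model(spec, res.params, cols)

    return jackknife(fit, predict, data)
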