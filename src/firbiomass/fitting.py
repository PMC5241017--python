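"""Model fitting and evaluation criteria.

Any catalogued form (or a user-supplied :class:`~firbiomass.catalogue.ModelSpec`)
is fitted to a tree table by multi-start nonlinear least squares.  The loss is
the residual sum of squares on the model's own response scale — ln(B) for
log-response forms, B (kg) for natural forms — while every evaluation
criterion is computed on the natural kg scale after back-transformation:

    MAB  = sum |B_i - Bhat_i| / n                       (mean absolute bias, kg)
    RMSE = sqrt( sum (B_i - Bhat_i)^2 / (n - 1) )       (kg)
    ARE  = 100 * sum |(B_i - Bhat_i) / B_i| / n         (%)
    R2   = 1 - sum (B_i - Bhat_i)^2 / sum (B_i - Bbar)^2

RMSE deliberately uses the n-1 denominator and R2 the plain (unadjusted)
form to stay comparable with the published reference table; an adjusted R2
is available from :func:`adjusted_r2`.  AIC/BIC come from the Gaussian
log-likelihood kernel on the fitted response scale,

    AIC = n * ln(RSS) + 2p,      BIC = n * ln(RSS) + p * ln(n),

which reproduces the magnitude (including the sign) of the reference
analysis' printed values for log-scale fits; alternative conventions differ
only by additive constants within a fixed dataset and response scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .catalogue import (ModelSpec, PredictorMissingError, all_models,
                        evaluate_model)
from .metrics import DomainError

__all__ = [
    "FitResult",
    "compute_criteria",
    "information_criteria",
    "adjusted_r2",
    "MultistartConfig",
    "fit_model",
    "fit_all",
    "evaluate_fixed",
]

log = logging.getLogger(__name__)


def compute_criteria(observed, predicted, n_params: int = 0) -> dict:
    """MAB, RMSE, ARE (%) and R2 comparing observed and predicted biomass (kg)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError(f"observed {obs.shape} and predicted {pred.shape} must be "
                         "1-d vectors of equal length")
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = obs - pred
    out = {
        "MAB": float(np.sum(np.abs(resid)) / n),
        "RMSE": float(math.sqrt(np.sum(resid ** 2) / (n - 1))),
        "R2": float(1.0 - np.sum(resid ** 2) / np.sum((obs - obs.mean()) ** 2)),
    }
    if np.any(obs <= 0):
        raise DomainError("ARE divides by observed biomass; observations must be > 0")
    out["ARE"] = float(np.sum(np.abs(resid / obs)) / n * 100.0)
    return out


def information_criteria(rss: float, n: int, n_params: int) -> dict:
    """AIC and BIC from the response-scale residual sum of squares."""
    if rss <= 0:  # perfect interpolation: likelihood unbounded
        return {"AIC": -math.inf, "BIC": -math.inf}
    return {
        "AIC": n * math.log(rss) + 2 * n_params,
        "BIC": n * math.log(rss) + n_params * math.log(n),
    }


def adjusted_r2(r2: float, n: int, n_params: int) -> float:
    """Degrees-of-freedom adjusted R2 (not the default reporting form)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


@dataclass(frozen=True)
class MultistartConfig:
    """Latin-hypercube multi-start policy for the nonlinear optimizer.

    ``n_starts`` points are drawn once from a seeded Latin hypercube over
    ``param_range`` per parameter; the reference parameter values (when the
    catalogue has them) and a unit vector are appended as extra starts.
    """

    n_starts: int = 32
    param_range: tuple[float, float] = (-5.0, 5.0)
    max_nfev: int = 500
    ftol: float = 1e-12
    xtol: float = 1e-12

    def starts(self, n_params: int, seed: int, extra: Iterable[Sequence[float]] = ()) \
            -> np.ndarray:
        sampler = qmc.LatinHypercube(d=n_params, seed=seed)
        lo, hi = self.param_range
        pts = qmc.scale(sampler.random(self.n_starts), [lo] * n_params, [hi] * n_params)
        rows = [np.ones(n_params)] + [np.asarray(e, dtype=float) for e in extra]
        return np.vstack([pts] + [r[None, :] for r in rows if r.size == n_params])


@dataclass
class FitResult:
    """Outcome of fitting one model form to one dataset."""

    model_id: int | str
    params: Optional[np.ndarray]
    converged: bool
    criteria: Optional[dict]       # MAB, RMSE, ARE, R2, AIC, BIC (absent if misconverged)
    n: int
    start_point: Optional[np.ndarray] = None
    loss: float = math.inf         # RSS on the fitted response scale
    response_scale: str = "natural"
    param_names: tuple = ()
    data_hash: Optional[int] = None
    predictions: Optional[np.ndarray] = None

    def summary(self) -> dict:
        d = {"model_id": self.model_id, "converged": self.converged, "n": self.n}
        if self.converged:
            d.update({name: float(v) for name, v in zip(self.param_names, self.params)})
            d.update(self.criteria)
        return d


def _as_columns(data) -> dict:
    """Normalise a DataFrame / mapping / TreeRecord sequence to column arrays."""
    if isinstance(data, pd.DataFrame):
        return {c: data[c].to_numpy(dtype=float) for c in data.columns
                if pd.api.types.is_numeric_dtype(data[c])}
    if isinstance(data, Mapping):
        return {k: np.asarray(v, dtype=float) for k, v in data.items()}
    # sequence of TreeRecord
    cols: dict[str, list] = {}
    fields = ("D", "H", "WD", "G", "SI", "V", "TB")
    for t in data:
        for f in fields:
            cols.setdefault(f, []).append(getattr(t, f, None))
    return {k: np.asarray([np.nan if v is None else v for v in vals], dtype=float)
            for k, vals in cols.items()
            if any(v is not None for v in vals)}


def _data_hash(cols: dict) -> int:
    keys = sorted(cols)
    arr = np.concatenate([np.asarray(cols[k], dtype=float).ravel() for k in keys])
    return hash((tuple(keys), arr.size, float(np.nansum(arr)), float(np.nansum(arr**2))))


def _response_target(spec: ModelSpec, tb: np.ndarray) -> np.ndarray:
    return np.log(tb) if spec.response_scale == "log" else tb


_PENALTY = 1e8


def fit_model(spec: ModelSpec, data, multistart: MultistartConfig | None = None,
              seed: int = 0) -> FitResult:
    """Fit one model form by multi-start nonlinear least squares.

    The winner is the start with the lowest final RSS (ties broken by the
    smallest parameter L2 norm).  A result with ``converged=False`` — every
    start ending in a non-finite loss or optimizer failure — mirrors the
    reference table's "misconvergence" rows and carries no criteria.
    """
    multistart = multistart or MultistartConfig()
    cols = _as_columns(data)
    if "TB" not in cols or np.asarray(cols["TB"]).size == 0:
        raise ValueError("data must supply total biomass TB")
    tb = np.asarray(cols["TB"], dtype=float)
    n = tb.size
    if n <= spec.n_params:
        raise ValueError(f"need more trees ({n}) than parameters ({spec.n_params})")
    if spec.response_scale == "log" and np.any(tb <= 0):
        raise DomainError("log-response fit requires strictly positive TB")

    missing = [p for p in spec.required_predictors if p not in cols and p != "G"]
    if missing:
        raise PredictorMissingError(
            f"model {spec.id}: predictors {missing} absent from data")
    if "G" in spec.required_predictors and "G" not in cols:
        cols = dict(cols)
        cols["G"] = np.pi * (cols["D"] / 200.0) ** 2

    target = _response_target(spec, tb)

    def residuals(p):
        with np.errstate(all="ignore"):
            r = target - spec.response(p, cols)
        return np.where(np.isfinite(r), r, _PENALTY)

    extra = [spec.reference_params] if spec.reference_params else []
    starts = multistart.starts(spec.n_params, seed, extra=extra)

    best = None
    for x0 in starts:
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(residuals, x0, method="trf",
                                    max_nfev=multistart.max_nfev,
                                    ftol=multistart.ftol, xtol=multistart.xtol)
        except Exception:   # singular steps, overflow in the model form
            continue
        rss = float(np.sum(sol.fun ** 2))
        if not np.isfinite(rss) or np.any(np.abs(sol.fun) >= _PENALTY):
            continue
        key = (rss, float(np.linalg.norm(sol.x)))
        if best is None or key < (best[0], float(np.linalg.norm(best[1]))):
            best = (rss, sol.x, x0)

    if best is None:
        return FitResult(model_id=spec.id, params=None, converged=False,
                         criteria=None, n=n, response_scale=spec.response_scale,
                         param_names=spec.param_names, data_hash=_data_hash(cols))

    rss, params, x0 = best
    # final polish from the winning start with a higher-accuracy jacobian
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = least_squares(residuals, params, method="trf", jac="3-point",
                                max_nfev=multistart.max_nfev,
                                ftol=1e-15, xtol=1e-15, gtol=1e-14)
        polished = float(np.sum(sol.fun ** 2))
        if np.isfinite(polished) and polished <= rss:
            rss, params = polished, sol.x
    except Exception:
        pass
    pred = evaluate_model(spec, params, cols)
    crit = compute_criteria(tb, pred, spec.n_params)
    crit.update(information_criteria(rss, n, spec.n_params))
    return FitResult(model_id=spec.id, params=np.asarray(params), converged=True,
                     criteria=crit, n=n, start_point=np.asarray(x0), loss=rss,
                     response_scale=spec.response_scale,
                     param_names=spec.param_names, data_hash=_data_hash(cols),
                     predictions=np.asarray(pred, dtype=float))


def fit_all(data, models: Sequence[ModelSpec] | None = None,
            multistart: MultistartConfig | None = None, seed: int = 0,
            rank_by: str = "MAB") -> list[FitResult]:
    """Fit every applicable catalogued form and rank the results.

    Models whose predictors are unavailable (typically the site-index form
    when SI is absent) are skipped with a logged reason.  The ranking is by
    ``rank_by`` ascending (``R2`` descending); results that failed to
    converge sort last.
    """
    cols = _as_columns(data)
    if not cols or np.asarray(next(iter(cols.values()))).size == 0:
        raise ValueError("empty dataset")
    models = list(models) if models is not None else all_models()
    results: list[FitResult] = []
    for i, spec in enumerate(models):
        try:
            results.append(fit_model(spec, cols, multistart=multistart,
                                     seed=seed + spec.id))
        except PredictorMissingError as exc:
            log.warning("skipping model %s: %s", spec.id, exc)
    sign = -1.0 if rank_by.upper() == "R2" else 1.0

    def key(r: FitResult):
        if not r.converged:
            return (1, math.inf, r.model_id)
        return (0, sign * r.criteria[rank_by.upper()], r.model_id)

    return sorted(results, key=key)


def evaluate_fixed(spec: ModelSpec, params: Sequence[float], data) -> FitResult:
    """Criteria for a model with externally supplied (not refitted) coefficients.

    Used for benchmarking published fixed-coefficient equations — e.g. the
    Chinese Fir equation B = 0.0618 * (D^2*H)^0.8532 of Zhang et al. (2013) —
    against locally fitted forms on the same trees.
    """
    cols = _as_columns(data)
    tb = np.asarray(cols["TB"], dtype=float)
    pred = np.asarray(evaluate_model(spec, params, cols), dtype=float)
    crit = compute_criteria(tb, pred, len(params))
    resp_target = _response_target(spec, tb)
    with np.errstate(all="ignore"):
        resp_pred = spec.response(np.asarray(params, dtype=float), cols)
    rss = float(np.sum((resp_target - resp_pred) ** 2))
    crit.update(information_criteria(rss, tb.size, len(params)))
    return FitResult(model_id=spec.id, params=np.asarray(params, dtype=float),
                     converged=True, criteria=crit, n=tb.size, loss=rss,
                     response_scale=spec.response_scale,
                     param_names=spec.param_names, data_hash=_data_hash(cols),
                     predictions=pred)
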