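"""Catalogue of 74 published allometric total-biomass model forms.

Each entry predicts whole-tree dry biomass B (kg) from some subset of the
predictors D (diameter at breast height, cm), H (total height, m), WD (wood
density, kg m^-3), G/BA (basal area, m^2), SI (site index) and V (stem
volume, m^3), with up to five free parameters named a..e.  Log-response
forms model ln(B); natural-response forms model B directly.

The numeric side of the catalogue (reference parameter values and the fit
statistics published for a 35-tree Chinese Fir sample, plus an errata note
for every repaired transcription) ships as ``data/model_catalogue.csv``;
the evaluable structural forms live here, keyed by catalogue id.  Forms
65-74 failed to converge in the reference analysis and carry no reference
values, but remain fully fittable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import DomainError, basal_area

__all__ = [
    "ModelSpec",
    "ModelNotFoundError",
    "PredictorMissingError",
    "get_model",
    "all_models",
    "list_models",
    "evaluate_model",
    "catalogue_table",
    "PREDICTORS",
]

PREDICTORS = frozenset({"D", "H", "WD", "G", "SI", "V"})

ln = np.log
pi = math.pi


class ModelNotFoundError(KeyError):
    """Requested catalogue id does not exist."""


class PredictorMissingError(ValueError):
    """A required predictor is absent from the supplied tree data."""


@dataclass(frozen=True)
class ModelSpec:
    """One catalogued model form.

    ``response(params, x)`` returns the modelled response on the model's own
    scale (ln(B) for log forms, B for natural forms); use
    :func:`evaluate_model` for predictions in kg.
    """

    id: int
    formula: str
    response_scale: str                      # 'natural' | 'log'
    param_names: tuple[str, ...]
    required_predictors: frozenset
    response: Callable[[Sequence[float], Mapping[str, np.ndarray]], np.ndarray]
    reference_status: str = "converged"      # per the published reference fit
    reference_params: Optional[tuple[float, ...]] = None
    reference_criteria: Optional[dict] = None
    note: str = ""

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __repr__(self) -> str:  # keep the table readable in logs
        return f"ModelSpec(id={self.id}, {self.formula!r})"


# ---------------------------------------------------------------------------
# structural forms: id -> (required predictors, n_params, response callable)
# Log forms return ln(B); natural forms return B.
# ---------------------------------------------------------------------------

def _forms():
    D = lambda x: x["D"]
    H = lambda x: x["H"]
    return {
        1: ("DHW", 5, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*ln(x["H"])**2
            + p[3]*ln(x["H"])**3 + p[4]*ln(x["WD"])),
        2: ("DH", 5, lambda p, x: np.exp(p[0]) * (x["D"]+1)**p[1] * x["H"]**p[2]
            * np.exp(p[3]*x["D"]) * np.exp(p[4]*x["H"])),
        3: ("DH", 4, lambda p, x: np.exp(p[0]) * (x["D"]+1)**p[1] * x["H"]**p[2]
            * np.exp(p[3]*x["D"])),
        4: ("DH", 5, lambda p, x: p[0] + p[1]*x["D"] + p[2]*x["D"]**2
            + p[3]*x["H"] + p[4]*x["D"]*x["H"]),
        5: ("DHW", 3, lambda p, x: p[0] + p[1]*ln(x["D"]**2*x["H"]) + p[2]*ln(x["WD"])),
        6: ("DW", 3, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*ln(x["WD"])),
        7: ("DHW", 4, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*ln(x["H"])
            + p[3]*ln(x["WD"])),
        8: ("DH", 4, lambda p, x: p[0] + p[1]*x["D"] + p[2]*x["D"]**2
            + p[3]*(x["D"]**3/x["H"])),
        9: ("DH", 4, lambda p, x: p[0] + p[1]*x["D"]**2 + p[2]*x["D"]
            + p[3]*x["D"]*x["H"]),
        10: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"]**2 + p[2]*x["D"]*x["H"]),
        11: ("D", 2, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+10))),
        12: ("DH", 4, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+7)) + p[2]*x["H"]
             + p[3]*ln(x["H"])),
        13: ("DH", 3, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+11)) + p[2]*ln(x["H"])),
        14: ("DH", 2, lambda p, x: np.exp(p[0] + p[1]*ln(x["D"]**2*x["H"]))),
        15: ("DH", 2, lambda p, x: p[0]*(x["D"]**2*x["H"])**p[1]),
        16: ("DH", 3, lambda p, x: p[0]*x["D"]**p[1]*x["H"]**p[2]),
        17: ("D", 2, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+11))),
        18: ("DH", 3, lambda p, x: np.exp(p[0])*(x["D"]+1)**p[1]*x["H"]**p[2]),
        19: ("DHG", 2, lambda p, x: np.exp(p[0] + p[1]*ln(x["D"]**2*x["H"]*x["G"]))),
        20: ("DH", 3, lambda p, x: p[0] + p[1]*x["H"] + p[2]*x["D"]**2),
        21: ("DH", 4, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+13)) + p[2]*x["H"]
             + p[3]*ln(x["H"])),
        22: ("D", 2, lambda p, x: p[0] + p[1]*x["D"]**2),
        23: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"]**2*x["H"] + p[2]*x["D"]**2),
        24: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"] + p[2]*x["D"]**2*x["H"]),
        25: ("D", 3, lambda p, x: p[0] + p[1]*x["D"]**p[2]),
        26: ("DH", 3, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+14)) + p[2]*ln(x["H"])),
        27: ("D", 2, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+13))),
        28: ("D", 3, lambda p, x: p[0] + p[1]*x["D"] + p[2]*x["D"]**2),
        29: ("D", 2, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+14))),
        30: ("DH", 4, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+18)) + p[2]*x["H"]
             + p[3]*ln(x["H"])),
        31: ("D", 2, lambda p, x: p[0]*x["D"]**p[1]),
        32: ("D", 2, lambda p, x: np.exp(p[0] + p[1]*ln(x["D"]))),
        33: ("DH", 3, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*ln(x["H"]*x["D"]**2)),
        34: ("D", 2, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+5))),
        35: ("DH", 4, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*x["H"]
             + p[3]*ln(x["H"]*x["D"]**2)),
        36: ("DH", 3, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*x["H"]),
        37: ("D", 2, lambda p, x: p[0] + p[1]*ln(x["D"])),
        38: ("D", 2, lambda p, x: p[0] + p[1]*ln(pi*x["D"])),
        39: ("DH", 4, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+30)) + p[2]*x["H"]
             + p[3]*ln(x["H"])),
        40: ("D", 2, lambda p, x: p[0] + p[1]*(x["D"]/(x["D"]+18))),
        41: ("DHW", 1, lambda p, x: p[0]*(x["WD"]*x["D"]**2*x["H"])/1000.0),
        42: ("DH", 3, lambda p, x: p[0] + p[1]*x["H"] + p[2]*x["D"]**2*x["H"]),
        43: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"]**2*x["H"] + p[2]*x["H"]**2),
        44: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"] + p[2]*(x["D"]**2*x["H"])**2),
        45: ("H", 3, lambda p, x: p[0] + p[1]*x["H"]**2 + p[2]*x["H"]**3),
        46: ("H", 2, lambda p, x: p[0]*x["H"]**p[1]),
        47: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"] + p[2]*x["H"]**2),
        48: ("V", 2, lambda p, x: p[0]*x["V"] + p[1]),
        49: ("DH", 2, lambda p, x: p[0] + p[1]*x["D"]**2*x["H"]),
        50: ("D", 2, lambda p, x: p[0] + p[1]*x["D"]),
        51: ("DH", 3, lambda p, x: p[0] + p[1]*x["D"] + p[2]*x["H"]),
        52: ("DH", 1, lambda p, x: p[0]*x["H"]*x["D"]**2),
        53: ("DH", 3, lambda p, x: p[0] + p[1]*x["H"] + p[2]*(x["D"]**2*x["H"])**2),
        # literal left-to-right reading: (1/D^2 * H) * D^2 * H == H^2
        54: ("DH", 2, lambda p, x: p[0] + p[1]*(1/x["D"]**2*x["H"])*x["D"]**2*x["H"]),
        55: ("D", 2, lambda p, x: p[0] + p[1]*ln(x["D"])**2),
        56: ("H", 2, lambda p, x: p[0]*np.exp(x["H"]*p[1])),
        57: ("D", 2, lambda p, x: p[0]*np.exp(p[1]*x["D"])),
        58: ("GS", 3, lambda p, x: p[0]*x["G"]**p[1]*x["SI"]**p[2]),
        59: ("H", 2, lambda p, x: ln(p[0]) + p[1]*x["H"]),
        60: ("H", 2, lambda p, x: p[0] + p[1]*x["H"]),
        61: ("D", 2, lambda p, x: p[0] + p[1]*ln(x["D"])),
        62: ("DH", 2, lambda p, x: p[0]*ln(x["H"]*x["D"]**2) + p[1]),
        63: ("DH", 2, lambda p, x: p[0] + p[1]*ln(x["D"]**2*x["H"])),
        64: ("H", 2, lambda p, x: p[0] + p[1]*ln(x["H"])),
        65: ("D", 2, lambda p, x: ln(p[0]) + p[1]*x["D"]),
        66: ("DH", 2, lambda p, x: ln(p[0]) + p[1]*x["D"]**2*x["H"]),
        67: ("DW", 5, lambda p, x: (x["WD"]/p[0])*np.exp(p[1]*ln(x["D"])
             + p[2]*ln(x["D"])**2 + p[3]*ln(x["D"])**3 + p[4])),
        68: ("DW", 3, lambda p, x: (x["WD"]/p[0])*np.exp(p[1]*ln(x["D"]) + p[2])),
        69: ("DHG", 5, lambda p, x: np.exp(p[0] + p[1]*ln(x["D"]) + p[2]*ln(x["D"])**2
             + p[3]*ln(x["H"]) + p[4]*ln(x["G"]))),
        70: ("DH", 4, lambda p, x: p[0]*x["H"]**p[1]*(x["D"]+1)**(p[2]+p[3]*ln(x["D"]))),
        71: ("D", 3, lambda p, x: p[0]*x["D"]**2 + (x["D"]**2 - p[1])*p[2]),
        72: ("DH", 4, lambda p, x: p[0] + p[1]*ln(x["D"]) + p[2]*ln(x["D"]**2)
             + p[3]*ln(x["H"])),
        73: ("D", 4, lambda p, x: np.exp(p[0] + p[1]*ln(x["D"]))
             + np.exp(p[2] + p[3]*ln(x["D"]))),
        74: ("D", 3, lambda p, x: p[0] + (p[1]*(1/x["D"]**2) + p[2]*(1/x["D"]**2))
             *x["D"]**2),
    }


_PRED_CODES = {"D": "D", "H": "H", "W": "WD", "G": "G", "S": "SI", "V": "V"}


def _load_catalogue() -> dict[int, ModelSpec]:
    with resources.files("firbiomass.data").joinpath("model_catalogue.csv").open() as fh:
        table = pd.read_csv(fh)
    forms = _forms()
    specs: dict[int, ModelSpec] = {}
    for row in table.itertuples(index=False):
        mid = int(row.id)
        preds_code, n_params, fn = forms[mid]
        ref_params = tuple(
            float(v) for v in (row.a, row.b, row.c, row.d, row.e)[:n_params]
            if pd.notna(v)
        ) or None
        ref_crit = None
        if pd.notna(row.mab):
            ref_crit = {"MAB": float(row.mab), "RMSE": float(row.rmse),
                        "R2": float(row.r2)}
        specs[mid] = ModelSpec(
            id=mid,
            formula=row.formula,
            response_scale=row.response_scale,
            param_names=tuple("abcde"[:n_params]),
            required_predictors=frozenset(_PRED_CODES[c] for c in preds_code),
            response=fn,
            reference_status=row.status,
            reference_params=ref_params,
            reference_criteria=ref_crit,
            note="" if pd.isna(row.note) else str(row.note),
        )
    return specs


_CATALOGUE = _load_catalogue()


def catalogue_table() -> pd.DataFrame:
    """The shipped machine-readable catalogue as a DataFrame (verbatim copy)."""
    with resources.files("firbiomass.data").joinpath("model_catalogue.csv").open() as fh:
        return pd.read_csv(fh)


def get_model(model_id: int) -> ModelSpec:
    """Return the immutable spec for one catalogue id (1-74)."""
    try:
        return _CATALOGUE[int(model_id)]
    except (KeyError, TypeError, ValueError):
        raise ModelNotFoundError(f"no catalogued model with id {model_id!r}") from None


def all_models() -> list[ModelSpec]:
    """All 74 specs in id order."""
    return [_CATALOGUE[i] for i in sorted(_CATALOGUE)]


def list_models(available_predictors: Iterable[str]) -> list[ModelSpec]:
    """Specs whose required predictors are all available, in id order."""
    avail = frozenset(available_predictors)
    unknown = avail - PREDICTORS
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    return [m for m in all_models() if m.required_predictors <= avail]


def _predictor_mapping(spec: ModelSpec, tree) -> dict:
    """Extract the predictors a spec needs from a TreeRecord/mapping/row.

    Basal area G is derived from D when absent; SI never is.
    """
    x = {}
    for name in spec.required_predictors:
        val = None
        if isinstance(tree, Mapping):
            val = tree.get(name)
        else:
            val = getattr(tree, name, None)
        if val is None and name == "G":
            d = tree.get("D") if isinstance(tree, Mapping) else getattr(tree, "D", None)
            if d is not None:
                val = basal_area(d) if np.isscalar(d) else np.pi*(np.asarray(d)/200.0)**2
        if val is None or (np.isscalar(val) and not np.isfinite(val)):
            raise PredictorMissingError(
                f"model {spec.id} requires predictor {name!r}, absent from tree data")
        x[name] = val
    return x


def evaluate_model(spec: ModelSpec, params: Sequence[float], tree) -> np.ndarray | float:
    """Predicted total biomass (kg, natural scale) for one tree or a column batch.

    ``tree`` may be a TreeRecord, a mapping of predictor arrays/scalars, or a
    DataFrame row.  Log-response forms are back-transformed by plain
    exponentiation (no lognormal bias correction); pass the prediction through
    ``exp(s^2/2)`` yourself if a Baskerville correction is wanted.
    """
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(
            f"model {spec.id} takes {spec.n_params} parameters, got {params.size}")
    x = _predictor_mapping(spec, tree)
    with np.errstate(all="ignore"):
        resp = spec.response(params, x)
        out = np.exp(resp) if spec.response_scale == "log" else resp
    if not np.all(np.isfinite(out)):
        raise DomainError(
            f"model {spec.id} produced a non-finite prediction "
            "(log of a non-positive intermediate?)")
    return out
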