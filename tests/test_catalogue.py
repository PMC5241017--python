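"""The 74-form model catalogue: lookup, evaluation, filtering, reference data."""

import math

import numpy as np
import pandas as pd
import pytest

from firbiomass.catalogue import (ModelNotFoundError, PredictorMissingError,
                                  all_models, catalogue_table, evaluate_model,
                                  get_model, list_models)
from firbiomass.metrics import DomainError
from conftest import MEAN_TREE


def test_ids_unique_and_cover_range():
    ids = [m.id for m in all_models()]
    assert ids == list(range(1, 75))


def test_reference_status_split():
    for m in all_models():
        expected = "misconverged" if m.id >= 65 else "converged"
        assert m.reference_status == expected
        if expected == "misconverged":
            assert m.reference_params is None and m.reference_criteria is None


def test_every_model_requires_a_predictor():
    for m in all_models():
        assert m.required_predictors, f"model {m.id} requires no predictor"
        assert m.required_predictors <= {"D", "H", "WD", "G", "SI", "V"}


def test_n_params_matches_reference_parameter_cells():
    table = catalogue_table().set_index("id")
    for m in all_models():
        if m.reference_status != "converged":
            continue
        cells = table.loc[m.id, ["a", "b", "c", "d", "e"]].notna().sum()
        assert m.n_params == cells, f"model {m.id}"


def test_get_model_examples():
    m1 = get_model(1)
    assert m1.response_scale == "log" and m1.n_params == 5
    assert m1.required_predictors == {"D", "H", "WD"}
    m41 = get_model(41)
    assert m41.n_params == 1 and m41.response_scale == "natural"
    with pytest.raises(ModelNotFoundError):
        get_model(0)
    with pytest.raises(ModelNotFoundError):
        get_model(75)


@pytest.mark.parametrize("mid, params, tree, expected, tol", [
    # closed-form arithmetic oracles
    (48, [312.470, 24.740], {"V": 0.2655}, 312.470 * 0.2655 + 24.740, 1e-12),
    (31, [1.0, 0.0], {"D": 12.3}, 1.0, 1e-12),
    (15, [0.162, 0.748], {"D": 17.0, "H": 15.8},
     0.162 * (17.0 ** 2 * 15.8) ** 0.748, 1e-12),
    (41, [0.054], {"D": 17.0, "H": 15.8, "WD": 304.2},
     0.054 * 304.2 * 17.0 ** 2 * 15.8 / 1000, 1e-12),
])
def test_evaluate_model_against_arithmetic_oracle(mid, params, tree, expected, tol):
    got = evaluate_model(get_model(mid), params, tree)
    assert got == pytest.approx(expected, rel=tol)


def test_evaluate_model_known_value():
    # B = a*V + b at the sample-mean volume
    assert evaluate_model(get_model(48), [312.470, 24.740], {"V": 0.2655}) == \
        pytest.approx(107.70, abs=5e-3)


def test_list_models_filtering():
    only_d = {m.id for m in list_models({"D"})}
    assert {11, 22, 25, 31, 32, 37} <= only_d
    assert 1 not in only_d          # needs WD
    assert 48 not in only_d         # needs V
    assert list_models(set()) == []
    assert len(list_models({"D", "H", "WD", "G", "SI", "V"})) == 74
    with pytest.raises(ValueError):
        list_models({"D", "diameter"})


def test_converged_reference_rows_predict_finite_positive_at_mean_tree():
    """Reference parameter columns evaluated at the sample-mean tree.

    Rows whose printed parameter columns are flagged suspect in the errata
    notes (signs/order inconsistent with the form) are excluded.
    """
    tree = dict(MEAN_TREE)
    for m in all_models():
        if m.reference_params is None or "suspect" in m.note:
            continue
        val = float(evaluate_model(m, m.reference_params, tree))
        assert math.isfinite(val) and val > 0, f"model {m.id}: {val}"


# independent scalar re-implementations of every log-response form
_LOG_ORACLES = {
    1: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*math.log(H)**2
        + p[3]*math.log(H)**3 + p[4]*math.log(WD),
    5: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D*D*H) + p[2]*math.log(WD),
    6: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*math.log(WD),
    7: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*math.log(H)
        + p[3]*math.log(WD),
    11: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+10),
    12: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+7) + p[2]*H + p[3]*math.log(H),
    13: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+11) + p[2]*math.log(H),
    17: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+11),
    21: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+13) + p[2]*H + p[3]*math.log(H),
    26: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+14) + p[2]*math.log(H),
    27: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+13),
    29: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+14),
    30: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+18) + p[2]*H + p[3]*math.log(H),
    33: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*math.log(H*D*D),
    34: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+5),
    35: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*H
        + p[3]*math.log(H*D*D),
    36: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*H,
    37: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D),
    38: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(math.pi*D),
    39: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+30) + p[2]*H + p[3]*math.log(H),
    40: lambda p, D, H, WD, G, SI: p[0] + p[1]*D/(D+18),
    55: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D)**2,
    59: lambda p, D, H, WD, G, SI: math.log(p[0]) + p[1]*H,
    65: lambda p, D, H, WD, G, SI: math.log(p[0]) + p[1]*D,
    66: lambda p, D, H, WD, G, SI: math.log(p[0]) + p[1]*D*D*H,
    72: lambda p, D, H, WD, G, SI: p[0] + p[1]*math.log(D) + p[2]*math.log(D*D)
        + p[3]*math.log(H),
}


def test_log_models_equal_exp_of_independent_linear_predictor():
    """Every log-response form equals exp(scalar oracle) on random draws."""
    log_ids = {m.id for m in all_models() if m.response_scale == "log"}
    assert log_ids == set(_LOG_ORACLES), "oracle table out of sync"
    rng = np.random.default_rng(42)
    for mid, oracle in _LOG_ORACLES.items():
        spec = get_model(mid)
        for _ in range(10):
            D, H = rng.uniform(5, 40), rng.uniform(4, 32)
            WD = rng.uniform(120, 420)
            tree = {"D": D, "H": H, "WD": WD, "G": math.pi*(D/200)**2, "SI": 16.0}
            p = rng.uniform(0.1, 2.0, spec.n_params)   # positive: ln(a) forms
            if mid == 66:          # slope multiplies D^2*H; keep exp() finite
                p[1] *= 1e-4
            expected = math.exp(oracle(p, D, H, WD, tree["G"], tree["SI"]))
            got = float(evaluate_model(spec, p, tree))
            assert got == pytest.approx(expected, rel=1e-12), f"model {mid}"


def test_missing_predictor_error_names_the_predictor():
    with pytest.raises(PredictorMissingError, match="WD"):
        evaluate_model(get_model(1), [1, 1, 1, 1, 1], {"D": 17.0, "H": 15.8})


def test_basal_area_is_derived_from_D_when_absent():
    got = evaluate_model(get_model(19), [0.0, 1.0], {"D": 20.0, "H": 20.0})
    G = math.pi * (20.0 / 200) ** 2
    assert got == pytest.approx(20.0 ** 2 * 20.0 * G, rel=1e-12)


def test_log_of_nonpositive_predictor_is_domain_error():
    with pytest.raises(DomainError):
        evaluate_model(get_model(37), [1.0, 2.0], {"D": -3.0})


def test_wrong_parameter_count_rejected():
    with pytest.raises(ValueError, match="parameters"):
        evaluate_model(get_model(31), [1.0], {"D": 10.0})


def test_formula_strings_are_well_formed():
    for m in all_models():
        assert m.formula.count("(") == m.formula.count(")"), f"model {m.id}"
        starts_log = m.formula.startswith("ln(B)")
        assert starts_log == (m.response_scale == "log"), f"model {m.id}"
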