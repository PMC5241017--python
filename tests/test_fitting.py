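"""Fit criteria, multi-start nonlinear least squares, catalogue-wide fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from firbiomass.catalogue import ModelSpec, get_model
from firbiomass.fitting import (FitResult, MultistartConfig, compute_criteria,
                                evaluate_fixed, fit_all, fit_model,
                                information_criteria, adjusted_r2)
from firbiomass.metrics import DomainError


def literal_loop_criteria(obs, pred):
    """Brute-force per-tree loop, independent of the vectorized implementation."""
    n = len(obs)
    mab = sum(abs(o - p) for o, p in zip(obs, pred)) / n
    rmse = math.sqrt(sum((o - p) ** 2 for o, p in zip(obs, pred)) / (n - 1))
    are = sum(abs((o - p) / o) for o, p in zip(obs, pred)) / n * 100
    mean = sum(obs) / n
    r2 = 1 - sum((o - p) ** 2 for o, p in zip(obs, pred)) / \
        sum((o - mean) ** 2 for o in obs)
    return {"MAB": mab, "RMSE": rmse, "ARE": are, "R2": r2}


def test_criteria_hand_example():
    crit = compute_criteria([1, 2, 3], [1.1, 1.9, 3.2])
    assert crit["MAB"] == pytest.approx(0.13333, abs=1e-4)
    assert crit["RMSE"] == pytest.approx(0.17321, abs=1e-4)
    assert crit["ARE"] == pytest.approx(7.2222, abs=1e-3)
    assert crit["R2"] == pytest.approx(0.97, abs=1e-10)


def test_criteria_perfect_fit():
    v = np.array([4.0, 9.0, 16.0, 25.0])
    crit = compute_criteria(v, v)
    assert crit["MAB"] == 0 and crit["RMSE"] == 0 and crit["ARE"] == 0
    assert crit["R2"] == 1


def test_criteria_match_literal_loop_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(2, 40)
        obs = rng.uniform(1, 500, n)
        pred = obs * rng.uniform(0.5, 1.5, n)
        got = compute_criteria(obs, pred)
        want = literal_loop_criteria(list(obs), list(pred))
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-12, abs=1e-12), k


def test_criteria_contract_errors():
    with pytest.raises(ValueError):
        compute_criteria([1, 2], [1, 2, 3])
    with pytest.raises(DomainError):
        compute_criteria([1, -2, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        compute_criteria([1], [1])


def test_information_criteria_conventions():
    ic = information_criteria(rss=0.0668, n=35, n_params=4)
    assert ic["AIC"] == pytest.approx(35 * math.log(0.0668) + 8)
    assert ic["BIC"] == pytest.approx(35 * math.log(0.0668) + 4 * math.log(35))
    assert information_criteria(0.0, 10, 2)["AIC"] == -math.inf
    assert adjusted_r2(0.97, 35, 4) < 0.97


def test_noiseless_power_law_recovery():
    D = np.linspace(6, 35, 30)
    data = {"D": D, "TB": 0.245 * D ** 2.090}
    res = fit_model(get_model(31), data, seed=0)
    assert res.converged
    assert res.params == pytest.approx([0.245, 2.090], rel=1e-6)
    assert res.criteria["MAB"] == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("mid", [22, 28, 48, 50])
def test_linear_models_match_closed_form_least_squares(mid, trees35):
    """Linear-in-parameter forms agree with the normal-equation solution."""
    trees, _ = trees35
    res = fit_model(get_model(mid), trees, seed=3)
    tb = trees["TB"].to_numpy()
    designs = {
        22: np.column_stack([np.ones(len(trees)), trees["D"] ** 2]),
        28: np.column_stack([np.ones(len(trees)), trees["D"], trees["D"] ** 2]),
        48: np.column_stack([trees["V"], np.ones(len(trees))]),
        50: np.column_stack([np.ones(len(trees)), trees["D"]]),
    }
    X = designs[mid]
    beta, *_ = np.linalg.lstsq(X, tb, rcond=None)
    assert res.converged
    # the optimum itself is matched to near machine precision; individual
    # parameters only to what the design's conditioning allows
    rss_ols = float(np.sum((tb - X @ beta) ** 2))
    assert res.loss <= rss_ols * (1 + 1e-12)   # at least as good an optimum
    assert res.loss == pytest.approx(rss_ols, rel=1e-10)
    assert res.predictions == pytest.approx(X @ beta, rel=1e-6, abs=1e-6)
    assert res.params == pytest.approx(beta, rel=1e-5, abs=1e-4)


def test_multistart_optimum_never_worse_than_any_start(trees35):
    trees, _ = trees35
    spec = get_model(16)
    cfg = MultistartConfig(n_starts=16)
    res = fit_model(spec, trees, multistart=cfg, seed=5)
    cols = {c: trees[c].to_numpy() for c in ("D", "H")}
    tb = trees["TB"].to_numpy()
    for x0 in cfg.starts(spec.n_params, seed=5, extra=[spec.reference_params]):
        with np.errstate(all="ignore"):
            pred = spec.response(x0, cols)
            rss0 = float(np.nansum((tb - pred) ** 2))
        if np.isfinite(rss0):
            assert res.loss <= rss0 + 1e-9


def test_more_starts_never_increase_optimum_loss(trees35):
    trees, _ = trees35
    spec = get_model(25)
    few = fit_model(spec, trees, multistart=MultistartConfig(n_starts=8), seed=5)
    many = fit_model(spec, trees, multistart=MultistartConfig(n_starts=32), seed=5)
    assert many.loss <= few.loss * (1 + 1e-9)


def test_fit_is_deterministic_for_fixed_seed(trees35):
    trees, _ = trees35
    a = fit_model(get_model(16), trees, seed=11)
    b = fit_model(get_model(16), trees, seed=11)
    assert np.array_equal(a.params, b.params)
    assert a.loss == b.loss


def test_misconvergence_yields_flagged_result_not_exception(trees35):
    trees, _ = trees35
    bad = ModelSpec(
        id="always-nan", formula="B = nan", response_scale="natural",
        param_names=("a",), required_predictors=frozenset({"D"}),
        response=lambda p, x: np.full_like(np.asarray(x["D"], float), np.nan),
    )
    res = fit_model(bad, trees, seed=0)
    assert not res.converged and res.criteria is None and res.params is None


def test_insufficient_data_is_contract_error():
    with pytest.raises(ValueError, match="more trees"):
        fit_model(get_model(1), {"D": [10, 11], "H": [12, 13],
                                 "WD": [300, 310], "TB": [50, 60]}, seed=0)


def test_fit_all_skips_models_without_predictors(trees35, caplog):
    trees, _ = trees35
    results = fit_all(trees, models=[get_model(31), get_model(58)], seed=0)
    assert [r.model_id for r in results] == [31]   # site-index form skipped


def test_fit_all_single_model(trees35):
    trees, _ = trees35
    results = fit_all(trees, models=[get_model(31)], seed=0)
    assert len(results) == 1 and results[0].model_id == 31


def test_fit_all_empty_data_is_error():
    with pytest.raises(ValueError):
        fit_all(pd.DataFrame({"D": [], "TB": []}))


def test_equivalent_forms_tie_on_exact_power_law_data():
    """B=a*(D^2 H)^b and its exp/ln twin fit identically when data obey it."""
    rng = np.random.default_rng(0)
    D = rng.uniform(6, 35, 40)
    H = 1.24 * D ** 0.9
    TB = 0.162 * (D ** 2 * H) ** 0.748
    data = {"D": D, "H": H, "TB": TB}
    r14 = fit_model(get_model(14), data, seed=2)
    r15 = fit_model(get_model(15), data, seed=2)
    assert r14.criteria["MAB"] < 1e-6 and r15.criteria["MAB"] < 1e-6
    # same optimum in the shared parameterization: exp(a14) == a15, b equal
    assert math.exp(r14.params[0]) == pytest.approx(r15.params[0], rel=1e-5)
    assert r14.params[1] == pytest.approx(r15.params[1], rel=1e-5)


def test_evaluate_fixed_consistency(trees35):
    trees, _ = trees35
    spec = get_model(15)
    fitted = fit_model(spec, trees, seed=1)
    fixed = evaluate_fixed(spec, fitted.params, trees)
    for k in ("MAB", "RMSE", "ARE", "R2"):
        assert fixed.criteria[k] == pytest.approx(fitted.criteria[k], rel=1e-12)


def test_evaluate_fixed_zero_coefficients_log_model(trees35):
    trees, _ = trees35
    res = evaluate_fixed(get_model(37), [0.0, 0.0], trees)   # predicts 1 kg always
    assert np.allclose(res.predictions, 1.0)
    assert np.isfinite(res.criteria["MAB"])


def test_published_fixed_coefficients_beat_nothing_but_lose_to_local_fit(trees35):
    """A fixed published Chinese Fir curve scores worse than a local refit."""
    trees, _ = trees35
    spec = get_model(15)    # same structural form as B = 0.0618*(D^2 H)^0.8532
    fixed = evaluate_fixed(spec, [0.0618, 0.8532], trees)
    local = fit_model(spec, trees, seed=1)
    assert fixed.criteria["MAB"] >= local.criteria["MAB"]
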