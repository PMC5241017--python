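"""Synthetic tree and stand generator.

Emulates the destructive-sampling campaign behind the reference Chinese Fir
dataset: 35 felled plantation trees whose summary statistics are published
(D mean 17.0 sd 7.3 cm on [5.1, 38.4]; H on [4.1, 31.8] m; WD mean 304.2
sd 59.7 kg/m^3 on [117.0, 427.1]; BCEF mean 391.8 sd 81.4 on [236.3, 613.8];
TB mean 107.8 sd 101.3 kg on [4.6, 482.4]).  The generative chain is

    D     ~ truncated lognormal matched to the D mean/sd and bounds
    H     = alpha * D^beta * exp(eps_H),     eps_H ~ N(0, h_sigma)
    WD    ~ truncated normal (mean 304.2, sd 59.7)
    BEF   ~ lognormal around 1.29, truncated so BCEF = BEF*WD stays in bounds
    TV    = taper stem volume of (D, H)
    ln TB = a + b*ln(TV) + c*ln(WD) + d*ln(BCEF) + sigma*eps

with (a, b, c, d) defaulting to the refined Chinese Fir coefficients and
sigma defaulting to the log-scale residual spread implied by that model's
published error statistics (about 4.5% relative error).  Component masses
are carved out of TB consistently with BEF and WD (trunk = WD*TV,
aboveground = BCEF*TV), so the derived-metric pipeline recovers the
generator's WD/BEF/BCEF exactly.  Age is generated for schema fidelity but
enters no model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .metrics import taper_volume
from .stand import DEFAULT_BI_COEFFICIENTS, StandRecord, stand_biomass, \
    reference_tree_from_stand

__all__ = ["SyntheticConfig", "generate_trees", "generate_stand"]

#: canonical column order of a generated tree table
COLUMNS = [
    "D", "H", "age", "stem_mass", "bark_mass", "branch_mass", "foliage_mass",
    "stump_mass", "coarse_root_mass", "middle_root_mass", "small_root_mass",
    "trunk_mass", "aboveground_mass", "TB", "V", "WD", "BEF", "BCEF", "G",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Distributions and coefficients of the generator (units as in TreeRecord)."""

    n_trees: int = 35
    seed: int = 0
    # D: lognormal calibrated to mean 17.0, sd 7.3, truncated to the sample range
    d_mean: float = 17.0
    d_sd: float = 7.3
    d_bounds: tuple[float, float] = (5.1, 38.4)
    # H = h_alpha * D^h_beta * exp(N(0, h_sigma)); spans roughly 4.1-31.8 m
    h_alpha: float = 1.24
    h_beta: float = 0.9
    h_sigma: float = 0.08
    # WD: truncated normal
    wd_mean: float = 304.2
    wd_sd: float = 59.7
    wd_bounds: tuple[float, float] = (117.0, 427.1)
    # BEF lognormal; BCEF = BEF*WD kept inside the sample range
    bef_mean: float = 1.29
    bef_log_sd: float = 0.10
    bcef_bounds: tuple[float, float] = (236.3, 613.8)
    # biomass law ln(TB) = a + b ln(TV) + c ln(WD) + d ln(BCEF) + sigma*eps
    coefficients: tuple[float, float, float, float] = DEFAULT_BI_COEFFICIENTS
    sigma: float = 0.045
    # component split fractions
    bark_fraction_of_trunk: float = 0.15
    branch_fraction_of_crown: float = 0.6
    age_bounds: tuple[float, float] = (6.0, 38.0)

    def validate(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for lo, hi, name in ((*self.d_bounds, "d_bounds"),
                             (*self.wd_bounds, "wd_bounds"),
                             (*self.bcef_bounds, "bcef_bounds")):
            if not lo < hi:
                raise ValueError(f"infeasible truncation bounds {name}: ({lo}, {hi})")
        if not (self.d_bounds[0] < self.d_mean < self.d_bounds[1]):
            raise ValueError("d_mean outside d_bounds: truncation infeasible")


def _truncated_lognormal_mu(target_mean: float, s: float, lo: float, hi: float) -> float:
    """Location mu such that lognormal(mu, s) truncated to [lo, hi] has the
    requested mean (plain moment-matching would bias the mean once the tails
    are cut)."""
    from scipy.optimize import brentq
    from scipy.stats import norm
    la, lb = math.log(lo), math.log(hi)

    def trunc_mean(mu):
        z1, z2 = (la - mu) / s, (lb - mu) / s
        num = norm.cdf(z2 - s) - norm.cdf(z1 - s)
        den = norm.cdf(z2) - norm.cdf(z1)
        return math.exp(mu + s * s / 2.0) * num / den

    return brentq(lambda m: trunc_mean(m) - target_mean, la, lb, xtol=1e-12)


def _truncated(rng, draw, lo, hi, size, max_iter=1000):
    """Rejection-sample `size` values from `draw` restricted to [lo, hi]."""
    out = np.empty(0)
    for _ in range(max_iter):
        need = size - out.size
        if need <= 0:
            return out[:size]
        vals = draw(rng, need * 2 + 8)
        out = np.concatenate([out, vals[(vals >= lo) & (vals <= hi)]])
    raise ValueError("truncation bounds reject essentially all draws")


def generate_trees(config: SyntheticConfig | None = None, *,
                   n_trees: Optional[int] = None, seed: Optional[int] = None,
                   sigma: Optional[float] = None) -> tuple[pd.DataFrame, dict]:
    """Draw a tree table plus a ground-truth record.

    Returns ``(trees, truth)`` where ``trees`` is a DataFrame in canonical
    column order and ``truth`` echoes the config together with the
    generating coefficients and the per-tree noiseless biomass.  Identical
    (config, seed) always give an identical table.
    """
    config = config or SyntheticConfig()
    if n_trees is not None or seed is not None or sigma is not None:
        from dataclasses import replace
        kw = {}
        if n_trees is not None:
            kw["n_trees"] = n_trees
        if seed is not None:
            kw["seed"] = seed
        if sigma is not None:
            kw["sigma"] = sigma
        config = replace(config, **kw)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_trees

    # D: lognormal with spread matched to the target cv and location chosen
    # so the *truncated* distribution has mean d_mean
    s = math.sqrt(math.log(1.0 + (config.d_sd / config.d_mean) ** 2))
    mu = _truncated_lognormal_mu(config.d_mean, s, *config.d_bounds)
    D = _truncated(rng, lambda r, k: r.lognormal(mu, s, k),
                   *config.d_bounds, n)

    H = config.h_alpha * D ** config.h_beta * np.exp(
        rng.normal(0.0, config.h_sigma, n))
    H = np.maximum(H, 1.4)
    age = np.round(rng.uniform(*config.age_bounds, n))

    WD = _truncated(rng, lambda r, k: r.normal(config.wd_mean, config.wd_sd, k),
                    *config.wd_bounds, n)
    # BEF given WD: lognormal truncated (exactly, by inverse CDF) to the
    # interval that keeps BCEF = BEF*WD inside its calibration bounds
    mu_bef = math.log(config.bef_mean) - config.bef_log_sd ** 2 / 2.0
    lo, hi = config.bcef_bounds
    z_lo = (np.log(lo / WD) - mu_bef) / config.bef_log_sd
    z_hi = (np.log(hi / WD) - mu_bef) / config.bef_log_sd
    u = rng.uniform(_norm.cdf(z_lo), _norm.cdf(z_hi))
    BEF = np.exp(mu_bef + config.bef_log_sd * _norm.ppf(u))
    # numerical safety in the extreme tails
    BEF = np.clip(BEF, lo / WD, hi / WD)
    BCEF = BEF * WD

    TV = np.array([taper_volume(d, h) for d, h in zip(D, H)])
    a, b, c, d_ = config.coefficients
    ln_tb_true = a + b * np.log(TV) + c * np.log(WD) + d_ * np.log(BCEF)

    aboveground = BCEF * TV
    trunk = WD * TV
    if config.sigma == 0.0:
        TB = np.exp(ln_tb_true)   # exactly on the law
    else:
        # mean-zero noise that still respects mass balance (roots cannot have
        # negative mass, so TB must exceed the aboveground mass): the standard
        # normal is truncated *symmetrically* to (z, -z), where z < 0 is the
        # standardized log-distance from the law's prediction down to the
        # aboveground mass.  Symmetry keeps E[eps | predictors] = 0, so fitted
        # coefficients stay unbiased; at the default sigma the truncation is
        # ~4 sd out and practically inactive.
        z = (np.log(aboveground * 1.001) - ln_tb_true) / config.sigma
        z = np.minimum(z, -1e-6)
        u = rng.uniform(_norm.cdf(z), _norm.cdf(-z))
        eps = _norm.ppf(u)
        TB = np.exp(ln_tb_true + config.sigma * eps)

    below = np.maximum(TB - aboveground, 0.0)
    bark = config.bark_fraction_of_trunk * trunk
    stem = trunk - bark
    crown = aboveground - trunk
    branch = config.branch_fraction_of_crown * crown
    foliage = crown - branch
    trees = pd.DataFrame({
        "D": D, "H": H, "age": age,
        "stem_mass": stem, "bark_mass": bark,
        "branch_mass": branch, "foliage_mass": foliage,
        "stump_mass": 0.30 * below, "coarse_root_mass": 0.45 * below,
        "middle_root_mass": 0.15 * below, "small_root_mass": 0.10 * below,
        "trunk_mass": trunk, "aboveground_mass": aboveground, "TB": TB,
        "V": TV, "WD": WD, "BEF": BEF, "BCEF": BCEF,
        "G": np.pi * (D / 200.0) ** 2,
    }, columns=COLUMNS)
    truth = {
        "config": asdict(config),
        "coefficients": {"intercept": a, "ln(TV)": b, "ln(WD)": c, "ln(BCEF)": d_},
        "sigma": config.sigma,
        "ln_tb_noiseless": ln_tb_true.tolist(),
    }
    return trees, truth


def generate_stand(config: SyntheticConfig | None = None, count: int = 100,
                   **kwargs) -> tuple[StandRecord, pd.DataFrame, dict]:
    """A synthetic stand of ``count`` trees.

    Returns the upscaled :class:`StandRecord` (using the default
    quadratic-mean reference tree), the member table, and a truth record
    whose ``SB_true`` is the summed member biomass — the quantity the bi
    method approximates.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    members, truth = generate_trees(config, n_trees=count, **kwargs)
    sv = float(members["V"].sum())
    ref = reference_tree_from_stand(members)
    coeffs = tuple(truth["coefficients"].values())
    record = stand_biomass(sv, ref, coeffs)
    truth["SB_true"] = float(members["TB"].sum())
    truth["SV"] = sv
    return record, members, truth
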