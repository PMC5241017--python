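"""Per-tree derived quantities: stem volume, conversion factors, basal area.

Stem volume comes from a fixed taper model for Chinese Fir,

    V = (pi/40000) * int_0^H D^2 * ((H - h) / (H - 1.3))^(3.482321 - 2.153699 * h^0.007) dh,

with D the over-bark diameter at breast height (cm), H total height (m) and
h height above ground (m).  The exponent varies slowly with h, so the relative
taper profile ((H - h)/(H - 1.3))^p behaves like a power-law bole shape; the
1/40000 factor converts cm^2 to m^2.  The conversion factors are

    BEF  = aboveground dry mass / trunk (stem) dry mass      (dimensionless)
    WD   = trunk dry mass / stem volume                      (kg m^-3)
    BCEF = BEF * WD  =  aboveground dry mass / stem volume   (kg m^-3)

so BCEF converts a stem volume directly into aboveground biomass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate

__all__ = [
    "TreeRecord",
    "DomainError",
    "taper_volume",
    "compute_bef",
    "compute_wd",
    "compute_bcef",
    "basal_area",
    "derive_metrics",
    "TAPER_EXPONENT_INTERCEPT",
    "TAPER_EXPONENT_SLOPE",
    "TAPER_EXPONENT_POWER",
]

# Taper exponent p(h) = INTERCEPT - SLOPE * h**POWER
TAPER_EXPONENT_INTERCEPT = 3.482321
TAPER_EXPONENT_SLOPE = 2.153699
TAPER_EXPONENT_POWER = 0.007

#: plausibility bounds for WD and BCEF (kg m^-3); outside -> warning, not error
DENSITY_PLAUSIBLE = (50.0, 1500.0)


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


@dataclass
class TreeRecord:
    """One measured or simulated tree.

    Units are fixed: D in cm, H in m, masses in kg, volumes in m^3,
    densities in kg m^-3.  Optional fields default to None and are filled
    by :func:`derive_metrics` where derivable.
    """

    D: float
    H: float
    age: Optional[float] = None
    # component dry masses (kg)
    stem_mass: Optional[float] = None
    bark_mass: Optional[float] = None
    branch_mass: Optional[float] = None
    foliage_mass: Optional[float] = None
    stump_mass: Optional[float] = None
    coarse_root_mass: Optional[float] = None
    middle_root_mass: Optional[float] = None
    small_root_mass: Optional[float] = None
    # aggregates (kg)
    TB: Optional[float] = None
    aboveground_mass: Optional[float] = None
    trunk_mass: Optional[float] = None
    # derived
    V: Optional[float] = None
    WD: Optional[float] = None
    BEF: Optional[float] = None
    BCEF: Optional[float] = None
    G: Optional[float] = None
    SI: Optional[float] = None

    def validate(self) -> None:
        if not (self.D > 0):
            raise DomainError(f"D must be positive, got {self.D}")
        if self.H is not None and not (self.H > 1.3) and self.V is None:
            raise DomainError(f"H must exceed 1.3 m, got {self.H}")
        if self.TB is not None and self.aboveground_mass is not None:
            if self.TB + 1e-9 < self.aboveground_mass:
                raise DomainError("TB smaller than aboveground mass")
        if self.BCEF is not None and self.BEF is not None and self.WD is not None:
            if abs(self.BCEF - self.BEF * self.WD) > 1e-9 * abs(self.BCEF):
                raise DomainError("BCEF inconsistent with BEF * WD")


def _taper_integrand(h, D, H):
    r = (H - h) / (H - 1.3)
    p = TAPER_EXPONENT_INTERCEPT - TAPER_EXPONENT_SLOPE * np.power(h, TAPER_EXPONENT_POWER)
    # r -> 0 at the tip with p > 0 for any realistic height, so the
    # integrand vanishes there; guard against 0**p evaluated as 0**0.
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(r > 0, np.exp(p * np.log(np.where(r > 0, r, 1.0))), 0.0)
    return D * D * val


def taper_volume(D: float, H: float, *, abs_tol: float = 1e-8) -> float:
    """Stem volume (m^3) of a tree of diameter ``D`` (cm) and height ``H`` (m).

    Integrates the taper profile from ground to tip with adaptive
    Gauss-Kronrod quadrature to absolute tolerance ``abs_tol`` (m^3).
    Below breast height (h < 1.3) the relative profile exceeds 1 and is used
    as-is (no clamping).  Strictly positive and exactly proportional to D^2.
    """
    if not (np.isfinite(D) and np.isfinite(H)):
        raise DomainError("D and H must be finite")
    if D <= 0:
        raise DomainError(f"D must be positive, got {D}")
    if H <= 1.3:
        raise DomainError(f"H must exceed 1.3 m (breast height), got {H}")
    integral, _ = integrate.quad(
        _taper_integrand, 0.0, H, args=(D, H), epsabs=abs_tol * 40000 / math.pi,
        epsrel=1e-10, limit=200,
    )
    return math.pi / 40000.0 * integral


def compute_bef(aboveground_mass: float, trunk_mass: float) -> float:
    """Biomass expansion factor: aboveground dry mass over trunk dry mass."""
    if trunk_mass is None or trunk_mass <= 0:
        raise DomainError(f"trunk mass must be positive, got {trunk_mass}")
    if aboveground_mass is None or aboveground_mass <= 0:
        raise DomainError(f"aboveground mass must be positive, got {aboveground_mass}")
    if aboveground_mass < trunk_mass:
        warnings.warn(
            "aboveground mass below trunk mass: BEF < 1 flags a data-quality issue",
            stacklevel=2,
        )
    return aboveground_mass / trunk_mass


def compute_wd(stem_dry_mass: float, stem_volume: float, *, printed_variant: bool = False,
               aboveground_mass: float | None = None) -> float:
    """Wood density (kg m^-3): stem dry mass per unit stem volume.

    ``printed_variant=True`` selects a legacy aboveground-mass numerator kept
    only for comparison with older reports; it is dimensionally a conversion
    factor rather than a density and is never the default.
    """
    if stem_volume is None or stem_volume <= 0:
        raise DomainError(f"stem volume must be positive, got {stem_volume}")
    if printed_variant:
        if aboveground_mass is None or aboveground_mass <= 0:
            raise DomainError("printed variant needs a positive aboveground mass")
        return aboveground_mass / stem_volume
    if stem_dry_mass is None or stem_dry_mass <= 0:
        raise DomainError(f"stem dry mass must be positive, got {stem_dry_mass}")
    wd = stem_dry_mass / stem_volume
    if not (DENSITY_PLAUSIBLE[0] <= wd <= DENSITY_PLAUSIBLE[1]):
        warnings.warn(f"WD {wd:.1f} kg/m^3 outside plausible bounds {DENSITY_PLAUSIBLE}",
                      stacklevel=2)
    return wd


def compute_bcef(BEF: float, WD: float) -> float:
    """Biomass conversion and expansion factor BCEF = BEF * WD (kg m^-3)."""
    if BEF is None or BEF <= 0:
        raise DomainError(f"BEF must be positive, got {BEF}")
    if WD is None or WD <= 0:
        raise DomainError(f"WD must be positive, got {WD}")
    bcef = BEF * WD
    if not (DENSITY_PLAUSIBLE[0] <= bcef <= DENSITY_PLAUSIBLE[1]):
        warnings.warn(f"BCEF {bcef:.1f} kg/m^3 outside plausible bounds {DENSITY_PLAUSIBLE}",
                      stacklevel=2)
    return bcef


def basal_area(D: float) -> float:
    """Breast-height basal area (m^2) from diameter D (cm): pi * (D/200)^2."""
    if D is None or D <= 0:
        raise DomainError(f"D must be positive, got {D}")
    return math.pi * (D / 200.0) ** 2


def derive_metrics(tree: TreeRecord, *, abs_tol: float = 1e-8) -> TreeRecord:
    """Fill every derivable field of ``tree`` in place and return it.

    Aggregation: trunk = stem + bark; aboveground = trunk + branches +
    foliage; TB = aboveground + all root components.  V comes from the taper
    model, then WD, BEF, BCEF and G follow from their definitions.  Existing
    values are never overwritten.
    """
    parts = tree
    if parts.trunk_mass is None and parts.stem_mass is not None:
        parts.trunk_mass = parts.stem_mass + (parts.bark_mass or 0.0)
    if parts.aboveground_mass is None and parts.trunk_mass is not None:
        parts.aboveground_mass = (
            parts.trunk_mass + (parts.branch_mass or 0.0) + (parts.foliage_mass or 0.0)
        )
    below = sum(
        m for m in (parts.stump_mass, parts.coarse_root_mass,
                    parts.middle_root_mass, parts.small_root_mass)
        if m is not None
    )
    if parts.TB is None and parts.aboveground_mass is not None:
        parts.TB = parts.aboveground_mass + below
    if parts.V is None and parts.H is not None:
        parts.V = taper_volume(parts.D, parts.H, abs_tol=abs_tol)
    if parts.WD is None and parts.trunk_mass is not None and parts.V is not None:
        parts.WD = compute_wd(parts.trunk_mass, parts.V)
    if parts.BEF is None and parts.aboveground_mass is not None and parts.trunk_mass is not None:
        parts.BEF = compute_bef(parts.aboveground_mass, parts.trunk_mass)
    if parts.BCEF is None and parts.BEF is not None and parts.WD is not None:
        parts.BCEF = compute_bcef(parts.BEF, parts.WD)
    if parts.G is None:
        parts.G = basal_area(parts.D)
    return parts
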