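"""Morphology–kinematics scaling: power-law fits and the drag balance.

Across rolling-samara species, wing thickness b is the single most
predictive morphological trait: mass scales as m ~ b^−1.44, planform
area as A ~ b^0.46, and both angular rates decrease with thickness
(ωr ~ b^−0.84, ωp ~ b^−0.90).  Substituting the convenient nearby
exponents m ~ b^−3/2 and A ~ b^1/2 into the steady drag balance

    m·g ~ ½·C_D·ρ·Vd²·A·cos θ

yields the headline scaling Vd ~ 1/b: thinner-winged samaras are
heavier and fall faster.  This module provides the log-log power-law
regression (OLS on log10–log10, via statsmodels), the drag-balance
exponent algebra, a drag-coefficient calibration, the classical
wing-loading predictor (mg/A)^½ for comparison, and the
volume-conservation check m vs b·A.

R² of power-law fits is reported on the log scale — the scale of the
fit; the linear-model R² (straight line on the original scale) is
reported alongside for model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import units


@dataclass
class PowerLawFit:
    """y = prefactor · x^exponent fitted by OLS of log10 y on log10 x."""

    exponent: float
    prefactor: float
    r_squared: float           # on the log-log scale
    n: int
    exponent_ci95: float       # 95% half-width on the exponent
    exponent_se: float
    linear_r_squared: float    # straight-line fit on the original scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R² must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("need n ≥ 3")
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")

    def predict(self, x) -> np.ndarray:
        return self.prefactor * np.asarray(x, float) ** self.exponent


def fit_power_law(x, y) -> PowerLawFit:
    """Fit y ~ x^β by ordinary least squares on the log10–log10 scale."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise ValueError("degenerate x (zero variance)")
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = res.conf_int(alpha=0.05)
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    return PowerLawFit(
        exponent=float(res.params[1]),
        prefactor=float(10.0 ** res.params[0]),
        r_squared=_safe_r2(res),
        n=int(x.size),
        exponent_ci95=float((ci[1, 1] - ci[1, 0]) / 2.0),
        exponent_se=float(res.bse[1]),
        linear_r_squared=_safe_r2(lin),
    )


def _safe_r2(res) -> float:
    """OLS R², defined as 1 for an exact fit to a constant response."""
    if res.centered_tss <= 0:
        return 1.0 if res.ssr < 1e-20 else 0.0
    return float(min(max(res.rsquared, 0.0), 1.0))


def fit_power_law_nls(x, y, p0: tuple[float, float] | None = None) -> PowerLawFit:
    """Nonlinear least squares on the original scale (optional variant).

    Off the default path; the canonical fit is :func:`fit_power_law`.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    if p0 is None:
        start = fit_power_law(x, y)
        p0 = (start.prefactor, start.exponent)
    popt, pcov = curve_fit(lambda xx, k, b: k * xx ** b, x, y, p0=p0,
                           maxfev=10000)
    resid = y - popt[0] * x ** popt[1]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    se = float(np.sqrt(pcov[1, 1]))
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    return PowerLawFit(exponent=float(popt[1]), prefactor=float(popt[0]),
                       r_squared=max(0.0, min(1.0, r2)), n=int(x.size),
                       exponent_ci95=1.96 * se, exponent_se=se,
                       linear_r_squared=float(lin.rsquared))


# ----------------------------------------------------------------------
@dataclass
class DragBalanceContext:
    """Constants of the steady drag balance mg ~ ½·C_D·ρ·Vd²·A·cosθ."""

    g: float = units.G
    rho: float = units.RHO_AIR
    theta_deg: float = 0.0     # coning angle; cosθ = 1 when unmeasured

    def __post_init__(self) -> None:
        if self.g <= 0 or self.rho <= 0:
            raise ValueError("g and rho must be positive")


def drag_balance_exponent(mass_exponent: float, area_exponent: float) -> float:
    """Exponent of Vd in b implied by mg ∝ Vd²·A at fixed C_D, ρ, cosθ.

    With m ~ b^e_m and A ~ b^e_A, Vd² ~ b^(e_m − e_A), so the descent
    velocity scales as b^((e_m − e_A)/2).  The published choice
    (−3/2, 1/2) gives −1: Vd ~ 1/b.
    """
    return (mass_exponent - area_exponent) / 2.0


@dataclass
class DragCoefficientFit:
    c_d: float
    residuals_N: np.ndarray = field(repr=False)


def fit_drag_coefficient(m_mg, A_cm2, Vd_cm_s,
                         ctx: DragBalanceContext | None = None) -> DragCoefficientFit:
    """Least-squares C_D from mg = ½·C_D·ρ·Vd²·A·cosθ across specimens.

    Inputs in field units (mg, cm², cm/s); a single specimen inverts
    the balance exactly.
    """
    ctx = ctx or DragBalanceContext()
    m = units.MG_TO_KG * np.atleast_1d(np.asarray(m_mg, float))
    A = units.CM2_TO_M2 * np.atleast_1d(np.asarray(A_cm2, float))
    v = units.CM_S_TO_M_S * np.atleast_1d(np.asarray(Vd_cm_s, float))
    if np.any(A <= 0) or np.any(v <= 0) or np.any(m <= 0):
        raise ValueError("mass, area and velocity must be positive")
    k = 0.5 * ctx.rho * v ** 2 * A * math.cos(math.radians(ctx.theta_deg))
    weight = m * ctx.g
    c_d = float(np.sum(weight * k) / np.sum(k ** 2))
    return DragCoefficientFit(c_d=c_d, residuals_N=weight - c_d * k)


def wing_loading_velocity(m_mg: float, A_cm2: float, g: float = units.G) -> float:
    """Classical wing-loading predictor (m·g/A)^½ in m/s scale.

    The traditional view relates terminal velocity to wing loading via
    Vd ~ (mg/A)^½; exposed so the comparison against the thickness
    scaling can be reproduced on any dataset.
    """
    if A_cm2 <= 0:
        raise ValueError("area must be positive")
    if m_mg < 0:
        raise ValueError("mass must be non-negative")
    return math.sqrt(units.MG_TO_KG * m_mg * g / (units.CM2_TO_M2 * A_cm2))


# ----------------------------------------------------------------------
@dataclass
class VolumeConservationFit:
    """Origin-constrained slopes of m versus b·A, one per species.

    The slope is an effective density in g/cm³ (mass per volume proxy
    b·A); a common slope within species with species-specific values
    indicates volume-conserving construction.
    """

    slopes_g_cm3: dict[str, float]
    pooled_r_squared: float


def volume_conservation_fit(df: pd.DataFrame) -> VolumeConservationFit:
    """Per-species slope of m vs b·A through the origin, plus pooled R².

    Expects columns ``species``, ``b_mm``, ``m_mg``, ``A_cm2``.
    """
    for col in ("species", "b_mm", "m_mg", "A_cm2"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df["species"].isna().any():
        raise ValueError("missing species labels")
    x_all = (df["b_mm"].to_numpy() * 0.1) * df["A_cm2"].to_numpy()  # cm³
    y_all = df["m_mg"].to_numpy() * 1e-3                            # g
    slopes: dict[str, float] = {}
    yhat = np.empty_like(y_all)
    for sp, sub in df.groupby("species", sort=False):
        idx = sub.index.to_numpy()
        pos = df.index.get_indexer(idx)
        if len(pos) < 2:
            raise ValueError(f"need ≥ 2 specimens per species ({sp})")
        x, y = x_all[pos], y_all[pos]
        slope = float(np.sum(x * y) / np.sum(x ** 2))
        slopes[str(sp)] = slope
        yhat[pos] = slope * x
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y_all - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return VolumeConservationFit(slopes_g_cm3=slopes, pooled_r_squared=r2)


# ----------------------------------------------------------------------
#: (y column, x column) pairs of the standard thickness-scaling report
STANDARD_PAIRS = (
    ("m_mg", "b_mm"),
    ("A_cm2", "b_mm"),
    ("omega_r_rad_s", "b_mm"),
    ("omega_p_rad_s", "b_mm"),
    ("Vd_cm_s", "b_mm"),
)


def scaling_report(df: pd.DataFrame,
                   pairs=STANDARD_PAIRS) -> pd.DataFrame:
    """Power-law fits for each (y, x) column pair present in ``df``.

    Returns a tidy table with one row per fit: pair, exponent, 95% CI
    half-width, prefactor, log-scale R², linear-scale R², n.
    """
    rows = []
    for ycol, xcol in pairs:
        if ycol not in df.columns or xcol not in df.columns:
            continue
        fit = fit_power_law(df[xcol].to_numpy(), df[ycol].to_numpy())
        rows.append(dict(pair=f"{ycol}~{xcol}", exponent=fit.exponent,
                         exponent_ci95=fit.exponent_ci95,
                         prefactor=fit.prefactor, r_squared=fit.r_squared,
                         linear_r_squared=fit.linear_r_squared, n=fit.n))
    return pd.DataFrame(rows)
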