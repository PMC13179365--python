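"""Interfacial enzyme kinetics on solid PET.

With excess solid substrate the roles of enzyme and substrate are swapped
relative to classical Michaelis-Menten: the measured rate saturates in the
*enzyme* concentration,

    v = invVmax * [E] / (invKM + [E])

``invVmax`` (nmol g^-1 s^-1, TPA equivalents normalized to PET load) is the
rate at surface saturation and ``invKM`` (uM) the enzyme concentration at
half saturation. Released TPA equivalents are quantified from A240 through
a linear standard curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, DataError


@dataclass
class StandardCurve:
    """Linear A240-vs-concentration calibration."""

    slope: float  # A240 per mM
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DataError(f"standard-curve slope must be positive, got {self.slope}")


@dataclass
class InverseMMFit:
    inv_Vmax: float  # nmol g^-1 s^-1
    inv_KM: float  # uM
    inv_Vmax_se: float
    inv_KM_se: float
    residual_norm: float
    n_points: int

    def predict(self, enzyme_um) -> np.ndarray:
        return inverse_mm(np.asarray(enzyme_um, dtype=float), self.inv_Vmax, self.inv_KM)


def inverse_mm(enzyme_um, inv_vmax: float, inv_km: float) -> np.ndarray:
    """The inverse Michaelis-Menten law v = invVmax*[E]/(invKM + [E])."""
    e = np.asarray(enzyme_um, dtype=float)
    return inv_vmax * e / (inv_km + e)


def fit_standard_curve(concentrations_mm, absorbances) -> StandardCurve:
    """Ordinary least-squares line through the calibration points."""
    c = np.asarray(concentrations_mm, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 3:
        raise DataError("standard curve needs at least 3 calibration points")
    if np.ptp(c) == 0:
        raise DataError("calibration concentrations have zero variance")
    res = stats.linregress(c, a)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n_points=c.size,
    )


def quantify_tpa(a240, curve: StandardCurve) -> np.ndarray:
    """Invert the standard curve; warns when a prediction is negative."""
    conc = (np.asarray(a240, dtype=float) - curve.intercept) / curve.slope
    if np.any(conc < 0):
        warnings.warn("negative predicted TPA concentration(s)", stacklevel=2)
    return conc


def _double_reciprocal_guess(e: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Seed (invVmax, invKM) from the linearization 1/v = invKM/invVmax * 1/[E] + 1/invVmax."""
    mask = (e > 0) & (v > 0)
    if mask.sum() < 2:
        return float(np.max(v, initial=1.0)) or 1.0, float(np.median(e[e > 0])) or 0.1
    slope, intercept = np.polyfit(1.0 / e[mask], 1.0 / v[mask], 1)
    if intercept <= 0 or slope <= 0:
        return float(np.max(v[mask])), float(np.median(e[mask]))
    return 1.0 / intercept, slope / intercept


def fit_inverse_mm(
    data: pd.DataFrame,
    include_zero: bool = True,
    enzyme_col: str = "enzyme_um",
    rate_col: str = "rate_nmol_g_s",
) -> InverseMMFit:
    """Pooled nonlinear least-squares fit of the inverse MM law.

    Replicates are fitted jointly (stacked residuals). Residuals are
    weighted by the model rate at the double-reciprocal initial guess
    (relative weighting, matching the multiplicative error structure of
    absorbance-derived rates); standard errors come from the Jacobian-based
    covariance. ``include_zero=False`` drops the zero-enzyme anchor points
    before fitting.
    """
    if not {enzyme_col, rate_col}.issubset(data.columns):
        raise DataError(f"kinetics table must have columns {enzyme_col!r}, {rate_col!r}")
    e = data[enzyme_col].to_numpy(dtype=float)
    v = data[rate_col].to_numpy(dtype=float)
    if np.any(e < 0):
        raise DataError("enzyme concentrations must be non-negative")
    if not include_zero:
        keep = e > 0
        e, v = e[keep], v[keep]
    if np.unique(e[e > 0]).size < 4:
        raise DataError("need at least 4 distinct nonzero enzyme concentrations")
    if np.allclose(v, 0):
        raise DataError("all rates are zero; nothing to fit")

    p0 = _double_reciprocal_guess(e, v)
    pred = inverse_mm(e, *p0)
    floor = pred[pred > 0].min() if np.any(pred > 0) else 1.0
    sigma = np.where(pred > 0, pred, floor)
    try:
        popt, pcov = optimize.curve_fit(
            inverse_mm, e, v, p0=p0, sigma=sigma, maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise ConvergenceError(f"inverse-MM fit did not converge: {exc}") from exc
    inv_vmax, inv_km = popt
    if inv_vmax <= 0 or inv_km <= 0:
        raise ConvergenceError(
            f"inverse-MM fit produced non-positive parameters "
            f"(invVmax={inv_vmax:.3g}, invKM={inv_km:.3g})"
        )
    se = np.sqrt(np.diag(pcov))
    resid = v - inverse_mm(e, inv_vmax, inv_km)
    return InverseMMFit(
        inv_Vmax=float(inv_vmax),
        inv_KM=float(inv_km),
        inv_Vmax_se=float(se[0]),
        inv_KM_se=float(se[1]),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=e.size,
    )
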