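"""Shear-thinning power-law (Ostwald–de Waele) analysis of flow curves.

The model is η(γ̇) = η₀ · γ̇ⁿ with consistency η₀ (the apparent
viscosity at γ̇ = 1 s⁻¹, in mPa·s) and flow index n (dimensionless,
n < 0 for shear-thinning media; n ≈ −1 indicates plastic behavior).
Fitting is ordinary least squares of log10 η on log10 γ̇, which is the
field's standard linearization and weights relative errors evenly
across the decades a flow curve spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .datatypes import FlowCurve
from .errors import AggregationError, InsufficientDataError, RangeError, ValidationError

__all__ = [
    "PowerLawFit",
    "RefViscosity",
    "fit_power_law",
    "evaluate_viscosity",
    "aggregate_replicates",
    "GAMMA_LVE",
    "GAMMA_JET",
]

#: reference shear rate of the linear-viscoelastic regime (s⁻¹)
GAMMA_LVE = 0.3
#: reference shear rate of the jetting regime (s⁻¹); 75 is accepted as
#: an alias for the same regime
GAMMA_JET = 75.4


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power-law parameters with OLS standard errors.

    ``eta0`` is in mPa·s at γ̇ = 1 s⁻¹; ``se_eta0`` is the delta-method
    standard error propagated from the log-intercept.  ``fit_range`` is
    the (γ̇_min, γ̇_max) window the fit actually used.
    """

    eta0: float
    n: float
    se_eta0: float
    se_n: float
    r2: float
    fit_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.eta0 > 0:
            raise ValidationError("eta0 must be positive")

    def predict(self, gamma: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Model viscosity η₀·γ̇ⁿ in mPa·s."""
        return self.eta0 * np.asarray(gamma, dtype=float) ** self.n


@dataclass(frozen=True)
class RefViscosity:
    """Replicate-aggregated viscosity at one reference shear rate
    (mean ± 1 sample s.d., n−1 denominator)."""

    gamma_ref: float
    eta_mean: float
    eta_sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.n_replicates == 1 and self.eta_sd != 0:
            raise ValidationError("eta_sd must be 0 for a single replicate")


def fit_power_law(
    curve: FlowCurve,
    fit_range: Optional[tuple[float, float]] = None,
) -> PowerLawFit:
    """Fit η = η₀·γ̇ⁿ to one flow curve by OLS in log-log space.

    Parameters
    ----------
    curve : FlowCurve
    fit_range : (float, float), optional
        Restrict the fit to shear rates in [γ̇_min, γ̇_max] (inclusive).
        Default: the full measured span.

    Returns
    -------
    PowerLawFit
        With exactly 2 points the fit is an interpolation: standard
        errors are 0 and r² is 1.
    """
    gamma = curve.shear_rate
    eta = curve.viscosity
    if fit_range is not None:
        lo, hi = fit_range
        mask = (gamma >= lo) & (gamma <= hi)
        gamma, eta = gamma[mask], eta[mask]
    if len(gamma) < 2:
        raise InsufficientDataError("power-law fit needs >= 2 points in range")

    x = np.log10(gamma)
    y = np.log10(eta)
    m = len(x)
    design = np.column_stack([np.ones(m), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, slope = coef
    resid = y - design @ coef
    sxx = float(np.sum((x - x.mean()) ** 2))
    if m > 2:
        s2 = float(resid @ resid) / (m - 2)
        se_slope = np.sqrt(s2 / sxx)
        se_intercept = np.sqrt(s2 * (1.0 / m + x.mean() ** 2 / sxx))
    else:
        se_slope = se_intercept = 0.0
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if m == 2 or syy == 0 else 1.0 - float(resid @ resid) / syy

    eta0 = float(10.0**intercept)
    return PowerLawFit(
        eta0=eta0,
        n=float(slope),
        se_eta0=float(eta0 * np.log(10.0) * se_intercept),
        se_n=float(se_slope),
        r2=float(min(max(r2, 0.0), 1.0)),
        fit_range=(float(gamma[0]), float(gamma[-1])),
    )


def evaluate_viscosity(
    curve_or_fit: Union[FlowCurve, PowerLawFit],
    gamma_ref: float,
    extrapolate: bool = False,
) -> float:
    """Viscosity (mPa·s) at a reference shear rate.

    For a :class:`FlowCurve`: a measured grid point is returned exactly;
    between points the value is linearly interpolated in
    (log10 γ̇, log10 η); outside the span a power-law fit of the whole
    curve is used, but only when ``extrapolate`` is set — otherwise a
    :class:`~rheojet.errors.RangeError` is raised.  For a
    :class:`PowerLawFit` the model is evaluated directly.
    """
    if isinstance(curve_or_fit, PowerLawFit):
        return float(curve_or_fit.predict(gamma_ref))
    curve = curve_or_fit
    if gamma_ref <= 0:
        raise ValidationError("gamma_ref must be positive")
    lo, hi = curve.span
    exact = np.isclose(curve.shear_rate, gamma_ref, rtol=1e-12, atol=0)
    if exact.any():
        return float(curve.viscosity[int(np.argmax(exact))])
    if lo <= gamma_ref <= hi:
        logeta = np.interp(
            np.log10(gamma_ref), np.log10(curve.shear_rate), np.log10(curve.viscosity)
        )
        return float(10.0**logeta)
    if not extrapolate:
        raise RangeError(
            f"gamma_ref {gamma_ref:g} s^-1 outside measured span [{lo:g}, {hi:g}]"
        )
    return float(fit_power_law(curve).predict(gamma_ref))


def aggregate_replicates(
    values: Sequence[float],
    gamma_ref: float,
    gamma_refs: Optional[Sequence[float]] = None,
) -> RefViscosity:
    """Mean ± sample s.d. (n−1) of replicate viscosities at one
    reference shear rate.

    ``gamma_refs``, when given, carries the per-value reference rates
    and must be uniform — mixing rates is an aggregation error.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 1:
        raise AggregationError("no values to aggregate")
    if gamma_refs is not None:
        refs = np.asarray(gamma_refs, dtype=float)
        if not np.allclose(refs, gamma_ref, rtol=1e-12):
            raise AggregationError("replicates measured at mixed reference shear rates")
    n = len(vals)
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return RefViscosity(
        gamma_ref=float(gamma_ref),
        eta_mean=float(np.mean(vals)),
        eta_sd=sd,
        n_replicates=n,
    )
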