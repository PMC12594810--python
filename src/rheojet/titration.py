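"""Additive-titration modeling and stability-boundary estimation.

Softening additives (MPD, PEGs) reduce LCP viscosity roughly
exponentially with concentration: over the four decades an MPD series
spans, log10 η is close to linear in concentration.  Fitting that line
lets one interpolate the concentration at which a medium crosses a
jet-stability threshold, and bracketing label changes in a labeled
series yields boundary-viscosity estimates (geometric mean of the
bracketing points — the symmetric midpoint on the log scale the data
occupy).

PEG softening is dose-like: concentration × molecular weight is the
operative quantity, so PEGs of different chain length can be
interconverted at equal dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import Stability
from .errors import InsufficientDataError, LabelingError, ValidationError

__all__ = [
    "TitrationSeries",
    "ConcViscFit",
    "ThresholdCrossing",
    "fit_conc_model",
    "predict_conc_at_threshold",
    "boundary_geomean",
    "peg_dose",
    "equivalent_conc",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Viscosity at one reference shear rate vs additive concentration
    (% v/v of the aqueous fraction), optionally with observed
    stability labels per point."""

    additive: str
    gamma_ref: float
    conc: np.ndarray
    eta: np.ndarray
    mw: Optional[float] = None
    labels: Optional[tuple[Stability, ...]] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        if len(conc) != len(eta):
            raise ValidationError("conc and eta lengths differ")
        if np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if np.any(conc < 0) or np.any(eta <= 0):
            raise ValidationError("concentrations must be >= 0 and viscosities > 0")
        if self.labels is not None:
            labels = tuple(Stability(l) for l in self.labels)
            if len(labels) != len(conc):
                raise ValidationError("labels length differs from conc")
            object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "eta", eta)

    def __len__(self) -> int:
        return len(self.conc)


@dataclass(frozen=True)
class ConcViscFit:
    """log10 η = a + b·c fit of a titration series.

    ``a``: log10 viscosity (mPa·s) at zero additive; ``b``: decades of
    viscosity change per % concentration (negative for softeners).
    """

    a: float
    b: float
    r2: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValidationError("fit parameters must be finite")

    def predict(self, conc):
        """Model viscosity (mPa·s) at concentration ``conc`` (%)."""
        return 10.0 ** (self.a + self.b * np.asarray(conc, dtype=float))


def fit_conc_model(series: TitrationSeries) -> ConcViscFit:
    """OLS of log10(η) on concentration."""
    if len(series) < 2:
        raise InsufficientDataError("titration fit needs >= 2 points")
    c = series.conc
    y = np.log10(series.eta)
    design = np.column_stack([np.ones(len(c)), c])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if syy == 0 else 1.0 - float(resid @ resid) / syy
    return ConcViscFit(
        a=float(coef[0]),
        b=float(coef[1]),
        r2=float(min(max(r2, 0.0), 1.0)),
        conc_range=(float(c[0]), float(c[-1])),
    )


@dataclass(frozen=True)
class ThresholdCrossing:
    """Concentration at which the fitted series crosses a viscosity
    threshold; ``extrapolated`` marks crossings outside the fitted
    concentration range."""

    conc: float
    eta_threshold: float
    extrapolated: bool


def predict_conc_at_threshold(fit: ConcViscFit, eta_threshold: float) -> ThresholdCrossing:
    """Invert the log-linear model: c* = (log10 η* − a) / b."""
    if not eta_threshold > 0:
        raise ValidationError("threshold must be positive")
    if fit.b == 0:
        raise ValidationError("flat concentration model never crosses a threshold")
    c_star = (np.log10(eta_threshold) - fit.a) / fit.b
    lo, hi = fit.conc_range
    return ThresholdCrossing(
        conc=float(c_star),
        eta_threshold=float(eta_threshold),
        extrapolated=bool(c_star < lo or c_star > hi),
    )


def boundary_geomean(series: TitrationSeries) -> dict[tuple[str, str], float]:
    """Boundary-viscosity estimates from a labeled titration series.

    Labels must degrade monotonically (never improve) as concentration
    of the softener increases.  For every adjacent label change the
    geometric mean of the two bracketing viscosities is returned,
    keyed by the (better, worse) label pair.
    """
    if series.labels is None:
        raise LabelingError("series has no stability labels")
    labels = series.labels
    offending = [
        (float(series.conc[i]), float(series.conc[i + 1]))
        for i in range(len(labels) - 1)
        if labels[i + 1].rank > labels[i].rank
    ]
    if offending:
        raise LabelingError(f"labels improve with concentration at pairs {offending}")
    out: dict[tuple[str, str], float] = {}
    for i in range(len(labels) - 1):
        if labels[i + 1] is not labels[i]:
            key = (labels[i].value, labels[i + 1].value)
            out[key] = float(np.sqrt(series.eta[i] * series.eta[i + 1]))
    return out


def peg_dose(conc_pct: float, mw: float) -> float:
    """PEG softening dose = concentration (%) × molecular weight
    (g/mol).  Equal dose ⇒ near-identical viscosity profile regardless
    of chain length."""
    if mw <= 0:
        raise ValidationError("molecular weight must be positive")
    if conc_pct < 0:
        raise ValidationError("concentration must be non-negative")
    return conc_pct * mw


def equivalent_conc(dose: float, mw: float) -> float:
    """Concentration (%) of a PEG of molecular weight ``mw`` that
    delivers the given dose; inverse of :func:`peg_dose`."""
    if mw <= 0:
        raise ValidationError("molecular weight must be positive")
    if dose < 0:
        raise ValidationError("dose must be non-negative")
    return dose / mw
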