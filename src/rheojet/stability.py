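"""Jet-stability classification for high-viscosity extrusion (HVE).

Two published decision rules map a medium's viscosity to a predicted
jetting regime:

* **absolute** — compare the viscosity at a reference shear rate with
  fixed critical values: at 0.3 s⁻¹ (LVE regime) the metastable and
  unstable boundaries are 7×10⁵ and 10⁴ mPa·s; at 75.4 s⁻¹ (jet
  regime) they are 2×10⁴ and 3×10³ mPa·s.
* **ratio** — compare the sample/pure-LCP viscosity ratio (both at the
  same shear rate) with cuts 0.02 (metastable below) and 0.001
  (unstable below).  Being a ratio, it is insensitive to rheometer
  setup bias.

A boundary value is assigned to the better class (a medium exactly at
7×10⁵ mPa·s is called stable).

The module also converts nozzle flow conditions to an average in-jet
shear rate via the Hagen–Poiseuille relation, and scores either
classifier against the packaged labeled reference table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .datatypes import MediumRecord, Stability
from .errors import ValidationError

__all__ = [
    "ThresholdSet",
    "StabilityCall",
    "NozzleFlow",
    "LVE_THRESHOLDS",
    "JET_THRESHOLDS",
    "RATIO_CUT_METASTABLE",
    "RATIO_CUT_UNSTABLE",
    "JET_THRESHOLD_WARNING",
    "classify_absolute",
    "classify_ratio",
    "shear_rate_hp",
    "flow_rate_for_shear",
    "order_of_magnitude",
    "concordance_report",
    "ConcordanceReport",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Absolute viscosity thresholds at one reference shear rate.

    ``stable_min``: lowest viscosity still called stable;
    ``unstable_max``: viscosity below which the jet is unstable.
    """

    gamma_ref: float
    stable_min: float
    unstable_max: float

    def __post_init__(self) -> None:
        if not (self.gamma_ref > 0 and self.stable_min > 0 and self.unstable_max > 0):
            raise ValidationError("thresholds and gamma_ref must be positive")
        if not self.stable_min > self.unstable_max:
            raise ValidationError("stable_min must exceed unstable_max")


#: published critical values at the 0.3 s⁻¹ (LVE) reference shear rate
LVE_THRESHOLDS = ThresholdSet(gamma_ref=0.3, stable_min=7e5, unstable_max=1e4)
#: published critical values at the 75.4 s⁻¹ (jet) reference shear rate
JET_THRESHOLDS = ThresholdSet(gamma_ref=75.4, stable_min=2e4, unstable_max=3e3)
#: sample/reference viscosity-ratio cuts
RATIO_CUT_METASTABLE = 0.02
RATIO_CUT_UNSTABLE = 0.001

JET_THRESHOLD_WARNING = (
    "jet-shear (75.4 s^-1) absolute thresholds reproduce only a minority of the "
    "labeled reference media; prefer the 0.3 s^-1 thresholds or the ratio method"
)


@dataclass(frozen=True)
class StabilityCall:
    """A classification verdict plus the evidence it used."""

    label: Stability
    method: str
    eta_used: float
    thresholds: Optional[ThresholdSet] = None
    ratio_cuts: Optional[tuple[float, float]] = None
    reference_eta: Optional[float] = None
    warnings: tuple[str, ...] = ()


def classify_absolute(eta: float, thresholds: ThresholdSet = LVE_THRESHOLDS) -> StabilityCall:
    """Classify from an absolute viscosity at the thresholds' shear rate.

    stable iff η ≥ stable_min; metastable iff unstable_max ≤ η <
    stable_min; unstable iff η < unstable_max.
    """
    if not eta > 0:
        raise ValidationError("viscosity must be positive")
    if eta >= thresholds.stable_min:
        label = Stability.stable
    elif eta >= thresholds.unstable_max:
        label = Stability.metastable
    else:
        label = Stability.unstable
    method = "absolute_jet" if thresholds.gamma_ref > 1 else "absolute_lve"
    warns = (JET_THRESHOLD_WARNING,) if method == "absolute_jet" else ()
    return StabilityCall(
        label=label, method=method, eta_used=eta, thresholds=thresholds, warnings=warns
    )


def classify_ratio(
    eta_sample: float,
    eta_reference: float,
    cut_meta: float = RATIO_CUT_METASTABLE,
    cut_unstable: float = RATIO_CUT_UNSTABLE,
) -> StabilityCall:
    """Classify from the sample / pure-LCP viscosity ratio.

    Both viscosities must be measured at the same shear rate; the
    reference is the unmodified LCP (monoolein:water 3:2 w/w ≈ 70:30
    v/v) measured on the same setup.
    """
    if eta_reference == 0:
        raise ZeroDivisionError("reference viscosity is zero")
    if not (eta_sample > 0 and eta_reference > 0):
        raise ValidationError("viscosities must be positive")
    r = eta_sample / eta_reference
    if r >= cut_meta:
        label = Stability.stable
    elif r >= cut_unstable:
        label = Stability.metastable
    else:
        label = Stability.unstable
    return StabilityCall(
        label=label,
        method="ratio",
        eta_used=eta_sample,
        ratio_cuts=(cut_meta, cut_unstable),
        reference_eta=eta_reference,
    )


# --- Hagen-Poiseuille shear-rate mapping --------------------------------

_UL_MIN_TO_M3_S = 1e-9 / 60.0
_UM_TO_M = 1e-6


def shear_rate_hp(Q: float, R: float, variant: str = "as_printed") -> float:
    """Average shear rate (s⁻¹) in a capillary jet from flow conditions.

    Parameters
    ----------
    Q : float
        Volumetric flow rate in µL/min.
    R : float
        Capillary inner radius in µm.
    variant : {"as_printed", "wall_shear"}
        ``as_printed`` evaluates γ̇ₐ = 4Q/(2πR³), the published average
        in-stream form; ``wall_shear`` the standard Newtonian wall
        shear rate 4Q/(πR³) (exactly twice the former).
    """
    if R <= 0:
        raise ValidationError("radius must be positive")
    if Q < 0:
        raise ValidationError("flow rate must be non-negative")
    q = Q * _UL_MIN_TO_M3_S
    r = R * _UM_TO_M
    gamma = 4.0 * q / (2.0 * math.pi * r**3)
    if variant == "wall_shear":
        gamma *= 2.0
    elif variant != "as_printed":
        raise ValidationError(f"unknown variant {variant!r}")
    return gamma


def flow_rate_for_shear(gamma: float, R: float, variant: str = "as_printed") -> float:
    """Flow rate (µL/min) producing a target average shear rate;
    exact algebraic inverse of :func:`shear_rate_hp`."""
    if R <= 0:
        raise ValidationError("radius must be positive")
    if gamma < 0:
        raise ValidationError("shear rate must be non-negative")
    if variant not in ("as_printed", "wall_shear"):
        raise ValidationError(f"unknown variant {variant!r}")
    r = R * _UM_TO_M
    # gamma = 4 Q / (denom * pi * R^3), denom = 2 (printed) or 1 (wall)
    denom = 2.0 if variant == "as_printed" else 1.0
    q = gamma * denom * math.pi * r**3 / 4.0
    return q / _UL_MIN_TO_M3_S


def order_of_magnitude(value: float) -> int:
    """Nearest-integer decimal order: 42.4 → 2 (i.e. ~10²)."""
    if value <= 0:
        raise ValidationError("order of magnitude needs a positive value")
    return int(round(math.log10(value)))


@dataclass(frozen=True)
class NozzleFlow:
    """Nozzle flow condition with its derived average shear rate."""

    radius_um: float
    flow_rate_ul_min: float
    variant: str = "as_printed"
    shear_rate: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "shear_rate",
            shear_rate_hp(self.flow_rate_ul_min, self.radius_um, self.variant),
        )


# --- concordance against the labeled reference table -------------------


@dataclass(frozen=True)
class ConcordanceReport:
    """Predicted vs observed stability over a labeled record set."""

    method: str
    n_total: int
    n_agree: int
    rows: tuple[dict, ...]
    mismatches: tuple[str, ...]

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_total


def concordance_report(
    records: Iterable[MediumRecord],
    method: str = "absolute_lve",
    reference_eta: Optional[float] = None,
) -> ConcordanceReport:
    """Score a classifier against labeled media records.

    ``method`` is one of ``absolute_lve`` (0.3 s⁻¹ thresholds on
    ``eta_lve``), ``absolute_jet`` (75.4 s⁻¹ thresholds on
    ``eta_jet``) or ``ratio`` (``eta_lve`` over the pure-LCP
    reference).  For ``ratio``, the reference defaults to the record
    named "LCP no additive" in the set.
    """
    records = list(records)
    if method == "ratio" and reference_eta is None:
        ref = [r for r in records if r.additive is None]
        if not ref:
            raise ValidationError("ratio method needs a reference_eta or a no-additive record")
        reference_eta = ref[0].eta_lve

    rows = []
    mismatches = []
    for rec in records:
        if method == "absolute_lve":
            call = classify_absolute(rec.eta_lve, LVE_THRESHOLDS)
        elif method == "absolute_jet":
            call = classify_absolute(rec.eta_jet, JET_THRESHOLDS)
        elif method == "ratio":
            call = classify_ratio(rec.eta_lve, reference_eta)
        else:
            raise ValidationError(f"unknown method {method!r}")
        agree = call.label is rec.label
        rows.append(
            {
                "name": rec.name,
                "predicted": call.label.value,
                "observed": rec.label.value,
                "eta_used": call.eta_used,
                "agree": agree,
            }
        )
        if not agree:
            mismatches.append(rec.name)
    n_agree = sum(r["agree"] for r in rows)
    return ConcordanceReport(
        method=method,
        n_total=len(rows),
        n_agree=n_agree,
        rows=tuple(rows),
        mismatches=tuple(mismatches),
    )
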