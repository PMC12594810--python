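"""Measurement containers for rheometer data.

Three raw-measurement types cover everything the analysis consumes:

* :class:`FlowCurve` — one replicate's steady-state viscosity curve
  η(γ̇) from a rotational experiment.
* :class:`ThixoTrace` — a three-phase thixotropy (recovery) trace used
  as a repeatability gate before each viscosity curve.
* :class:`OscSweep` — an oscillatory amplitude or frequency sweep
  (storage modulus G′ and loss modulus G″).

plus :class:`MediumRecord`, one row of the packaged reference table of
LCP media with additives (viscosity at 0.3 and 75.4 s⁻¹ and the observed
jetting-stability label).

Units are fixed package-wide: shear rate in s⁻¹, viscosity in mPa·s,
moduli in Pa, time in s, strain in %, angular frequency in rad/s.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "FlowCurve",
    "ThixoTrace",
    "OscSweep",
    "MediumRecord",
    "Stability",
    "SweepKind",
    "parse_stability_glyph",
]


class Stability(str, enum.Enum):
    """Jetting-stability taxonomy.

    ``stable``: steady jet pointing and speed; ``metastable``:
    instabilities that sheath-gas focusing or a higher flow rate can
    mitigate; ``unstable``: the jet cannot be stabilized (dripping,
    variable speed).  Ordered worst → best for monotonicity checks.
    """

    unstable = "unstable"
    metastable = "metastable"
    stable = "stable"

    @property
    def rank(self) -> int:
        return {"unstable": 0, "metastable": 1, "stable": 2}[self.value]


#: dash-like characters that reference tables use interchangeably
_DASHES = set("-‐‑‒–—−")


def parse_stability_glyph(glyph: str) -> Stability:
    """Decode a stability glyph (``+`` / ``-`` / ``--`` or en-dash).

    Published tables mark stable media ``+``, metastable ``-`` (single
    hyphen) and unstable with an en-dash, typographically ambiguous with
    the hyphen.  We therefore count dash-like characters: one dash →
    metastable, two dashes or a single en/em-dash → unstable.
    """
    s = glyph.strip()
    if s == "+":
        return Stability.stable
    if s and all(c in _DASHES for c in s):
        if s == "-":
            return Stability.metastable
        return Stability.unstable
    try:
        return Stability(s.lower())
    except ValueError:
        raise ValidationError(f"unrecognized stability glyph: {glyph!r}") from None


class SweepKind(str, enum.Enum):
    amplitude = "amplitude"
    frequency = "frequency"


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class FlowCurve:
    """One replicate's steady-state viscosity vs shear rate.

    Parameters
    ----------
    sample_id : str
        Medium identifier.
    replicate_id : int
        Replicate index within the sample.
    shear_rate : array-like of float
        Shear rates γ̇ in s⁻¹, strictly increasing, all > 0.
    viscosity : array-like of float
        Apparent viscosities η in mPa·s, same length, all > 0.
    temperature : float, default 20
        Plate temperature in °C.
    humidity : float, default 75
        Relative humidity in % maintained around the sample.
    """

    sample_id: str
    replicate_id: int
    shear_rate: np.ndarray
    viscosity: np.ndarray
    temperature: float = 20.0
    humidity: float = 75.0

    def __post_init__(self) -> None:
        gamma = _as_float_array(self.shear_rate, "shear_rate")
        eta = _as_float_array(self.viscosity, "viscosity")
        if len(gamma) != len(eta):
            raise ValidationError(
                f"shear_rate and viscosity lengths differ "
                f"({len(gamma)} vs {len(eta)}) for {self.sample_id!r}"
            )
        if len(gamma) < 2:
            raise ValidationError("a flow curve needs at least 2 points")
        if np.any(gamma <= 0):
            idx = int(np.argmax(gamma <= 0))
            raise ValidationError(f"non-positive shear rate at row {idx}")
        if np.any(eta <= 0):
            idx = int(np.argmax(eta <= 0))
            raise ValidationError(f"non-positive viscosity at row {idx}")
        if np.any(np.diff(gamma) <= 0):
            idx = int(np.argmax(np.diff(gamma) <= 0))
            if gamma[idx + 1] == gamma[idx]:
                raise ValidationError(
                    f"duplicate shear rate {gamma[idx]:g} s^-1 within replicate"
                )
            raise ValidationError("shear rates must be strictly increasing")
        object.__setattr__(self, "shear_rate", gamma)
        object.__setattr__(self, "viscosity", eta)

    def __len__(self) -> int:
        return len(self.shear_rate)

    @property
    def span(self) -> tuple[float, float]:
        """(γ̇_min, γ̇_max) of the measured grid."""
        return float(self.shear_rate[0]), float(self.shear_rate[-1])


_PHASES = ("pre", "disturb", "post")


@dataclass(frozen=True)
class ThixoTrace:
    """Three-phase thixotropy trace: low-shear hold, high-shear
    disturbance, low-shear recovery.

    The ``phase`` labels must form a contiguous pre → disturb → post
    partition with at least 2 points in pre and post.  ``replicate_id``
    pairs the trace with the flow curve measured right after it.
    """

    sample_id: str
    time: np.ndarray
    shear_rate: np.ndarray
    viscosity: np.ndarray
    phase: Sequence[str]
    replicate_id: int = 0

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        gamma = _as_float_array(self.shear_rate, "shear_rate")
        eta = _as_float_array(self.viscosity, "viscosity")
        phase = tuple(str(p) for p in self.phase)
        n = len(t)
        if not (len(gamma) == len(eta) == len(phase) == n):
            raise ValidationError("thixotropy trace columns must have equal length")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValidationError("time must be non-negative and increasing")
        if np.any(gamma <= 0) or np.any(eta <= 0):
            raise ValidationError("shear rate and viscosity must be positive")
        bad = set(phase) - set(_PHASES)
        if bad:
            raise ValidationError(f"unknown phase labels: {sorted(bad)}")
        # contiguity: labels in order pre, disturb, post with no interleaving
        order = [p for i, p in enumerate(phase) if i == 0 or phase[i - 1] != p]
        if order != [p for p in _PHASES if p in set(phase)]:
            raise ValidationError("phase must be a contiguous pre->disturb->post partition")
        for required in ("pre", "post"):
            if sum(p == required for p in phase) < 2:
                raise ValidationError(f"{required} phase needs at least 2 points")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "shear_rate", gamma)
        object.__setattr__(self, "viscosity", eta)
        object.__setattr__(self, "phase", phase)

    def phase_slice(self, name: str) -> np.ndarray:
        """Boolean mask selecting one phase."""
        return np.array([p == name for p in self.phase])


@dataclass(frozen=True)
class OscSweep:
    """Oscillatory sweep: G′ and G″ vs strain (amplitude sweep, x in %)
    or angular frequency (frequency sweep, x in rad/s)."""

    sample_id: str
    sweep_kind: SweepKind
    x: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray

    def __post_init__(self) -> None:
        kind = SweepKind(self.sweep_kind)
        x = _as_float_array(self.x, "x")
        gp = _as_float_array(self.g_prime, "g_prime")
        gpp = _as_float_array(self.g_double_prime, "g_double_prime")
        if not (len(x) == len(gp) == len(gpp)):
            raise ValidationError("sweep columns must have equal length")
        if len(x) < 3:
            raise ValidationError("a sweep needs at least 3 points")
        if np.any(x <= 0) or np.any(np.diff(x) <= 0):
            raise ValidationError("x must be positive and strictly increasing")
        if np.any(gp <= 0) or np.any(gpp <= 0):
            raise ValidationError("moduli must be positive")
        object.__setattr__(self, "sweep_kind", kind)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_double_prime", gpp)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class MediumRecord:
    """One reference-table row: an LCP medium with (optionally) one
    additive, its viscosity at the two reference shear rates and the
    observed jetting-stability label.

    Concentrations keep their printed basis (``conc_unit`` is
    ``pct_vv`` for % v/v of the aqueous fraction, ``mM`` for final-
    concentration salts, ``none`` for the pure reference); the printed
    string is preserved in ``conc_display`` and never silently
    converted.
    """

    name: str
    additive: Optional[str]
    additive_pct_aqueous: Optional[float]
    conc_unit: str
    additive_pct_total: Optional[float]
    conc_display: str
    eta_lve: float
    eta_lve_sd: float
    eta_jet: float
    eta_jet_sd: float
    label: Stability
    mw: Optional[float] = None

    def __post_init__(self) -> None:
        for v, what in (
            (self.eta_lve, "eta_lve"),
            (self.eta_lve_sd, "eta_lve_sd"),
            (self.eta_jet, "eta_jet"),
            (self.eta_jet_sd, "eta_jet_sd"),
        ):
            if not v > 0:
                raise ValidationError(f"{what} must be positive for {self.name!r}")
        object.__setattr__(self, "label", Stability(self.label))
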