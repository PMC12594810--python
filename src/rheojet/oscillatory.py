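"""Oscillatory-sweep summaries: LVE limit and loss factor.

An amplitude sweep of a gel-like material shows a storage-modulus (G′)
plateau at low strain — the linear viscoelastic (LVE) region — followed
by a sharp decline once the internal structure yields.  The strain at
which G′ first leaves the plateau is the critical shear strain; for
monoolein cubic phase it is around 3%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import OscSweep, SweepKind
from .errors import ValidationError

__all__ = ["LveLimit", "lve_limit", "loss_factor", "DEFAULT_LVE_DEVIATION_TOL"]

DEFAULT_LVE_DEVIATION_TOL = 0.10


@dataclass(frozen=True)
class LveLimit:
    """Critical shear strain estimate from an amplitude sweep.

    ``limit_found`` is False when G′ never leaves the plateau within
    the sweep; ``critical_strain`` is then the sweep maximum.
    """

    critical_strain: float
    plateau_g: float
    limit_found: bool
    deviation_tol: float


def lve_limit(sweep: OscSweep, deviation_tol: float = DEFAULT_LVE_DEVIATION_TOL) -> LveLimit:
    """Find the upper bound of the linear viscoelastic region.

    The plateau modulus is the mean of G′ over the lowest decade of
    strain (points with strain ≤ 10 × the smallest strain measured).
    The critical strain is the smallest strain where G′ deviates from
    the plateau by more than ``deviation_tol`` (relative).  If no point
    deviates, the sweep maximum is returned with ``limit_found=False``.
    """
    if sweep.sweep_kind is not SweepKind.amplitude:
        raise ValidationError("lve_limit requires an amplitude sweep")
    strain = sweep.x
    gp = sweep.g_prime
    decade = strain <= strain[0] * 10.0
    plateau = float(np.mean(gp[decade]))
    deviation = np.abs(gp - plateau) / plateau
    beyond = deviation > deviation_tol
    if not beyond.any():
        return LveLimit(float(strain[-1]), plateau, False, deviation_tol)
    idx = int(np.argmax(beyond))
    return LveLimit(float(strain[idx]), plateau, True, deviation_tol)


def loss_factor(sweep: OscSweep) -> np.ndarray:
    """Pointwise loss factor tan δ = G″ / G′.

    tan δ < 1 means elastically dominated (gel-like) response; the
    cubic phase stays below 1 across the frequency range, i.e. it
    behaves as an elastic solid under small-amplitude oscillation.
    """
    if np.any(sweep.g_prime == 0):
        raise ZeroDivisionError("G' contains zeros")
    return sweep.g_double_prime / sweep.g_prime
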