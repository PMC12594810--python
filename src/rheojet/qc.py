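"""Thixotropic repeatability gate.

Lipid cubic phase recovers its structure after a high-shear
disturbance; a sample that does not recover (slip, dehydration,
phase change) gives unreliable viscosity curves.  The gate compares the
low-shear viscosity before and after the disturbance and excludes a
replicate when the relative change exceeds a tolerance (default 20%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ThixoTrace
from .errors import ProtocolError, ValidationError

__all__ = ["QCResult", "thixo_qc", "DEFAULT_QC_TOLERANCE", "DEFAULT_QC_WINDOW_S"]

DEFAULT_QC_TOLERANCE = 0.20
#: averaging window: the trailing seconds of each low-shear hold, where
#: the material is closest to steady state
DEFAULT_QC_WINDOW_S = 60.0


@dataclass(frozen=True)
class QCResult:
    """Outcome of the thixotropy gate for one replicate."""

    eta_before: float
    eta_after: float
    rel_change: float
    passed: bool
    tolerance: float = DEFAULT_QC_TOLERANCE

    def __post_init__(self) -> None:
        expected = abs(self.eta_after - self.eta_before) / self.eta_before
        if not np.isclose(self.rel_change, expected, rtol=1e-12, atol=0):
            raise ValidationError("rel_change inconsistent with eta_before/eta_after")
        if self.passed != (self.rel_change <= self.tolerance):
            raise ValidationError("passed flag inconsistent with tolerance")


def _tail_mean(time: np.ndarray, eta: np.ndarray, window: float) -> float:
    cutoff = time[-1] - window
    mask = time >= cutoff
    return float(np.mean(eta[mask]))


def thixo_qc(
    trace: ThixoTrace,
    tolerance: float = DEFAULT_QC_TOLERANCE,
    window: float = DEFAULT_QC_WINDOW_S,
) -> QCResult:
    """Gate one thixotropy trace.

    ``eta_before`` / ``eta_after`` are means of viscosity over the last
    ``window`` seconds of the pre- and post-disturbance low-shear
    holds.  The replicate fails iff
    ``|eta_after − eta_before| / eta_before > tolerance`` — the
    inequality is strict, so a change of exactly the tolerance passes.

    Raises
    ------
    ProtocolError
        If the trace lacks a pre or post phase.
    """
    for required in ("pre", "post"):
        if not trace.phase_slice(required).any():
            raise ProtocolError(f"trace has no {required!r} phase")
    pre = trace.phase_slice("pre")
    post = trace.phase_slice("post")
    # phase-relative clocks: each hold is windowed from its own end
    eta_before = _tail_mean(trace.time[pre], trace.viscosity[pre], window)
    eta_after = _tail_mean(trace.time[post], trace.viscosity[post], window)
    if eta_before == 0:
        raise ZeroDivisionError("pre-phase viscosity mean is zero")
    rel = abs(eta_after - eta_before) / eta_before
    return QCResult(
        eta_before=eta_before,
        eta_after=eta_after,
        rel_change=rel,
        passed=rel <= tolerance,
        tolerance=tolerance,
    )
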