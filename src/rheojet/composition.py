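"""Composition and concentration-basis arithmetic for LCP media.

LCP is mixed by volume in coupled syringes (e.g. 70:30 v/v
monoolein:water), while the literature often quotes w/w ratios; the
density of monoolein (~0.94 g/cm³) links the two.  Additive
concentrations are quoted relative to the aqueous fraction, so the
whole-volume percentage is the aqueous percentage scaled by the water
volume fraction.  Nothing here converts bases silently — every
operation is an explicit, named conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "Composition",
    "MONOOLEIN_DENSITY",
    "vv_to_ww",
    "ww_to_vv",
    "additive_total_percent",
    "mix_dilute",
]

#: density of monoolein (g/cm³) used for v/v <-> w/w recalculation
MONOOLEIN_DENSITY = 0.94


@dataclass(frozen=True)
class Composition:
    """Lipid/water composition by volume with optional additives.

    ``additives`` is a sequence of ``(name, pct, basis)`` with basis in
    {"aqueous_vv", "total_vv", "ww_stock"}; the basis tag travels with
    the number and is never coerced.
    """

    lipid_vv: float
    water_vv: float
    rho_lipid: float = MONOOLEIN_DENSITY
    rho_water: float = 1.0
    additives: Sequence[tuple[str, float, str]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if abs(self.lipid_vv + self.water_vv - 1.0) > 1e-9:
            raise ValidationError("lipid_vv + water_vv must equal 1")
        if not (0 <= self.lipid_vv <= 1 and 0 <= self.water_vv <= 1):
            raise ValidationError("volume fractions must lie in [0, 1]")
        if self.rho_lipid <= 0 or self.rho_water <= 0:
            raise ValidationError("densities must be positive")
        for name, pct, basis in self.additives:
            if basis not in ("aqueous_vv", "total_vv", "ww_stock"):
                raise ValidationError(f"unknown basis {basis!r} for additive {name!r}")


def vv_to_ww(comp: Composition) -> float:
    """Lipid w/w percentage of a v/v composition.

    w/w% = 100 · f_l·ρ_l / (f_l·ρ_l + f_w·ρ_w).  70:30 v/v monoolein:
    water gives 68.7% w/w (commonly rounded to "68:32").
    """
    m_lipid = comp.lipid_vv * comp.rho_lipid
    m_water = comp.water_vv * comp.rho_water
    return 100.0 * m_lipid / (m_lipid + m_water)


def ww_to_vv(lipid_ww_pct: float, rho_lipid: float = MONOOLEIN_DENSITY,
             rho_water: float = 1.0) -> float:
    """Lipid v/v percentage from a w/w percentage (inverse of
    :func:`vv_to_ww`)."""
    if not 0 <= lipid_ww_pct <= 100:
        raise ValidationError("percentage must lie in [0, 100]")
    v_lipid = lipid_ww_pct / rho_lipid
    v_water = (100.0 - lipid_ww_pct) / rho_water
    return 100.0 * v_lipid / (v_lipid + v_water)


def additive_total_percent(conc_aqueous_pct: float, water_vv: float) -> float:
    """Whole-volume additive percentage from the aqueous-fraction
    percentage: total = aqueous% × water volume fraction.

    e.g. 10% MPD in the 30% aqueous fraction of standard LCP → 3% of
    the combined volume.
    """
    if conc_aqueous_pct < 0:
        raise ValidationError("concentration must be non-negative")
    if not 0 <= water_vv <= 1:
        raise ValidationError("water volume fraction must lie in [0, 1]")
    return conc_aqueous_pct * water_vv


def mix_dilute(stock_pct: float, parts_stock: float, parts_medium: float) -> float:
    """Final whole-volume percentage after mixing a stock with a medium
    in the given volume ratio.

    A 35% w/w stabilizer stock mixed 1:1 with LCP ends at 17.5% of the
    combined volume; symmetrically, the medium's own additives are
    diluted by parts_medium/(parts_stock+parts_medium).
    """
    if stock_pct < 0:
        raise ValidationError("stock percentage must be non-negative")
    if parts_stock < 0 or parts_medium < 0 or parts_stock + parts_medium == 0:
        raise ValidationError("mixing ratio parts must be non-negative and not both zero")
    return stock_pct * parts_stock / (parts_stock + parts_medium)
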