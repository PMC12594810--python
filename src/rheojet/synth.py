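"""Seeded synthetic-data generators for every measurement class.

Each generator draws from a known ground-truth model so that every
analysis stage can be tested closed-loop without external data:

* flow curves from the power-law model η = η₀·γ̇ⁿ,
* three-phase thixotropy traces with a configurable recovery fraction,
* amplitude sweeps with a G′ plateau, a sharp post-critical decline
  and a biphasic G″,
* titration series with log-linear viscosity–concentration dependence.

Noise is multiplicative lognormal with mean 1 and coefficient of
variation ``noise_cv`` — viscosities are positive and span decades, so
additive Gaussian noise would be unphysical.  All generators are pure
functions of (parameters, seed) via :func:`numpy.random.default_rng`
(PCG64): the same configuration reproduces bitwise-identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .datatypes import FlowCurve, OscSweep, Stability, SweepKind, ThixoTrace
from .errors import ValidationError
from .titration import TitrationSeries

__all__ = [
    "SynthConfig",
    "lognormal_noise",
    "gen_flowcurve",
    "gen_thixo",
    "gen_amplitude_sweep",
    "gen_titration",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    ``gamma_range`` defaults to the 0.3–300 s⁻¹ window a rotational
    viscosity-curve measurement covers, log-spaced; ``noise_cv``
    defaults to 5%, the order of the relative standard deviations seen
    in replicate rheometry of LCP media.
    """

    seed: int
    n_points: int = 30
    gamma_range: tuple[float, float] = (0.3, 300.0)
    noise_cv: float = 0.05
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        lo, hi = self.gamma_range
        if not (lo > 0 and hi > lo):
            raise ValidationError("gamma_range must satisfy 0 < lo < hi")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


def lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise factors ε ~ lognormal with E[ε] = 1 and
    coefficient of variation ``cv`` (σ² = ln(1+cv²), μ = −σ²/2)."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def gen_flowcurve(eta0: float, n: float, cfg: SynthConfig,
                  sample_id: str = "synthetic") -> list[FlowCurve]:
    """Generate ``cfg.replicates`` flow curves from η = η₀·γ̇ⁿ.

    ``eta0`` in mPa·s at 1 s⁻¹.  With ``noise_cv=0`` the model is
    reproduced exactly and a power-law fit recovers (η₀, n) to
    machine precision.
    """
    if eta0 <= 0:
        raise ValidationError("eta0 must be positive")
    rng = np.random.default_rng(cfg.seed)
    gamma = np.geomspace(*cfg.gamma_range, cfg.n_points)
    model = eta0 * gamma**n
    curves = []
    for rep in range(cfg.replicates):
        eps = lognormal_noise(rng, cfg.noise_cv, cfg.n_points)
        curves.append(
            FlowCurve(
                sample_id=sample_id,
                replicate_id=rep,
                shear_rate=gamma,
                viscosity=model * eps,
            )
        )
    return curves


def gen_thixo(
    eta_low: float,
    recovery_fraction: float,
    cfg: SynthConfig,
    sample_id: str = "synthetic",
    replicate_id: int = 0,
    hold_s: float = 120.0,
    disturb_s: float = 10.0,
    dt: float = 5.0,
    gamma_low: float = 1.0,
    gamma_high: float = 300.0,
) -> ThixoTrace:
    """Generate a pre → disturb → post thixotropy trace.

    The pre phase holds ``eta_low`` at the low shear rate for
    ``hold_s`` seconds; the disturbance runs at ``gamma_high`` with
    strongly depressed viscosity; the post phase recovers to
    ``eta_low × recovery_fraction``.  At zero noise the quality gate's
    relative change equals ``|recovery_fraction − 1|`` exactly, so
    recovery 1.0 passes with zero change and recovery < 0.8 fails the
    default 20% rule.
    """
    if recovery_fraction <= 0:
        raise ValidationError("recovery_fraction must be positive")
    rng = np.random.default_rng(cfg.seed)
    t_pre = np.arange(0.0, hold_s + dt / 2, dt)
    t_dis = np.arange(t_pre[-1] + dt, t_pre[-1] + disturb_s + dt / 2, dt)
    t_post = np.arange(t_dis[-1] + dt, t_dis[-1] + hold_s + dt / 2, dt)
    time = np.concatenate([t_pre, t_dis, t_post])
    phase = ["pre"] * len(t_pre) + ["disturb"] * len(t_dis) + ["post"] * len(t_post)
    shear = np.concatenate(
        [np.full(len(t_pre), gamma_low), np.full(len(t_dis), gamma_high),
         np.full(len(t_post), gamma_low)]
    )
    # shear-thinning: viscosity during the disturbance is far below the hold level
    eta = np.concatenate(
        [
            np.full(len(t_pre), eta_low),
            np.full(len(t_dis), eta_low * 1e-2),
            np.full(len(t_post), eta_low * recovery_fraction),
        ]
    )
    eta = eta * lognormal_noise(rng, cfg.noise_cv, len(eta))
    return ThixoTrace(
        sample_id=sample_id,
        replicate_id=replicate_id,
        time=time,
        shear_rate=shear,
        viscosity=eta,
        phase=phase,
    )


def gen_amplitude_sweep(
    plateau_g: float,
    critical_strain: float,
    cfg: SynthConfig,
    sample_id: str = "synthetic",
    strain_range: tuple[float, float] = (0.01, 100.0),
    decline_exponent: float = 1.5,
    drop_factor: float = 0.85,
) -> OscSweep:
    """Generate an amplitude sweep with a G′ plateau and a yield at
    ``critical_strain`` (%).

    Below the critical strain G′ is flat at ``plateau_g``; at and
    beyond it G′ drops by ``drop_factor`` and declines as a power law —
    the sharp-yielding shape seen for structured gels.  G″ is biphasic:
    a lognormal bump centered at the critical strain on a baseline one
    decade below the plateau.  ``critical_strain`` is inserted into the
    strain grid when it lies inside ``strain_range``, so the LVE-limit
    detector recovers it exactly at zero noise.  Pass
    ``critical_strain = math.inf`` for a fully linear (flat) sweep.
    """
    if plateau_g <= 0:
        raise ValidationError("plateau_g must be positive")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = strain_range
    strain = np.geomspace(lo, hi, cfg.n_points)
    finite_crit = np.isfinite(critical_strain)
    if finite_crit and lo < critical_strain < hi:
        strain = np.unique(np.append(strain, critical_strain))
    g_prime = np.full(len(strain), float(plateau_g))
    if finite_crit:
        yielded = strain >= critical_strain
        g_prime[yielded] = (
            plateau_g * drop_factor * (strain[yielded] / critical_strain) ** -decline_exponent
        )
    baseline = plateau_g / 10.0
    if finite_crit:
        bump = 2.0 * np.exp(-(np.log(strain / critical_strain) ** 2) / (2 * 0.5**2))
        g_pp = baseline * (1.0 + bump)
    else:
        g_pp = np.full(len(strain), baseline)
    g_prime = g_prime * lognormal_noise(rng, cfg.noise_cv, len(strain))
    g_pp = g_pp * lognormal_noise(rng, cfg.noise_cv, len(strain))
    return OscSweep(
        sample_id=sample_id,
        sweep_kind=SweepKind.amplitude,
        x=strain,
        g_prime=g_prime,
        g_double_prime=g_pp,
    )


def gen_titration(
    a: float,
    b: float,
    concs: Sequence[float],
    cfg: SynthConfig,
    additive: str = "synthetic additive",
    gamma_ref: float = 0.3,
    mw: Optional[float] = None,
    classifier: Optional[Callable[[float], Stability]] = None,
) -> TitrationSeries:
    """Generate a titration series with η(c) = 10^(a + b·c) × noise.

    ``classifier``, when given, maps each generated viscosity to a
    stability label (e.g. the absolute classifier at the series'
    reference shear rate) for use in concordance tests.
    """
    rng = np.random.default_rng(cfg.seed)
    concs = np.asarray(concs, dtype=float)
    eta = 10.0 ** (a + b * concs) * lognormal_noise(rng, cfg.noise_cv, len(concs))
    labels = tuple(classifier(e) for e in eta) if classifier is not None else None
    return TitrationSeries(
        additive=additive, gamma_ref=gamma_ref, conc=concs, eta=eta, mw=mw, labels=labels
    )
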