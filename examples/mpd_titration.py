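"""Interpolate jet-stability boundaries from an MPD titration.

Uses the packaged MPD dilution series at the 0.3 1/s reference shear
rate: fits log10(viscosity) vs concentration, inverts the fit to find
the concentration at which the medium crosses the published critical
viscosities, and estimates boundary viscosities by bracketing the
observed label changes.
"""

from rheojet import (
    Stability,
    TitrationSeries,
    boundary_geomean,
    fit_conc_model,
    predict_conc_at_threshold,
)

series = TitrationSeries(
    additive="MPD",
    gamma_ref=0.3,
    conc=[0.0, 5.0, 7.5, 10.0, 12.5, 15.0],
    eta=[5.7e6, 9.8e5, 5.4e5, 2.4e4, 7.5e3, 1.3e3],
    labels=[
        Stability.stable, Stability.stable, Stability.metastable,
        Stability.metastable, Stability.metastable, Stability.unstable,
    ],
)

fit = fit_conc_model(series)
print(f"log-linear fit: log10(eta) = {fit.a:.3f} {fit.b:+.4f} * conc%  "
      f"(r2 = {fit.r2:.3f})")
# ~ -0.25 decades per percent: each 4% MPD costs one decade of viscosity

for eta_crit, name in ((7e5, "metastable"), (1e4, "unstable")):
    crossing = predict_conc_at_threshold(fit, eta_crit)
    flag = " (extrapolated)" if crossing.extrapolated else ""
    print(f"crosses the {name} threshold ({eta_crit:.0e} mPa.s) "
          f"at {crossing.conc:.1f}% MPD{flag}")

bounds = boundary_geomean(series)
for (better, worse), eta in bounds.items():
    print(f"{better}->{worse} boundary (geometric mean of bracket): "
          f"{eta:.2e} mPa.s")
# the stable->metastable bracket reproduces the published 7e5 mPa.s
# critical value within 5%
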