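"""Fit the shear-thinning power law to a synthetic pure-LCP flow curve.

Generates three replicate flow curves from the model eta = eta0 * gamma^n
(eta0 = 6.2e6 mPa.s, n = -1.06) with 5% measurement noise, fits each by
OLS in log-log space, and prints the recovered parameters.
"""

from rheojet import SynthConfig, fit_power_law, gen_flowcurve

cfg = SynthConfig(seed=1, n_points=30, gamma_range=(0.3, 300.0),
                  noise_cv=0.05, replicates=3)
curves = gen_flowcurve(eta0=6.2e6, n=-1.06, cfg=cfg, sample_id="pure LCP")

print("replicate   eta0 (mPa.s at 1/s)   flow index n      r^2")
for curve in curves:
    fit = fit_power_law(curve)
    print(f"{curve.replicate_id:>9}   {fit.eta0:>12.3e}          "
          f"{fit.n:+.3f}±{fit.se_n:.3f}   {fit.r2:.4f}")

# eta0 is the apparent viscosity at 1 s^-1 (the log-log intercept);
# n near -1 means the medium behaves plastically: stress is nearly
# independent of shear rate, which is what lets LCP extrude as a jet.
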