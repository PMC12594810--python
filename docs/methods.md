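# Methods

## Physical model

Monoolein-based lipid cubic phase (LCP) and its additive-softened
variants behave as shear-thinning gels. Over the 0.3–300 s⁻¹ window a
rotational rheometer covers, the steady-state flow curve follows the
Ostwald–de Waele power law

    η(γ̇) = η₀ · γ̇ⁿ

with the consistency η₀ defined as the apparent viscosity at
γ̇ = 1 s⁻¹ (the natural intercept of the log-log line, in mPa·s) and
the dimensionless flow index *n*. For pure LCP *n* is close to −1,
i.e. shear stress is nearly independent of shear rate — plastic
behavior. Oscillatory sweeps complement the flow curve: in an amplitude
sweep, the storage modulus G′ holds a plateau up to a critical shear
strain (~3% for pure LCP) beyond which the internal structure yields;
the loss factor tan δ = G″/G′ stays below 1 across frequency,
confirming elastically dominated response. (Some figure captions in
the field print the loss factor as G′/G″; this package uses the
standard definition tan δ = G″/G′ — the only one under which an
elastic gel has tan δ < 1.)

Jet stability of a high-viscosity-extrusion (HVE) stream is predicted
from viscosity at two reference shear rates: 0.3 s⁻¹ (inside the
linear-viscoelastic regime, where the measurement is most reliable)
and 75.4 s⁻¹ (the regime an extruded jet actually experiences; 75 is
accepted as an alias). Two published decision rules are implemented:

* absolute thresholds — at 0.3 s⁻¹: stable ≥ 7×10⁵ mPa·s, unstable
  < 10⁴ mPa·s, metastable between; at 75.4 s⁻¹: 2×10⁴ and 3×10³ mPa·s;
* viscosity ratio — sample over pure-LCP reference at the same shear
  rate, stable ≥ 0.02, unstable < 0.001.

A viscosity exactly at a threshold takes the better class; this
boundary convention is a package decision (the sources do not state
one) and is regression-tested. The two rules are *not* mutually
consistent (7×10⁵ / 5.7×10⁶ ≈ 0.12 ≠ 0.02); both are kept as
independent published rules, reports carry both calls plus a conflict
flag, and no arbitration is attempted. Direct evaluation against the
packaged labeled table shows the 0.3 s⁻¹ thresholds reproduce 18/22
observed outcomes and the ratio rule 19/22, while the 75.4 s⁻¹
thresholds reproduce only 5/22 — the jet-shear rule is therefore
provided but always carries a reliability warning.

The average shear rate inside a capillary jet is computed from the
Hagen–Poiseuille relation in its published average-in-stream form
γ̇ₐ = 4Q/(2πR³) (default), with the standard Newtonian wall shear rate
4Q/(πR³) — exactly twice as large — available as `wall_shear`. Units
are µL/min and µm on input, s⁻¹ out.

## Quality control

Every flow curve is preceded by a thixotropy trace: 2 min at 1 s⁻¹, a
10 s disturbance at 300 s⁻¹, 2 min recovery at 1 s⁻¹. The gate
compares the mean viscosity over the trailing 60 s of the pre- and
post-disturbance holds (tail windows approximate steady state; the
window length is configurable) and excludes the replicate when the
relative change exceeds 20% (strict inequality: exactly 20% passes).
The disturbance shear rate is taken as 300 s⁻¹ for unit consistency
with the 1 s⁻¹ holds. Passing replicates are aggregated as arithmetic
mean ± sample standard deviation (n−1); a single replicate reports
s.d. 0. Fewer than three passing replicates produces a warning, not an
error. Metadata outside 20 °C / 75–85% RH triggers a provenance
warning because the stability thresholds were calibrated under
humidity-controlled conditions; no numeric correction is attempted.

## Fitting and evaluation

Power-law and titration fits are ordinary least squares on log₁₀
viscosity (against log₁₀ shear rate and concentration respectively),
computed via `numpy.linalg.lstsq` with textbook standard-error
formulas; tests cross-check the fits against an independent
brute-force grid-search minimizer. Log-scale fitting weights relative
errors evenly across the several decades these data span; with exactly
two points the fit is an interpolation (zero standard errors, r² = 1).
The default fit window is the full measured span, overridable, because
the window behind published pure-LCP parameters is not stated: note
that η₀ = 6.2 kPa·s with n = −1.06 predicts ≈ 2.2×10⁷ mPa·s at
0.3 s⁻¹, a factor ~4 above the measured table value 5.7×10⁶ — the
package exposes both the fit-based and the point estimates and does
not force agreement.

Viscosity at a reference shear rate is read directly at a measured
grid point, linearly interpolated in (log₁₀γ̇, log₁₀η) between points,
and extrapolated by the power-law fit only when explicitly requested.
Whether a published "viscosity at 0.3 s⁻¹" is a grid read or an
interpolation is unstated; grid-read-with-interpolation-fallback is
the default here.

The LVE limit is detected from an amplitude sweep as the smallest
strain at which G′ deviates from its plateau (the mean over the lowest
decade of strain) by more than 10% relative; a sweep that never
deviates returns its maximum strain flagged "no limit found".

## Titration analysis

"Linear dependence" of viscosity on softener concentration is
implemented as linearity in log₁₀η: the MPD series spans nearly four
decades, untenable on the natural scale. The fitted line inverts in
closed form to the concentration crossing any viscosity threshold
(flagged when outside the fitted range). Stability boundaries from a
labeled series are estimated as the geometric mean of the two
viscosities bracketing each label change — symmetric on the log scale
the data occupy; the stable→metastable bracket of the MPD series
(9.8×10⁵, 5.4×10⁵) reproduces the published 7×10⁵ mPa·s critical value
within 5%. The published 10⁴ unstable boundary is not cleanly
reproducible from any bracketing pair; the operation reports all
label-change boundaries as computed. Labels must degrade monotonically
with softener concentration, else the offending pairs are reported as
an error.

One labeling subtlety: the packaged reference table prints the 7.5%
MPD medium as stable, while the jet-testing narrative describes it as
jetted with variable pointing — the metastable definition. The fixture
stores the table glyph verbatim (the concordance counts above depend
on it); boundary-estimation examples and tests use the jet-observation
label sequence, which is also the only reading under which the
bracketing estimate reproduces 7×10⁵.

PEG softening is modeled as dose-like: concentration (%) × molecular
weight (g/mol) is the operative quantity (50% PEG 300, 10% PEG 1500
and 2.5% PEG 6000 share dose 15000 and near-identical viscosity
profiles), with `equivalent_conc` as the inverse. Composition
arithmetic uses a monoolein density of 0.94 g/cm³ (a 35 °C literature
figure, applied at the 20 °C working temperature for lack of a better
one; overridable): 70:30 v/v monoolein:water computes to 68.7:31.3
w/w, commonly rounded to 68:32. Concentration bases (% v/v of the
aqueous fraction, % of total volume, w/w stock, mM) are carried as
explicit tags and never converted silently.

## Synthetic data

The generators emulate the study conditions: flow curves from
η₀·γ̇ⁿ on 30 log-spaced points over 0.3–300 s⁻¹; thixotropy traces
with 2-min holds, a 10 s disturbance and a configurable recovery
fraction (at zero noise the QC relative change equals
|recovery − 1| exactly); amplitude sweeps with a G′ plateau, a sharp
15% yield drop at the critical strain followed by power-law decline,
and a biphasic G″ (lognormal bump centered at the critical strain —
the qualitative published shape; its width and height are package
choices); titration series from 10^(a+b·c). Noise is multiplicative
lognormal with mean 1 and cv defaulting to 0.05, the order of the
relative standard deviations in the reference table; replicate
structure is i.i.d. — instrument drift and loading variation are not
modeled separately because they are not characterized in the source
data. All generators are pure functions of (parameters, seed) through
numpy's PCG64 `default_rng`; determinism is pinned to the algorithm,
not the platform.

What passing tests show — and don't: closed-loop recovery on synthetic
data demonstrates correctness of the estimators under the stated noise
model, not the accuracy of rheometry on real LCP; fixture-based
concordance demonstrates that the published decision rules are
implemented faithfully, not that they generalize beyond the 22 media
measured.

## Problem sizes and numerical choices

Parameter-recovery checks use 100 replicates of 30-point curves at 5%
noise (seconds of runtime); noise-calibration checks use 2×10⁴–5×10⁴
draws. OLS on a 2-parameter model needs no iteration or
initialization. Degenerate inputs are rejected by type invariants
(positive, strictly increasing grids; contiguous thixotropy phases;
≥ 2 points per fit). r² is clipped to [0, 1] against floating-point
round-off on perfect fits. JSON reports serialize with sorted keys and
no timestamp, so identical inputs and configuration produce
byte-identical reports.

## Known limitations

No yield-stress (Herschel–Bulkley) or Cross/Carreau modeling;
no frequency-dependent constitutive model or temperature
superposition; no fluid-dynamic jet simulation (breakup, gas focusing,
Rayleigh instability); no lipid-phase-diagram or SAXS modeling. How
the published critical values were originally derived (bracketing,
fit, or rounding judgment) is not stated in the sources; this package
treats them as given constants and separately reports what its own
bracketing estimator reproduces.
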