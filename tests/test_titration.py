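"""Titration modeling, boundary estimation, PEG dose equivalence and
composition arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rheojet import (
    Composition,
    Stability,
    SynthConfig,
    TitrationSeries,
    additive_total_percent,
    boundary_geomean,
    equivalent_conc,
    fit_conc_model,
    gen_titration,
    mix_dilute,
    peg_dose,
    predict_conc_at_threshold,
    vv_to_ww,
    ww_to_vv,
)
from rheojet.errors import InsufficientDataError, LabelingError, ValidationError

# the MPD dilution series at the 0.3 s^-1 reference shear rate
MPD_CONC = [0.0, 5.0, 7.5, 10.0, 12.5, 15.0]
MPD_ETA_LVE = [5.7e6, 9.8e5, 5.4e5, 2.4e4, 7.5e3, 1.3e3]
# labels as observed at the jet-testing station: the 7.5% sample jetted
# with variable pointing (metastable), unlike its reference-table glyph
MPD_JET_LABELS = [
    Stability.stable, Stability.stable, Stability.metastable,
    Stability.metastable, Stability.metastable, Stability.unstable,
]


def mpd_series(labels=None):
    return TitrationSeries(
        additive="MPD", gamma_ref=0.3, conc=MPD_CONC, eta=MPD_ETA_LVE,
        labels=labels,
    )


def brute_force_conc_fit(conc, eta, a_grid, b_grid):
    best = (None, None, np.inf)
    for a in a_grid:
        for b in b_grid:
            r = np.log10(eta) - (a + b * np.asarray(conc))
            sse = float(r @ r)
            if sse < best[2]:
                best = (a, b, sse)
    return best[0], best[1]


class TestConcentrationModel:
    def test_exact_log_linear_series_recovered(self):
        conc = np.array([0.0, 2.0, 4.0, 8.0])
        series = TitrationSeries("x", 0.3, conc, 10 ** (6 - 0.25 * conc))
        fit = fit_conc_model(series)
        assert fit.a == pytest.approx(6.0, abs=1e-12)
        assert fit.b == pytest.approx(-0.25, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_mpd_series_slope_matches_closed_form_ols(self):
        fit = fit_conc_model(mpd_series())
        # frozen from the closed-form OLS on the six printed points
        assert fit.b == pytest.approx(-0.2526215485741795, rel=1e-9)
        assert fit.a == pytest.approx(7.07996466288451, rel=1e-9)

    def test_agrees_with_brute_force_grid(self):
        fit = fit_conc_model(mpd_series())
        a_bf, b_bf = brute_force_conc_fit(
            MPD_CONC, MPD_ETA_LVE,
            np.linspace(fit.a - 0.02, fit.a + 0.02, 81),
            np.linspace(fit.b - 0.02, fit.b + 0.02, 81),
        )
        assert fit.a == pytest.approx(a_bf, abs=1e-3)
        assert fit.b == pytest.approx(b_bf, abs=1e-3)

    def test_constant_series_is_flat(self):
        series = TitrationSeries("x", 0.3, [0.0, 5.0, 10.0], [100.0] * 3)
        assert fit_conc_model(series).b == pytest.approx(0.0, abs=1e-12)

    def test_single_point_insufficient(self):
        fit_conc_model(TitrationSeries("x", 0.3, [0.0, 1.0], [10.0, 5.0]))  # two points OK
        with pytest.raises(InsufficientDataError):
            fit_conc_model(TitrationSeries("x", 0.3, [0.0], [10.0]))


class TestThresholdCrossing:
    def test_closed_form_inversion(self):
        from rheojet import ConcViscFit

        fit = ConcViscFit(a=6.0, b=-0.25, r2=1.0, conc_range=(0.0, 15.0))
        crossing = predict_conc_at_threshold(fit, 1e4)
        assert crossing.conc == pytest.approx(8.0)
        assert not crossing.extrapolated

    def test_intercept_case(self):
        from rheojet import ConcViscFit

        fit = ConcViscFit(a=6.0, b=-0.25, r2=1.0, conc_range=(0.0, 15.0))
        assert predict_conc_at_threshold(fit, 1e6).conc == pytest.approx(0.0)

    def test_above_intercept_flags_extrapolation(self):
        from rheojet import ConcViscFit

        fit = ConcViscFit(a=6.0, b=-0.25, r2=1.0, conc_range=(0.0, 15.0))
        crossing = predict_conc_at_threshold(fit, 1e7)
        assert crossing.conc < 0
        assert crossing.extrapolated

    def test_flat_fit_has_no_crossing(self):
        from rheojet import ConcViscFit

        fit = ConcViscFit(a=6.0, b=0.0, r2=1.0, conc_range=(0.0, 15.0))
        with pytest.raises(ValidationError):
            predict_conc_at_threshold(fit, 1e4)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(3, 8), b=st.floats(-0.5, -0.05), thr=st.floats(2, 7))
    def test_fit_and_inversion_are_mutually_inverse(self, a, b, thr):
        conc = np.linspace(0, 15, 6)
        series = TitrationSeries("x", 0.3, conc, 10 ** (a + b * conc))
        fit = fit_conc_model(series)
        crossing = predict_conc_at_threshold(fit, 10.0**thr)
        assert fit.predict(crossing.conc) == pytest.approx(10.0**thr, rel=1e-6)


class TestBoundaryGeomean:
    def test_stable_metastable_boundary_matches_published_critical_value(self):
        bounds = boundary_geomean(mpd_series(MPD_JET_LABELS))
        boundary = bounds[("stable", "metastable")]
        assert boundary == pytest.approx(math.sqrt(9.8e5 * 5.4e5))  # ~7.3e5
        assert abs(boundary - 7e5) / 7e5 < 0.05

    def test_metastable_unstable_boundary_reported(self):
        # the published 1e4 value is not bracketed cleanly by any label
        # change; the operation reports the geometric-mean estimate as is
        bounds = boundary_geomean(mpd_series(MPD_JET_LABELS))
        assert bounds[("metastable", "unstable")] == pytest.approx(
            math.sqrt(7.5e3 * 1.3e3)
        )

    def test_degenerate_bracket(self):
        series = TitrationSeries(
            "x", 0.3, [0.0, 1.0], [1e5, 1e5],
            labels=[Stability.stable, Stability.metastable],
        )
        assert boundary_geomean(series)[("stable", "metastable")] == pytest.approx(1e5)

    def test_closed_form_bracket(self):
        series = TitrationSeries(
            "x", 0.3, [0.0, 1.0], [1e4, 1e2],
            labels=[Stability.metastable, Stability.unstable],
        )
        assert boundary_geomean(series)[("metastable", "unstable")] == pytest.approx(1e3)

    def test_non_monotone_labels_rejected_with_pairs(self):
        series = TitrationSeries(
            "x", 0.3, [0.0, 1.0, 2.0], [1e5, 1e4, 1e3],
            labels=[Stability.metastable, Stability.stable, Stability.unstable],
        )
        with pytest.raises(LabelingError, match=r"\(0.0, 1.0\)"):
            boundary_geomean(series)

    def test_missing_labels_rejected(self):
        with pytest.raises(LabelingError):
            boundary_geomean(mpd_series())


class TestPegDose:
    def test_published_equivalence_triple(self):
        # three PEG conditions with near-identical viscosity profiles
        assert peg_dose(50.0, 300.0) == peg_dose(10.0, 1500.0) == peg_dose(2.5, 6000.0) == 15000.0

    def test_zero_concentration(self):
        assert peg_dose(0.0, 6000.0) == 0.0

    def test_equivalent_conc_inverse(self):
        assert equivalent_conc(15000.0, 6000.0) == pytest.approx(2.5)

    def test_equal_dose_titrations_overlap(self):
        """Softening that depends only on dose gives overlapping
        viscosity profiles across PEG molecular weights."""
        softening_per_dose = -0.25 / 1500.0  # decades per (% x g/mol)
        cv = 0.02
        series = {}
        for i, (mw, cmax) in enumerate(((300.0, 50.0), (1500.0, 10.0), (6000.0, 2.5))):
            concs = np.linspace(0.0, cmax, 6)[1:]
            series[mw] = gen_titration(
                a=6.756, b=softening_per_dose * mw, concs=concs,
                cfg=SynthConfig(seed=3 + i, noise_cv=cv), mw=mw,
            )
            np.testing.assert_allclose(series[mw].conc * mw, np.linspace(0, 15000, 6)[1:])
        # compare log-viscosity at matched dose across molecular weights
        logs = np.array([np.log10(series[mw].eta) for mw in (300.0, 1500.0, 6000.0)])
        max_gap = np.max(np.ptp(logs, axis=0))
        sigma_log10 = math.sqrt(math.log1p(cv * cv)) / math.log(10)
        assert max_gap < 6 * sigma_log10  # indistinguishable within noise


class TestComposition:
    def test_standard_lcp_vv_to_ww(self):
        comp = Composition(lipid_vv=0.70, water_vv=0.30)
        assert vv_to_ww(comp) == pytest.approx(68.68, abs=0.01)  # printed as "68:32"

    def test_equal_densities_identity(self):
        comp = Composition(lipid_vv=0.70, water_vv=0.30, rho_lipid=1.0)
        assert vv_to_ww(comp) == pytest.approx(70.0)

    def test_fifty_fifty(self):
        comp = Composition(lipid_vv=0.50, water_vv=0.50)
        assert vv_to_ww(comp) == pytest.approx(48.45, abs=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(ww=st.floats(1.0, 99.0))
    def test_ww_vv_round_trip(self, ww):
        comp_vv = ww_to_vv(ww) / 100.0
        comp = Composition(lipid_vv=comp_vv, water_vv=1 - comp_vv)
        assert vv_to_ww(comp) == pytest.approx(ww, rel=1e-12)

    @pytest.mark.parametrize(
        "conc,water,total",
        [(10.0, 0.30, 3.0), (6.0, 0.40, 2.4), (0.0, 0.30, 0.0)],
    )
    def test_aqueous_to_total_percent(self, conc, water, total):
        assert additive_total_percent(conc, water) == pytest.approx(total)

    def test_stock_mixing(self):
        assert mix_dilute(35.0, 1, 1) == pytest.approx(17.5)
        assert mix_dilute(42.0, 1, 0) == 42.0
        # the softened medium's own 3% PEG is halved by the 1:1 stabilizer mix
        assert mix_dilute(3.0, 1, 1) == pytest.approx(1.5)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            Composition(lipid_vv=0.7, water_vv=0.4)
        with pytest.raises(ValidationError):
            mix_dilute(10.0, 0, 0)
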