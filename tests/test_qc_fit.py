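"""Thixotropy QC, power-law fitting, reference-viscosity evaluation,
replicate aggregation and oscillatory summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rheojet import (
    FlowCurve,
    OscSweep,
    SweepKind,
    SynthConfig,
    aggregate_replicates,
    evaluate_viscosity,
    fit_power_law,
    gen_amplitude_sweep,
    gen_flowcurve,
    gen_thixo,
    loss_factor,
    lve_limit,
    thixo_qc,
)
from rheojet.errors import (
    AggregationError,
    InsufficientDataError,
    ProtocolError,
    RangeError,
    ValidationError,
)


def make_trace(eta_pre, eta_post):
    """Flat two-minute holds around a 10 s disturbance."""
    t_pre = np.arange(0, 121, 10.0)
    t_post = t_pre + 140.0
    return dict(
        sample_id="s",
        time=np.concatenate([t_pre, [125.0, 130.0], t_post]),
        shear_rate=np.concatenate(
            [np.full(len(t_pre), 1.0), [300.0, 300.0], np.full(len(t_post), 1.0)]
        ),
        viscosity=np.concatenate(
            [np.full(len(t_pre), eta_pre), [eta_pre / 100] * 2,
             np.full(len(t_post), eta_post)]
        ),
        phase=["pre"] * len(t_pre) + ["disturb"] * 2 + ["post"] * len(t_post),
    )


class TestThixoQC:
    @pytest.mark.parametrize(
        "eta_post,rel,passed",
        [
            (1000.0, 0.0, True),   # full recovery
            (1250.0, 0.25, False),  # 25% change exceeds the 20% gate
            (1150.0, 0.15, True),   # 15% change passes
            (1200.0, 0.20, True),   # exactly at tolerance: strict rule passes
        ],
    )
    def test_twenty_percent_rule(self, eta_post, rel, passed):
        from rheojet import ThixoTrace

        res = thixo_qc(ThixoTrace(**make_trace(1000.0, eta_post)))
        assert res.rel_change == pytest.approx(rel)
        assert res.passed is passed

    def test_window_averages_tail_of_each_hold(self):
        from rheojet import ThixoTrace

        d = make_trace(1000.0, 1000.0)
        # drift early in the pre phase must not affect the 60 s tail mean
        d["viscosity"][0] = 5000.0
        res = thixo_qc(ThixoTrace(**d))
        assert res.eta_before == pytest.approx(1000.0)

    def test_missing_phase_is_protocol_error(self):
        from rheojet import ThixoTrace

        with pytest.raises(ValidationError):
            # datatype invariant already rejects a trace without post
            ThixoTrace(
                "s", time=[0, 10, 20], shear_rate=[1, 1, 300],
                viscosity=[1e3, 1e3, 10], phase=["pre", "pre", "disturb"],
            )

    @settings(derandomize=True, max_examples=50)
    @given(delta=st.floats(0.21, 5.0), extra=st.floats(0.0, 5.0))
    def test_increasing_deviation_never_flips_fail_to_pass(self, delta, extra):
        from rheojet import ThixoTrace

        r1 = thixo_qc(ThixoTrace(**make_trace(1000.0, 1000.0 * (1 + delta))))
        r2 = thixo_qc(ThixoTrace(**make_trace(1000.0, 1000.0 * (1 + delta + extra))))
        assert not r1.passed
        assert not r2.passed
        assert r2.rel_change >= r1.rel_change

    def test_generated_recovery_fraction_maps_to_verdict(self, quiet_cfg):
        assert thixo_qc(gen_thixo(1e3, 1.0, quiet_cfg)).rel_change == 0.0
        assert not thixo_qc(gen_thixo(1e3, 0.7, quiet_cfg)).passed
        assert thixo_qc(gen_thixo(1e3, 0.85, quiet_cfg)).passed


def brute_force_power_law(gamma, eta, eta0_grid, n_grid):
    """Independent oracle: exhaustive grid search minimizing squared
    log10 residuals."""
    best = (None, None, np.inf)
    for log_eta0 in eta0_grid:
        for n in n_grid:
            r = np.log10(eta) - (log_eta0 + n * np.log10(gamma))
            sse = float(r @ r)
            if sse < best[2]:
                best = (log_eta0, n, sse)
    return 10.0 ** best[0], best[1]


class TestPowerLawFit:
    def test_noise_free_model_recovered_exactly(self, exact_curve):
        fit = fit_power_law(exact_curve)
        assert fit.eta0 == pytest.approx(1000.0, rel=1e-10)
        assert fit.n == pytest.approx(-1.0, abs=1e-10)
        assert fit.se_n >= 0 and fit.r2 == pytest.approx(1.0)

    def test_two_point_slope_closed_form(self):
        curve = FlowCurve("lcp", 0, [0.3, 75.4], [5.7e6, 3.6e4])
        fit = fit_power_law(curve)
        expected_n = math.log(3.6e4 / 5.7e6) / math.log(75.4 / 0.3)
        assert fit.n == pytest.approx(expected_n)  # ~ -0.916
        assert fit.n == pytest.approx(-0.916, abs=5e-4)
        assert fit.se_n == 0.0 and fit.se_eta0 == 0.0 and fit.r2 == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        npts = int(rng.integers(3, 6))
        gamma = np.sort(rng.uniform(0.3, 300, npts))
        eta = 10 ** rng.uniform(2, 6, npts)
        fit = fit_power_law(FlowCurve("s", 0, gamma, eta))
        # refine the grid around the OLS solution: agreement within grid step
        e_grid = np.linspace(np.log10(fit.eta0) - 0.05, np.log10(fit.eta0) + 0.05, 101)
        n_grid = np.linspace(fit.n - 0.05, fit.n + 0.05, 101)
        eta0_bf, n_bf = brute_force_power_law(gamma, eta, e_grid, n_grid)
        assert np.log10(fit.eta0) == pytest.approx(np.log10(eta0_bf), abs=1e-3)
        assert fit.n == pytest.approx(n_bf, abs=1e-3)

    def test_recovery_from_published_parameters_under_noise(self):
        """100 seeded 5%-noise curves from eta0=6.2e6 mPa.s, n=-1.06:
        mean fitted n within +/-0.02 and 2-se coverage near 95%."""
        fits = [
            fit_power_law(c)
            for c in gen_flowcurve(
                6.2e6, -1.06, SynthConfig(seed=7, noise_cv=0.05, replicates=100)
            )
        ]
        ns = np.array([f.n for f in fits])
        assert abs(ns.mean() + 1.06) < 0.02
        covered = np.array([abs(f.n + 1.06) <= 2 * f.se_n for f in fits])
        assert 0.85 <= covered.mean() <= 1.0
        # reported se consistent with the empirical replicate scatter
        assert np.mean([f.se_n for f in fits]) == pytest.approx(ns.std(), rel=0.35)

    def test_fit_range_restricts_points(self, exact_curve):
        fit = fit_power_law(exact_curve, fit_range=(1.0, 100.0))
        assert fit.fit_range[0] >= 1.0 and fit.fit_range[1] <= 100.0
        assert fit.n == pytest.approx(-1.0, abs=1e-12)

    def test_single_point_in_range_is_insufficient(self, exact_curve):
        with pytest.raises(InsufficientDataError):
            fit_power_law(exact_curve, fit_range=(0.29, 0.31))


class TestEvaluateViscosity:
    def test_grid_point_identity(self, exact_curve):
        for g, e in zip(exact_curve.shear_rate, exact_curve.viscosity):
            assert evaluate_viscosity(exact_curve, g) == e

    def test_log_log_midpoint(self):
        curve = FlowCurve("s", 0, [1.0, 100.0], [1000.0, 10.0])
        assert evaluate_viscosity(curve, 10.0) == pytest.approx(100.0)

    def test_out_of_span_requires_extrapolate(self, exact_curve):
        with pytest.raises(RangeError):
            evaluate_viscosity(exact_curve, 0.1)
        assert evaluate_viscosity(exact_curve, 0.1, extrapolate=True) == pytest.approx(
            1000.0 / 0.1, rel=1e-9
        )

    def test_fit_object_evaluates_model(self, exact_curve):
        fit = fit_power_law(exact_curve)
        assert evaluate_viscosity(fit, 75.4) == pytest.approx(1000.0 / 75.4, rel=1e-9)


class TestAggregateReplicates:
    def test_constant_input(self):
        rv = aggregate_replicates([100.0, 100.0, 100.0], gamma_ref=0.3)
        assert (rv.eta_mean, rv.eta_sd, rv.n_replicates) == (100.0, 0.0, 3)

    def test_two_value_sd_closed_form(self):
        rv = aggregate_replicates([90.0, 110.0], gamma_ref=0.3)
        assert rv.eta_mean == 100.0
        assert rv.eta_sd == pytest.approx(math.sqrt(200.0))  # ~14.14

    def test_singleton_rule(self):
        rv = aggregate_replicates([5.7e6], gamma_ref=0.3)
        assert (rv.eta_mean, rv.eta_sd, rv.n_replicates) == (5.7e6, 0.0, 1)

    def test_mixed_gamma_ref_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_replicates([1.0, 2.0], gamma_ref=0.3, gamma_refs=[0.3, 75.4])


class TestOscillatory:
    def test_flat_sweep_has_no_limit(self, quiet_cfg):
        sweep = gen_amplitude_sweep(1e4, math.inf, quiet_cfg)
        res = lve_limit(sweep)
        assert not res.limit_found
        assert res.critical_strain == sweep.x[-1]

    @pytest.mark.parametrize("crit", [3.0, 0.5])
    def test_generator_critical_strain_recovered(self, crit, quiet_cfg):
        res = lve_limit(gen_amplitude_sweep(1e4, crit, quiet_cfg))
        assert res.limit_found
        assert res.critical_strain == pytest.approx(crit)

    def test_explicit_ten_percent_drop_at_three_percent_strain(self):
        strain = np.geomspace(0.01, 100, 41)
        gp = np.where(strain < 3.0, 1e4, 0.89e4)
        sweep = OscSweep("s", SweepKind.amplitude, strain,
                         gp, np.full(len(strain), 1e3))
        res = lve_limit(sweep)
        # smallest measured strain at/above the 3% yield point
        assert res.critical_strain == pytest.approx(strain[strain >= 3.0][0])

    def test_frequency_sweep_rejected(self):
        sweep = OscSweep("s", SweepKind.frequency, [1.0, 10.0, 100.0],
                         [1e4, 1e4, 1e4], [1e3, 1e3, 1e3])
        with pytest.raises(ValidationError):
            lve_limit(sweep)

    def test_loss_factor_definition(self):
        sweep = OscSweep("s", SweepKind.frequency, [1.0, 10.0, 100.0],
                         [2.0, 2.0, 1.0], [1.0, 2.0, 1.0])
        np.testing.assert_allclose(loss_factor(sweep), [0.5, 1.0, 1.0])

    def test_elastic_gel_stays_below_unity(self, quiet_cfg):
        # G' an order of magnitude above G'' across frequency: tan(delta) < 1
        omega = np.geomspace(0.1, 100, 15)
        sweep = OscSweep("lcp", SweepKind.frequency, omega,
                         np.full(15, 1e4), np.full(15, 1.2e3))
        assert np.all(loss_factor(sweep) < 1.0)
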