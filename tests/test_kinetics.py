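"""Maintenance-energy kinetic model: closed form, fitting, growth-rate
reconstruction and glucose partitioning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nearzero import (
    BiomassTimeSeries,
    FitResult,
    RetentostatParams,
    chemostat_steady_state_biomass,
    doubling_time,
    fit_biomass_curve,
    glucose_partition,
    predict_biomass,
    residual_glucose_monod,
    specific_growth_rate,
)
from nearzero.kinetics import InsufficientDataError, ParameterError


def _ode_biomass(params: RetentostatParams, t_eval: np.ndarray) -> np.ndarray:
    """Independent oracle: numerically integrate the biomass balance."""

    def rhs(_t, cx):
        return params.Ysx_max * (
            params.D * (params.Cs_in - params.Cs) - params.ms_g * cx[0]
        )

    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        [params.cx0_effective],
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    return sol.y[0]


class TestPredictBiomass:
    def test_initial_condition(self, retentostat_params):
        assert predict_biomass(retentostat_params, 0.0) == pytest.approx(
            retentostat_params.cx0_effective, rel=1e-12
        )

    def test_maintenance_only_fixed_point(self, retentostat_params):
        # at t -> inf all substrate goes to maintenance: Cx = D*(Cs_in-Cs)/ms_g
        expected = retentostat_params.D * retentostat_params.Cs_in / retentostat_params.ms_g
        assert predict_biomass(retentostat_params, 1e6) == pytest.approx(expected, rel=1e-9)

    def test_matches_ode_integration(self, retentostat_params):
        t = np.array([48.0, 216.0, 384.0, 528.0])
        oracle = _ode_biomass(retentostat_params, t)
        closed = predict_biomass(retentostat_params, t)
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_matches_ode_for_random_parameter_sets(self, rng):
        t = np.linspace(1.0, 528.0, 25)
        for _ in range(20):
            params = RetentostatParams(
                D=rng.uniform(0.005, 0.1),
                Cs_in=rng.uniform(10, 80),
                Cs=rng.uniform(0, 0.5),
                ms_mmol=rng.uniform(0.1, 2.0),
                Ysx_max=rng.uniform(0.05, 0.5),
                Cx0=rng.uniform(0.5, 10.0),
            )
            oracle = _ode_biomass(params, t)
            closed = predict_biomass(params, t)
            assert np.allclose(closed, oracle, rtol=1e-6)

    def test_monotone_and_bounded_when_below_ceiling(self, retentostat_params):
        t = np.linspace(0, 2000, 400)
        cx = predict_biomass(retentostat_params, t)
        assert np.all(np.diff(cx) > 0)
        assert np.all(cx <= retentostat_params.cx_inf + 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            RetentostatParams(D=-0.01, Cs_in=50.0)
        with pytest.raises(ParameterError):
            RetentostatParams(D=0.025, Cs_in=50.0, Cs=60.0)


class TestChemostatSteadyState:
    def test_no_maintenance_gives_maximum_yield(self):
        params = RetentostatParams(D=0.1, Cs_in=50.0, ms_mmol=1e-12)
        assert chemostat_steady_state_biomass(params) == pytest.approx(
            50.0 * 0.097, rel=1e-6
        )

    def test_monotone_in_dilution_rate_below_max_yield(self):
        rates = [0.01, 0.05, 0.1, 0.5, 5.0]
        values = [
            chemostat_steady_state_biomass(RetentostatParams(D=d, Cs_in=50.0))
            for d in rates
        ]
        assert np.all(np.diff(values) > 0)
        assert values[-1] < 50.0 * 0.097

    def test_against_mass_balance_oracle(self, retentostat_params):
        # solve the glucose + biomass balances directly:
        # qs = D*(Cs_in - Cs)/Cx  and  qs = D/Ysx_max + ms_g  (Pirt, mu = D)
        qs = retentostat_params.D / retentostat_params.Ysx_max + retentostat_params.ms_g
        cx_oracle = retentostat_params.D * (retentostat_params.Cs_in - retentostat_params.Cs) / qs
        assert chemostat_steady_state_biomass(retentostat_params) == pytest.approx(
            cx_oracle, rel=1e-12
        )


class TestFitBiomassCurve:
    def test_recovers_noiseless_coefficients(self):
        t = np.linspace(0, 528, 23)
        a, b, c = -10.28, -0.00874, 13.87
        series = BiomassTimeSeries(
            t=t, Cx_total=a * np.exp(b * t) + c, viability=np.ones_like(t)
        )
        fit = fit_biomass_curve(series)
        assert fit.converged
        assert fit.A == pytest.approx(a, rel=1e-4)
        assert fit.B == pytest.approx(b, rel=1e-4)
        assert fit.C == pytest.approx(c, rel=1e-4)
        assert fit.sse <= 1e-10

    def test_constant_series_degenerates_to_flat_fit(self):
        t = np.linspace(0, 100, 8)
        c = 5.0
        series = BiomassTimeSeries(
            t=t, Cx_total=np.full_like(t, c), viability=np.ones_like(t)
        )
        fit = fit_biomass_curve(series)
        assert abs(fit.A) <= 1e-6 * c
        assert fit.C == pytest.approx(c, abs=1e-6 * c)

    def test_too_few_points_rejected(self):
        series = BiomassTimeSeries(
            t=np.array([0.0, 1.0, 2.0]),
            Cx_total=np.array([1.0, 2.0, 3.0]),
            viability=np.ones(3),
        )
        with pytest.raises(InsufficientDataError):
            fit_biomass_curve(series)

    def test_monte_carlo_asymptote_recovery(self, retentostat_params):
        # 2% multiplicative noise, n=20 points: median C error < 5% over 100 fits
        t = np.linspace(0, 528, 20)
        truth = predict_biomass(retentostat_params, t)
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(100):
            noisy = truth * rng.lognormal(0.0, 0.02, t.shape)
            fit = fit_biomass_curve(
                BiomassTimeSeries(t=t, Cx_total=noisy, viability=np.ones_like(t))
            )
            errors.append(abs(fit.C - retentostat_params.cx_inf) / retentostat_params.cx_inf)
        assert np.median(errors) < 0.05


class TestSpecificGrowthRate:
    def test_closed_form_identity_at_full_viability(self, retentostat_params):
        # with v = 1 and the ideal fit, mu(t) = k*(Cx_inf - Cx)/Cx
        k = retentostat_params.ms_g * retentostat_params.Ysx_max
        cx_inf = retentostat_params.cx_inf
        cx0 = retentostat_params.cx0_effective
        fit = FitResult(A=cx0 - cx_inf, B=-k, C=cx_inf, sse=0.0, converged=True)
        t = np.array([0.0, 48.0, 216.0, 384.0, 528.0])
        series = BiomassTimeSeries(
            t=t, Cx_total=fit.predict(t), viability=np.ones_like(t)
        )
        profile = specific_growth_rate(fit, series)
        cx = fit.predict(t)
        expected = k * (cx_inf - cx) / cx
        assert np.allclose(profile.mu, expected, rtol=1e-8)

    def test_flat_fit_gives_zero_growth(self):
        fit = FitResult(A=0.0, B=-0.01, C=5.0, sse=0.0, converged=True)
        t = np.linspace(0, 100, 6)
        series = BiomassTimeSeries(
            t=t, Cx_total=np.full_like(t, 5.0), viability=np.full_like(t, 0.9)
        )
        profile = specific_growth_rate(fit, series)
        assert np.all(profile.mu == 0.0)

    def test_halving_viability_doubles_mu(self, retentostat_params):
        k = retentostat_params.ms_g * retentostat_params.Ysx_max
        fit = FitResult(A=-10.0, B=-k, C=14.0, sse=0.0, converged=True)
        t = np.linspace(0, 500, 10)
        cx = fit.predict(t)
        full = specific_growth_rate(
            fit, BiomassTimeSeries(t=t, Cx_total=cx, viability=np.ones_like(t))
        )
        half = specific_growth_rate(
            fit, BiomassTimeSeries(t=t, Cx_total=cx, viability=np.full_like(t, 0.5))
        )
        assert np.allclose(half.mu, 2.0 * full.mu, rtol=1e-12)

    def test_zero_viability_names_the_time(self):
        fit = FitResult(A=-10.0, B=-0.01, C=14.0, sse=0.0, converged=True)
        t = np.array([0.0, 10.0, 20.0, 30.0])
        series = BiomassTimeSeries(
            t=t,
            Cx_total=fit.predict(t),
            viability=np.array([1.0, 1.0, 0.0, 1.0]),
        )
        with pytest.raises(ZeroDivisionError, match="20"):
            specific_growth_rate(fit, series)

    def test_negative_derivative_clipped_and_flagged(self):
        fit = FitResult(A=2.0, B=-0.01, C=5.0, sse=0.0, converged=True)  # decaying
        t = np.linspace(0, 100, 5)
        series = BiomassTimeSeries(
            t=t, Cx_total=fit.predict(t), viability=np.ones_like(t)
        )
        profile = specific_growth_rate(fit, series)
        assert np.all(profile.mu == 0.0)
        assert np.all(profile.clipped)


class TestDoublingTime:
    def test_near_zero_growth_doubling_times(self):
        # mu = 0.005 h-1 corresponds to a ~139 h doubling time,
        # mu = 0.001 h-1 to one beyond 600 h
        assert doubling_time(0.005) == pytest.approx(138.63, abs=0.01)
        assert round(doubling_time(0.005)) == 139
        assert doubling_time(0.001) == pytest.approx(693.15, abs=0.01)
        assert doubling_time(0.001) > 600

    def test_unit_doubling_at_ln2(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0, rel=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-8, max_value=1e3, allow_nan=False))
    def test_product_identity(self, mu):
        assert doubling_time(mu) * mu == pytest.approx(math.log(2), rel=1e-12)

    def test_nonpositive_growth_is_infinite(self):
        assert doubling_time(0.0) == math.inf
        assert doubling_time(-1.0) == math.inf


class TestGlucosePartition:
    def test_zero_growth_is_all_maintenance(self, retentostat_params):
        part = glucose_partition(retentostat_params, Cx_viable=5.0, mu=0.0)
        assert part.frac_maintenance[0] == pytest.approx(1.0)
        assert part.growth_flux[0] == 0.0

    def test_balance_point_is_even_split(self, retentostat_params):
        mu_star = retentostat_params.ms_g * retentostat_params.Ysx_max
        part = glucose_partition(retentostat_params, Cx_viable=5.0, mu=mu_star)
        assert part.frac_maintenance[0] == pytest.approx(0.5, rel=1e-12)
        assert part.frac_growth[0] == pytest.approx(0.5, rel=1e-12)

    def test_chemostat_start_against_hand_arithmetic(self, retentostat_params):
        # at t = 0 the culture is a chemostat at mu = D = 0.025 h-1
        cx0 = retentostat_params.cx0_effective
        maint = retentostat_params.ms_g * cx0
        growth = retentostat_params.D * cx0 / retentostat_params.Ysx_max
        part = glucose_partition(retentostat_params, Cx_viable=cx0, mu=retentostat_params.D)
        assert part.maintenance_flux[0] == pytest.approx(maint, rel=1e-12)
        assert part.growth_flux[0] == pytest.approx(growth, rel=1e-12)
        assert part.frac_maintenance[0] == pytest.approx(
            maint / (maint + growth), rel=1e-12
        )
        # at the chemostat start most glucose still funds growth
        assert part.frac_growth[0] > 0.7

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        st.floats(min_value=1e-3, max_value=20.0, allow_nan=False),
    )
    def test_fractions_sum_to_one(self, mu, cx):
        params = RetentostatParams(D=0.025, Cs_in=50.0)
        part = glucose_partition(params, cx, mu)
        assert part.frac_maintenance[0] + part.frac_growth[0] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_degenerate_zero_flux_flagged(self, retentostat_params):
        part = glucose_partition(retentostat_params, Cx_viable=0.0, mu=0.0)
        assert part.degenerate[0]
        assert np.isnan(part.frac_maintenance[0])


class TestResidualGlucoseMonod:
    def test_half_saturation(self):
        # choose mu so that qs = qs_max/2: then Cs = Ks
        qs_max, ks, ms = 15.0, 0.8, 0.50
        mu = (qs_max / 2 - ms) * 0.097 * 0.18016
        assert residual_glucose_monod(mu, qs_max, ks, ms) == pytest.approx(ks, rel=1e-12)

    def test_positive_floor_at_zero_growth(self):
        qs_max, ks, ms = 15.0, 0.8, 0.50
        floor = ks * ms / (qs_max - ms)
        assert residual_glucose_monod(0.0, qs_max, ks, ms) == pytest.approx(floor)
        assert floor > 0

    def test_monotone_in_growth_rate(self):
        mus = np.linspace(0, 0.2, 30)
        cs = residual_glucose_monod(mus)
        assert np.all(np.diff(cs) > 0)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturat"):
            residual_glucose_monod(10.0, qs_max=15.0)
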