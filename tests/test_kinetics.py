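"""Growth law, rate estimation and directionality classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptube.errors import (
    ConfigError,
    DegenerateDesignError,
    UndefinedCriticalConcentrationError,
)
from peptube.kinetics import (
    CYCLOFF_KINETICS,
    FF_KINETICS,
    EndRateEstimate,
    KineticParameters,
    classify_directionality,
    critical_concentration,
    estimate_terminus_rate,
    fit_growth_law,
    net_growth_rate,
)
from peptube.simulator import BathConfig, FilamentConfig, EndKinetics, simulate
from peptube.synthetic import MeasurementModel, observe

params_strategy = st.builds(
    KineticParameters,
    k_on=st.floats(0.01, 10),
    k_off=st.floats(0, 10),
)


class TestGrowthLaw:
    def test_ff_rates_at_experimental_concentrations(self):
        assert net_growth_rate(3.20, FF_KINETICS) == pytest.approx(3.352)
        assert net_growth_rate(1.60, FF_KINETICS) == pytest.approx(-2.024)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigError):
            net_growth_rate(-1.0, FF_KINETICS)

    @settings(derandomize=True)
    @given(params_strategy)
    def test_rate_vanishes_at_critical_concentration(self, p):
        cs = critical_concentration(p)
        assert net_growth_rate(cs, p) == pytest.approx(0.0, abs=1e-9)

    def test_critical_concentration_values(self):
        from peptube.units import round_half_up

        assert round_half_up(critical_concentration(FF_KINETICS), 1) == 2.2
        assert critical_concentration(CYCLOFF_KINETICS) == pytest.approx(8.0)
        assert critical_concentration(KineticParameters(2.0, 0.0)) == 0.0

    def test_zero_k_on_has_no_critical_concentration(self):
        with pytest.raises(UndefinedCriticalConcentrationError):
            critical_concentration(KineticParameters(0.0, 1.0))

    def test_non_finite_rates_rejected(self):
        with pytest.raises(ConfigError):
            KineticParameters(math.nan, 1.0)


class TestFitGrowthLaw:
    @settings(derandomize=True, max_examples=50)
    @given(
        params_strategy,
        st.lists(
            st.floats(0, 20), min_size=3, max_size=8, unique=True
        ).filter(lambda cs: max(cs) - min(cs) > 0.1),
    )
    def test_noiseless_data_recovers_parameters(self, p, concs):
        c = np.asarray(concs)
        r = p.k_on * c - p.k_off
        fit = fit_growth_law(c, r)
        assert fit.params.k_on == pytest.approx(p.k_on, abs=1e-8, rel=1e-8)
        assert fit.params.k_off == pytest.approx(p.k_off, abs=1e-8, rel=1e-8)
        assert fit.se_k_on == pytest.approx(0.0, abs=1e-6)
        assert critical_concentration(fit.params) == pytest.approx(
            critical_concentration(p), abs=1e-6, rel=1e-6
        )

    def test_two_points_give_exact_line(self):
        fit = fit_growth_law([1.0, 3.0], [-1.0, 3.0])
        assert fit.params.k_on == pytest.approx(2.0)
        assert fit.params.k_off == pytest.approx(3.0)
        assert fit.se_k_on == 0.0 and fit.se_k_off == 0.0
        assert fit.r_squared == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_growth_law([2.0, 2.0, 2.0], [1.0, 1.1, 0.9])

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigError):
            fit_growth_law([1, 2, 3], [1, 2, 3], weights=[1, -1, 1])

    def test_weighted_fit_with_equal_weights_matches_ols(self):
        rng = np.random.default_rng(3)
        c = np.linspace(1, 4, 6)
        r = 2.5 * c - 4.0 + rng.normal(0, 0.3, 6)
        f1 = fit_growth_law(c, r)
        f2 = fit_growth_law(c, r, weights=np.full(6, 2.0))
        assert f1.params.k_on == pytest.approx(f2.params.k_on)
        assert f1.se_k_on == pytest.approx(f2.se_k_on)


class TestEstimateTerminusRate:
    def test_perfect_line(self):
        t = np.arange(10.0)
        est = estimate_terminus_rate(t, 1.5 * t + 2.0, orientation=1)
        assert est.rate == pytest.approx(1.5)
        assert est.se == pytest.approx(0.0, abs=1e-12)
        assert est.n_frames == 10

    def test_constant_positions_zero_rate(self):
        est = estimate_terminus_rate([0, 1, 2], [5.0, 5.0, 5.0])
        assert est.rate == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_orientation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, 8))
        if np.any(np.diff(t) <= 0):
            t = np.arange(8.0)
        x = rng.normal(0, 1, 8)
        plus = estimate_terminus_rate(t, x, orientation=1)
        minus = estimate_terminus_rate(t, x, orientation=-1)
        assert minus.rate == pytest.approx(-plus.rate)
        assert minus.se == pytest.approx(plus.se)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ConfigError):
            estimate_terminus_rate([0.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_frames_rejected(self):
        with pytest.raises(ConfigError):
            estimate_terminus_rate([0.0], [0.0])

    def test_recovers_rate_of_simulated_growing_end(self):
        """The slope of a frame-sampled noisy trace matches the configured
        attachment rate within the combined uncertainty: the OLS SE (frame
        scatter) plus the Poisson path noise dL^2 * lambda / T of the
        attachment process itself."""
        dL, t_max, c, k_on = 0.002, 10.0, 3.2, 3.36
        fil = FilamentConfig(
            end_O=EndKinetics(k_on=k_on, k_off=0.0),
            end_N=EndKinetics(),
            layer_um=dL,
            initial_length_um=5.0,
        )
        trace = simulate(fil, BathConfig("open", c, t_max, seed=11))
        obs = observe(trace, MeasurementModel(frame_interval_min=0.25), seed=12)
        b = obs[obs.terminus == "B"]
        est = estimate_terminus_rate(b.time_min, b.position_um, orientation=1)
        sd_kmc = np.sqrt(dL**2 * (k_on * c / dL) / t_max)
        tol = 3 * np.hypot(est.se, sd_kmc)
        assert est.rate == pytest.approx(k_on * c, abs=tol)


class TestClassifyDirectionality:
    def test_one_active_end_is_unidirectional(self):
        call = classify_directionality(
            EndRateEstimate(5.0, 0.1, 20), EndRateEstimate(0.02, 0.1, 20)
        )
        assert call.label == "unidirectional"
        assert call.active_ends == 1

    def test_two_similar_active_ends_are_bidirectional(self):
        call = classify_directionality(
            EndRateEstimate(2.5, 0.3, 20), EndRateEstimate(2.4, 0.3, 20)
        )
        assert call.label == "bidirectional"
        assert abs(call.z_statistic) < 1.96

    def test_two_silent_ends_are_stalled(self):
        call = classify_directionality(
            EndRateEstimate(0.0, 0.5, 20), EndRateEstimate(0.0, 0.5, 20)
        )
        assert call.label == "stalled"

    def test_swap_symmetry(self):
        a = EndRateEstimate(1.2, 0.2, 20)
        b = EndRateEstimate(-0.1, 0.3, 20)
        c1 = classify_directionality(a, b)
        c2 = classify_directionality(b, a)
        assert c1.label == c2.label
        assert c1.z_statistic == pytest.approx(-c2.z_statistic)

    def test_exact_estimates(self):
        # se = 0 means exact: any non-zero rate is active
        call = classify_directionality(
            EndRateEstimate(0.01, 0.0, 20), EndRateEstimate(0.0, 0.0, 20)
        )
        assert call.label == "unidirectional"

    def test_non_finite_input_is_indeterminate_with_warning(self):
        with pytest.warns(RuntimeWarning):
            call = classify_directionality(
                EndRateEstimate(math.nan, 0.1, 20), EndRateEstimate(1.0, 0.1, 20)
            )
        assert call.label == "indeterminate"

    def test_bad_alpha_rejected(self):
        with pytest.raises(ConfigError):
            classify_directionality(
                EndRateEstimate(1, 0.1, 5), EndRateEstimate(1, 0.1, 5), alpha=1.5
            )

    def test_noise_free_limit_of_asymmetric_filament_is_unidirectional(self):
        """With exact measurements the silent terminus has rate exactly 0 and
        SE 0, so every strongly asymmetric tube classifies unidirectional."""
        from peptube.simulator import ff_filament

        fil = ff_filament(layer_um=0.05, initial_length_um=60.0)
        model = MeasurementModel(sigma_um=0.0)
        for seed in range(10):
            trace = simulate(fil, BathConfig("open", 3.2, 10.0, seed=seed))
            obs = observe(trace, model, seed=seed + 100)
            ests = {}
            for term, orient in (("A", -1), ("B", 1)):
                g = obs[obs.terminus == term]
                ests[term] = estimate_terminus_rate(
                    g.time_min, g.position_um, orientation=orient
                )
            call = classify_directionality(ests["A"], ests["B"])
            assert call.label == "unidirectional"
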