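"""Survival curves, exponential fits, and hazard/probability conversions."""

import math

import numpy as np
import pytest

from forminsim import (
    FilamentRecord,
    build_survival_curve,
    fit_exponential_mle,
    fit_survival_exponential,
    k_step_from_k_time,
    p_off_step_from_rate,
    p_off_time_from_rate,
    rate_from_p_off,
    run_time_from_length,
    step_probabilities,
    subunits_from_um,
    um_from_subunits,
)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "subunits, rate, expected",
        [(1000, 10, 100.0), (0, 10, 0.0), (5300, 18.55, 285.71)],
    )
    def test_run_time(self, subunits, rate, expected):
        assert run_time_from_length(subunits, rate) == pytest.approx(expected, rel=1e-4)

    def test_five_micromolar_anchor_consistency(self):
        # a 5300-subunit run at 18.55 sub/s lasts ~1/0.0035 s^-1
        assert run_time_from_length(5300, 18.55) == pytest.approx(1 / 0.0035, rel=0.01)

    @pytest.mark.parametrize("um, expected", [(1.0, 370.0), (0.0, 0.0), (14.324, 5299.88)])
    def test_subunits_from_um(self, um, expected):
        assert subunits_from_um(um) == pytest.approx(expected)

    def test_um_round_trip(self):
        assert um_from_subunits(subunits_from_um(3.7)) == pytest.approx(3.7)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            run_time_from_length(100, 0)
        with pytest.raises(ValueError):
            subunits_from_um(-1)


class TestProbabilityConversions:
    @pytest.mark.parametrize(
        "k, expected",
        [(0.0, 0.0), (1 / 5300, 1.8866145e-4)],
    )
    def test_p_off_step(self, k, expected):
        assert p_off_step_from_rate(k) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize(
        "k, dt, expected",
        [(0.0035, 0.01, 3.4999388e-5), (0.0, 0.5, 0.0), (math.log(2), 1.0, 0.5)],
    )
    def test_p_off_time(self, k, dt, expected):
        assert p_off_time_from_rate(k, dt) == pytest.approx(expected, rel=1e-6)

    def test_round_trip_is_exact_inverse(self):
        for k_delta in np.geomspace(1e-8, 5.0, 60):
            p = p_off_step_from_rate(k_delta)
            assert rate_from_p_off(p) == pytest.approx(k_delta, rel=1e-9)
            dt = 0.01
            p_t = p_off_time_from_rate(k_delta / dt, dt)
            assert rate_from_p_off(p_t, dt) == pytest.approx(k_delta / dt, rel=1e-9)

    @pytest.mark.parametrize(
        "k_time, rate, expected", [(0.0035, 17.5, 2.0e-4), (0.0, 17.5, 0.0), (0.0039, 15, 2.6e-4)]
    )
    def test_k_step_from_k_time(self, k_time, rate, expected):
        assert k_step_from_k_time(k_time, rate) == pytest.approx(expected)

    def test_bundle(self):
        sp = step_probabilities(0.0035, 17.5, dt=0.01)
        assert sp.k_off_step == pytest.approx(2.0e-4)
        assert sp.p_off_time == pytest.approx(1 - math.exp(-3.5e-5))
        assert sp.p_off_step == pytest.approx(1 - math.exp(-2.0e-4))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            p_off_step_from_rate(-1e-3)
        with pytest.raises(ValueError):
            p_off_time_from_rate(0.1, 0.0)
        with pytest.raises(ValueError):
            rate_from_p_off(1.0)
        with pytest.raises(ValueError):
            k_step_from_k_time(0.1, 0.0)


class TestSurvivalCurve:
    def test_empirical_survivor_function(self):
        curve = build_survival_curve(np.array([1.0, 2.0, 3.0]), domain="time")
        assert curve.values.tolist() == [1.0, 2.0, 3.0]
        assert curve.fractions.tolist() == pytest.approx([1.0, 2 / 3, 1 / 3])

    def test_identical_values_single_step(self):
        curve = build_survival_curve(np.array([5.0, 5.0, 5.0]), domain="length")
        assert curve.values.tolist() == [5.0]
        assert curve.fractions.tolist() == [1.0]

    def test_censored_records_excluded(self):
        records = [
            FilamentRecord(run_length_subunits=100 * i, elongation_rate=10.0) for i in (1, 2, 3)
        ] + [FilamentRecord(run_length_subunits=5.0, elongation_rate=10.0, censored=True)]
        curve = build_survival_curve(records, domain="length")
        assert curve.n_observations == 3

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="2 uncensored"):
            build_survival_curve(np.array([1.0]), domain="time")

    def test_log_survival_of_exponential_sample_is_linear(self):
        rng = np.random.default_rng(11)
        curve = build_survival_curve(rng.exponential(286.0, 5000), domain="time")
        slope = np.polyfit(curve.values, np.log(curve.fractions + 1e-12), 1)[0]
        assert slope == pytest.approx(-1 / 286.0, rel=0.05)


class TestExponentialFit:
    def test_noiseless_model_recovery(self):
        from forminsim.survival import SurvivalCurve

        x = np.linspace(0, 30000, 50)
        curve = SurvivalCurve("length", x, np.exp(-x / 5300), n_observations=50)
        fit = fit_survival_exponential(curve, omit_first=False)
        assert fit.rate == pytest.approx(1 / 5300, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.mean * fit.rate == pytest.approx(1.0)

    def test_free_amplitude_recovered(self):
        from forminsim.survival import SurvivalCurve

        x = np.linspace(0, 30000, 50)
        curve = SurvivalCurve("length", x, 1.3 * np.exp(-x / 5300), n_observations=50)
        fit = fit_survival_exponential(curve, omit_first=False)
        assert fit.amplitude == pytest.approx(1.3, rel=1e-6)
        assert fit.rate == pytest.approx(1 / 5300, rel=1e-6)

    def test_stochastic_recovery_within_ci(self):
        rng = np.random.default_rng(5)
        sample = rng.exponential(1 / 0.0035, 12000)
        fit = fit_survival_exponential(build_survival_curve(sample, domain="time"))
        lo, hi = fit.ci95_rate
        assert lo <= 0.0035 <= hi
        # cross-check against the ML mean of the sample itself
        assert fit.rate == pytest.approx(1 / sample.mean(), rel=0.03)

    def test_ci_coverage_at_paper_minimum_n(self):
        # n = 70 filaments: the reported 95% CI should cover the truth in
        # >= 90% of replicates
        rng = np.random.default_rng(17)
        k = 0.0035
        covered = 0
        for _ in range(200):
            fit = fit_survival_exponential(
                build_survival_curve(rng.exponential(1 / k, 70), domain="time")
            )
            lo, hi = fit.ci95_rate
            covered += lo <= k <= hi
        assert covered >= 180

    def test_length_and_time_domain_fits_consistent(self):
        # constant elongation rate links the domains: k_len * rate = k_time
        rng = np.random.default_rng(23)
        rate = 15.0
        lifetimes = rng.exponential(1 / 0.004, 5000)
        lengths = lifetimes * rate
        fit_t = fit_survival_exponential(build_survival_curve(lifetimes, domain="time"))
        fit_l = fit_survival_exponential(
            build_survival_curve(lengths, domain="length"), omit_first=False
        )
        assert fit_l.rate * rate == pytest.approx(fit_t.rate, rel=0.02)

    def test_omit_first_defaults_by_domain(self):
        rng = np.random.default_rng(2)
        sample = rng.exponential(500.0, 200)
        fit_len = fit_survival_exponential(build_survival_curve(sample, domain="length"))
        fit_time = fit_survival_exponential(build_survival_curve(sample, domain="time"))
        assert fit_len.omitted_first_point
        assert not fit_time.omitted_first_point

    def test_too_few_points_rejected(self):
        from forminsim.survival import SurvivalCurve

        curve = SurvivalCurve("time", np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.6, 0.2]), 3)
        with pytest.raises(ValueError, match="4 points"):
            fit_survival_exponential(curve, omit_first=False)


class TestCensoringAwareMLE:
    def test_unbiased_under_heavy_censoring(self):
        rng = np.random.default_rng(31)
        k = 0.004
        lifetimes = rng.exponential(1 / k, 8000)
        budget = 200.0  # censors ~45% of runs
        records = [
            FilamentRecord(
                run_length_subunits=min(t, budget) * 10.0,
                elongation_rate=10.0,
                run_time=min(t, budget),
                censored=t > budget,
            )
            for t in lifetimes
        ]
        fit = fit_exponential_mle(records, domain="time")
        assert fit.rate == pytest.approx(k, rel=0.05)
        lo, hi = fit.ci95_rate
        assert lo <= k <= hi

    def test_requires_at_least_one_event(self):
        records = [
            FilamentRecord(run_length_subunits=10.0, elongation_rate=1.0, censored=True)
        ]
        with pytest.raises(ValueError, match="event"):
            fit_exponential_mle(records)
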