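"""Mixture fitting, occupancy calling and overlap error estimation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom, norm

from dropread import (
    ChannelComponents,
    DegenerateFitError,
    DropletRecord,
    MixtureFit,
    call_occupancy,
    estimate_error_rates,
    estimate_stochastic_fp,
    fit_mixture,
)

from conftest import calls_from_flags, draw_mixture


def _records(intensities, channel="ch1"):
    return [
        DropletRecord(index=i, diameter_um=10.0, intensity={channel: float(v)})
        for i, v in enumerate(intensities)
    ]


class TestFitMixture:
    def test_parameter_recovery_within_5_percent(self):
        comp = ChannelComponents(2.0, 0.15, 3.2, 0.25)
        x, _ = draw_mixture(comp, weight_occupied=0.3, n=100000, seed=1)
        fit = fit_mixture(x)
        assert fit.converged
        for got, true in [
            (fit.weight_unoccupied, 0.7),
            (fit.weight_occupied, 0.3),
            (fit.unoccupied_loc, 2.0),
            (fit.unoccupied_scale, 0.15),
            (fit.occupied_loc, 3.2),
            (fit.occupied_scale, 0.25),
        ]:
            assert abs(got - true) / true < 0.05

    def test_identical_observations_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_mixture([100.0] * 200)

    def test_single_population_degenerate(self):
        x = 10 ** (2.0 + 0.1 * np.random.default_rng(0).standard_normal(5000))
        with pytest.raises(DegenerateFitError):
            fit_mixture(x)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_loglik_non_decreasing(self, seed):
        comp = ChannelComponents(2.0, 0.2, 2.8, 0.3)
        x, _ = draw_mixture(comp, 0.4, 3000, seed)
        fit = fit_mixture(x)
        path = np.array(fit.log_likelihood_path)
        assert np.all(np.diff(path) >= -1e-9 * np.abs(path[:-1]))

    def test_order_independence(self):
        comp = ChannelComponents(2.0, 0.15, 3.2, 0.25)
        x, _ = draw_mixture(comp, 0.3, 2000, seed=5)
        a = fit_mixture(x)
        b = fit_mixture(x[::-1].copy())
        assert a.unoccupied_loc == pytest.approx(b.unoccupied_loc, abs=1e-9)
        assert a.crossing_log10 == pytest.approx(b.crossing_log10, abs=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fit_mixture([1.0] * 10)  # too few
        with pytest.raises(ValueError):
            fit_mixture([-1.0] * 100)  # non-positive
        with pytest.raises(ValueError):
            fit_mixture(np.ones(100), family="log-t")  # unfittable family


def _symmetric_fit() -> MixtureFit:
    # equal weights and scales: crossing sits exactly midway at 2.5
    return MixtureFit(
        weight_unoccupied=0.5,
        weight_occupied=0.5,
        unoccupied_loc=2.0,
        unoccupied_scale=0.2,
        occupied_loc=3.0,
        occupied_scale=0.2,
        crossing_log10=2.5,
        fp_overlap=float(norm.sf(2.5, 2.0, 0.2)),
        fn_overlap=float(norm.cdf(2.5, 3.0, 0.2)),
        log_likelihood=0.0,
        n_iterations=1,
        converged=True,
    )


class TestCallOccupancy:
    def test_calls_at_component_locations(self):
        fit = _symmetric_fit()
        recs = _records([10**2.0, 10**3.0])
        calls = call_occupancy(recs, {"ch1": fit})
        assert calls[0].occupied["ch1"] is False
        assert calls[1].occupied["ch1"] is True

    def test_tie_at_crossing_point_called_unoccupied(self):
        fit = _symmetric_fit()
        (call,) = call_occupancy(_records([10**2.5]), {"ch1": fit})
        assert call.posterior["ch1"] == 0.5
        assert call.occupied["ch1"] is False

    def test_posteriors_normalized_and_monotone(self):
        fit = _symmetric_fit()
        grid = np.logspace(2.0, 3.5, 200)
        calls = call_occupancy(_records(grid), {"ch1": fit})
        post = np.array([c.posterior["ch1"] for c in calls])
        assert np.all((0 <= post) & (post <= 1))
        assert np.all(np.diff(post) >= -1e-12)  # non-decreasing above unoccupied loc

    def test_threshold_equivalence_with_crossing_point(self):
        fit = _symmetric_fit()
        grid = np.logspace(2.0, 3.2, 500)
        calls = call_occupancy(_records(grid), {"ch1": fit})
        for v, c in zip(grid, calls):
            assert c.occupied["ch1"] == (v > fit.crossing_point)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValueError):
            DropletRecord(index=0, diameter_um=9.0, intensity={"ch1": -2.0})
        fit = _symmetric_fit()
        with pytest.raises(ValueError):
            # record lacking the fitted channel is an invalid record too
            call_occupancy(
                [DropletRecord(index=0, diameter_um=9.0, intensity={"chX": 5.0})],
                {"ch1": fit},
            )

    def test_posterior_calibration_reliability(self):
        """Among fresh draws from a fitted mixture, the fraction truly
        occupied in each posterior bin tracks the bin midpoint."""
        comp = ChannelComponents(2.0, 0.25, 2.9, 0.35)  # deliberate overlap
        x, occ = draw_mixture(comp, 0.35, 100000, seed=7)
        fit = fit_mixture(x)
        fresh_x, fresh_occ = draw_mixture(
            ChannelComponents(
                fit.unoccupied_loc, fit.unoccupied_scale, fit.occupied_loc, fit.occupied_scale
            ),
            fit.weight_occupied,
            100000,
            seed=8,
        )
        post = fit.posterior(fresh_x)
        for lo in np.arange(0.0, 1.0, 0.05):
            sel = (post >= lo) & (post < lo + 0.05)
            if sel.sum() < 200:
                continue
            frac = fresh_occ[sel].mean()
            mid = lo + 0.025
            se = math.sqrt(max(mid * (1 - mid), 1e-4) / sel.sum())
            assert abs(frac - mid) < 0.025 + 4 * se


class TestErrorRates:
    def test_separation_limit_vanishing_overlap(self):
        fit = MixtureFit(
            weight_unoccupied=0.7,
            weight_occupied=0.3,
            unoccupied_loc=2.0,
            unoccupied_scale=0.1,
            occupied_loc=4.0,  # 20 scale units away
            occupied_scale=0.1,
            crossing_log10=3.0,
            fp_overlap=float(norm.sf(3.0, 2.0, 0.1)),
            fn_overlap=float(norm.cdf(3.0, 4.0, 0.1)),
            log_likelihood=0.0,
            n_iterations=1,
            converged=True,
        )
        fp, fn = estimate_error_rates(fit)
        assert fp < 1e-12 and fn < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_closed_form_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        comp = ChannelComponents(2.0, 0.1 + 0.1 * rng.random(), 3.0 + rng.random(), 0.2 + 0.3 * rng.random())
        x, _ = draw_mixture(comp, 0.25 + 0.3 * rng.random(), 20000, seed)
        fit = fit_mixture(x)
        fp, fn = estimate_error_rates(fit)
        fp_quad, _ = quad(
            lambda t: norm.pdf(t, fit.unoccupied_loc, fit.unoccupied_scale),
            fit.crossing_log10,
            fit.unoccupied_loc + 12 * fit.unoccupied_scale,
        )
        fn_quad, _ = quad(
            lambda t: norm.pdf(t, fit.occupied_loc, fit.occupied_scale),
            fit.occupied_loc - 12 * fit.occupied_scale,
            fit.crossing_log10,
        )
        assert abs(fp - fp_quad) < 1e-8
        assert abs(fn - fn_quad) < 1e-8

    def test_overlap_predicts_realized_error_on_fresh_draws(self):
        comp = ChannelComponents(2.0, 0.15, 2.9, 0.3)
        x, _ = draw_mixture(comp, 0.3, 100000, seed=3)
        fit = fit_mixture(x)
        fp, fn = estimate_error_rates(fit)
        fitted = ChannelComponents(
            fit.unoccupied_loc, fit.unoccupied_scale, fit.occupied_loc, fit.occupied_scale
        )
        fresh_x, fresh_occ = draw_mixture(fitted, fit.weight_occupied, 100000, seed=4)
        called = fresh_x > fit.crossing_point
        n_un, n_oc = (~fresh_occ).sum(), fresh_occ.sum()
        emp_fp = called[~fresh_occ].mean()
        emp_fn = (~called[fresh_occ]).mean()
        assert abs(emp_fp - fp) < 3 * math.sqrt(fp * (1 - fp) / n_un)
        assert abs(emp_fn - fn) < 3 * math.sqrt(fn * (1 - fn) / n_oc)

    def test_unconverged_fit_rejected(self):
        import dataclasses

        bad = dataclasses.replace(_symmetric_fit(), converged=False)
        with pytest.raises(ValueError):
            estimate_error_rates(bad)


class TestStochasticFP:
    def test_all_unoccupied_rate_zero(self):
        calls = calls_from_flags([{"ch1": False, "ch2": False}] * 100)
        rates = estimate_stochastic_fp(calls)
        assert rates["ch1"][0] == 0.0 and rates["ch2"][0] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_stochastic_fp([])

    def test_ci_coverage_at_least_99_percent(self):
        """Exact coverage of the 99% interval under the binomial law at the
        nominal contamination rate (p = 0.031, n = 1000)."""
        p, n = 0.031, 1000
        coverage = 0.0
        for k in range(0, n + 1):
            pm = binom.pmf(k, n, p)
            if pm < 1e-12:
                continue
            flags = [{"ch": True}] * k + [{"ch": False}] * (n - k)
            rates = estimate_stochastic_fp(calls_from_flags(flags))
            _, lo, hi = rates["ch"]
            if lo <= p <= hi:
                coverage += pm
        assert coverage >= 0.99
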