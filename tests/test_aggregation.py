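"""Variogram fitting, Eq.-style correlation and block-aggregate uncertainty."""

import numpy as np
import pandas as pd
import pytest

from socsnr.aggregation import (
    GridUnit,
    VariogramModel,
    aggregate_sd,
    aggregate_signal,
    correlation_from_variogram,
    empirical_variogram,
    fit_variogram,
    snr_grid,
    standardized_errors,
)
from socsnr.synthetic_data import simulate_error_field

RHO_ONE = lambda h: np.ones_like(h)  # noqa: E731
RHO_IDENTITY = lambda h: (h == 0).astype(float)  # noqa: E731


def random_unit(rng, n_pix):
    return GridUnit(
        cell_id="c",
        support_km=10.0,
        pixels_km=rng.uniform(0, 10, size=(n_pix, 2)),
        predictions=rng.normal(0, 1, n_pix),
        sds=rng.uniform(0.1, 3.0, n_pix),
    )


class TestStandardizedErrors:
    def test_basic_values(self):
        err, valid = standardized_errors(
            np.array([1.0, 1.0]), np.array([2.0, 2.0]), np.array([1.0, 3.0])
        )
        assert err[0] == 0.0 and err[1] == 1.0 and valid.all()

    def test_zero_sd_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            err, valid = standardized_errors(
                np.array([1.0, 1.0]), np.array([0.0, 1.0]), np.array([2.0, 2.0])
            )
        assert not valid[0] and np.isnan(err[0]) and err[1] == 1.0

    def test_calibrated_errors_have_unit_variance(self):
        rng = np.random.default_rng(0)
        sd = rng.uniform(0.5, 3.0, 4000)
        obs = rng.normal(0, sd)
        err, _ = standardized_errors(np.zeros(4000), sd, obs)
        assert err.var() == pytest.approx(1.0, rel=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            standardized_errors(np.zeros(2), np.ones(2), np.zeros(3))


class TestVariogramModel:
    def test_gamma_zero_at_origin_and_sill_at_infinity(self):
        for family in ("exponential", "spherical"):
            m = VariogramModel(family, 0.3, 0.7, 10.0)
            assert m.gamma(0.0) == 0.0
            assert m.gamma(1e6) == pytest.approx(1.0, abs=1e-6)

    def test_gamma_nondecreasing(self):
        for family in ("exponential", "spherical"):
            m = VariogramModel(family, 0.2, 0.8, 7.0)
            h = np.linspace(0, 50, 400)
            g = np.asarray(m.gamma(h))
            assert (np.diff(g) >= -1e-12).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("exponential", -0.1, 1.0, 5.0)
        with pytest.raises(ValueError):
            VariogramModel("exponential", 0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            VariogramModel("gaussian", 0.1, 1.0, 5.0)


class TestCorrelationFromVariogram:
    def test_rho_at_zero_is_one(self):
        m = VariogramModel("exponential", 0.5, 0.5, 5.0)
        assert correlation_from_variogram(m, 0.0) == 1.0

    def test_rho_vanishes_at_infinity(self):
        for family in ("exponential", "spherical"):
            m = VariogramModel(family, 0.3, 0.7, 5.0)
            assert correlation_from_variogram(m, 1e5) == pytest.approx(0.0, abs=1e-6)

    def test_nugget_discontinuity(self):
        # sill 1, nugget 0.72: rho just above zero separation is 0.28
        m = VariogramModel("exponential", 0.72, 0.28, 10.6)
        assert correlation_from_variogram(m, 1e-9) == pytest.approx(0.28, abs=1e-3)

    def test_monotone_nonincreasing_parameter_sweep(self):
        h = np.linspace(0.001, 100, 500)
        for family in ("exponential", "spherical"):
            for nug in (0.0, 0.3, 0.9):
                for rng_ in (1.0, 10.0, 50.0):
                    m = VariogramModel(family, nug, 1.0 - nug, rng_)
                    rho = np.asarray(correlation_from_variogram(m, h))
                    assert (np.diff(rho) <= 1e-12).all()
                    assert ((rho >= 0) & (rho <= 1)).all()

    def test_zero_sill_rejected(self):
        m = VariogramModel("exponential", 0.0, 0.0, 5.0)
        with pytest.raises(ValueError):
            correlation_from_variogram(m, 1.0)


class TestAggregateSd:
    def test_fully_correlated_limit_is_mean_sd(self):
        unit = GridUnit("c", 1.0, np.array([[0.0, 0.0], [1.0, 0.0]]),
                        np.zeros(2), np.array([2.0, 2.0]))
        assert aggregate_sd(unit, RHO_ONE) == pytest.approx(2.0, rel=1e-14)

    def test_independent_limit_is_rms_over_sqrt_b(self):
        unit = GridUnit("c", 1.0, np.array([[0.0, 0.0], [1.0, 0.0]]),
                        np.zeros(2), np.array([2.0, 2.0]))
        assert aggregate_sd(unit, RHO_IDENTITY) == pytest.approx(
            np.sqrt(2.0), rel=1e-14
        )

    def test_pure_nugget_variogram_matches_identity_rho(self):
        m = VariogramModel("exponential", 1.0, 0.0, 5.0)
        rng = np.random.default_rng(1)
        unit = random_unit(rng, 12)
        assert aggregate_sd(unit, m) == pytest.approx(
            aggregate_sd(unit, RHO_IDENTITY), rel=1e-12
        )

    def test_hand_set_rho_matrix_three_pixels(self):
        # pixels at distances giving rho values we can enumerate
        m = VariogramModel("exponential", 0.0, 1.0, 30.0)
        pix = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        sds = np.array([1.0, 2.0, 3.0])
        unit = GridUnit("c", 5.0, pix, np.zeros(3), sds)
        # brute-force double sum
        total = 0.0
        for i in range(3):
            for j in range(3):
                h = np.linalg.norm(pix[i] - pix[j])
                rho = 1.0 if h == 0 else correlation_from_variogram(m, h)
                total += sds[i] * sds[j] * rho
        assert aggregate_sd(unit, m) == pytest.approx(np.sqrt(total) / 3, rel=1e-12)

    def test_brute_force_oracle_random_cells(self):
        rng = np.random.default_rng(2)
        m = VariogramModel("exponential", 0.4, 0.6, 4.0)
        for _ in range(30):
            unit = random_unit(rng, int(rng.integers(3, 31)))
            B = unit.B
            total = 0.0
            for i in range(B):
                for j in range(B):
                    if i == j:
                        rho = 1.0
                    else:
                        h = float(np.linalg.norm(unit.pixels_km[i] - unit.pixels_km[j]))
                        rho = correlation_from_variogram(m, h)
                    total += unit.sds[i] * unit.sds[j] * rho
            oracle = np.sqrt(total) / B
            assert aggregate_sd(unit, m) == pytest.approx(oracle, rel=1e-10)

    def test_bounds_between_independent_and_correlated_limits(self):
        rng = np.random.default_rng(3)
        m = VariogramModel("exponential", 0.3, 0.7, 3.0)
        for _ in range(20):
            unit = random_unit(rng, 15)
            agg = aggregate_sd(unit, m)
            lower = np.sqrt((unit.sds**2).sum()) / unit.B
            upper = unit.sds.mean()
            assert lower - 1e-12 <= agg <= upper + 1e-12

    def test_monotone_in_pointwise_rho(self):
        rng = np.random.default_rng(4)
        lo = VariogramModel("exponential", 0.5, 0.5, 2.0)
        hi = VariogramModel("exponential", 0.1, 0.9, 20.0)  # pointwise larger rho
        for _ in range(10):
            unit = random_unit(rng, 10)
            assert aggregate_sd(unit, hi) >= aggregate_sd(unit, lo) - 1e-12

    def test_subsampled_estimator_close_to_exact(self):
        rng = np.random.default_rng(5)
        unit = random_unit(rng, 400)
        m = VariogramModel("exponential", 0.3, 0.7, 4.0)
        exact = aggregate_sd(unit, m)
        approx = aggregate_sd(unit, m, max_exact_b=100, n_pair_samples=400_000, seed=6)
        assert approx == pytest.approx(exact, rel=0.02)

    def test_single_pixel_identity(self):
        unit = GridUnit("c", 1.0, np.array([[0.0, 0.0]]), np.array([1.5]),
                        np.array([2.5]))
        m = VariogramModel("exponential", 0.5, 0.5, 5.0)
        assert aggregate_sd(unit, m) == 2.5
        assert aggregate_signal(unit) == 1.5


class TestAggregateSignal:
    def test_constant_and_antisymmetric_fields(self):
        pix = np.array([[0.0, 0.0], [1.0, 0.0]])
        const = GridUnit("c", 1.0, pix, np.array([4.0, 4.0]), np.ones(2))
        anti = GridUnit("c", 1.0, pix, np.array([4.0, -4.0]), np.ones(2))
        assert aggregate_signal(const) == 4.0
        assert aggregate_signal(anti) == 0.0


class TestFitVariogram:
    def test_iid_errors_flagged_pure_nugget(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 100, size=(1500, 2))
        vals = rng.standard_normal(1500)
        m = fit_variogram(coords, vals, max_lag_km=40.0)
        assert m.pure_nugget
        assert m.nugget == pytest.approx(m.sill, rel=0.1)

    def test_round_trip_recovery(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 120, size=(3000, 2))
        true = VariogramModel("exponential", 0.3, 0.7, 12.0)
        e = simulate_error_field(coords, true, seed=8)
        m = fit_variogram(coords, e, max_lag_km=50.0)
        assert m.range_km == pytest.approx(12.0, rel=0.25)
        assert m.nugget / m.sill == pytest.approx(0.3, abs=0.1)

    def test_duplicate_coordinates_in_zero_lag_bin(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        vals = np.array([0.0, 2.0, 1.0])
        emp = empirical_variogram(coords, vals, n_bins=5, max_lag_km=10.0)
        # duplicate pair (0,2): squared diff 4 -> semivariance 2 in bin 0
        assert emp.loc[0, "gamma"] == pytest.approx(2.0)
        assert emp.loc[0, "n_pairs"] == 1

    def test_too_few_bins_rejected(self):
        coords = np.random.default_rng(9).uniform(0, 10, size=(10, 2))
        with pytest.raises(ValueError, match="bins"):
            fit_variogram(coords, np.random.default_rng(9).normal(size=10))


class TestSnrGrid:
    def grid(self, n=40, pixel=1.0, pred=2.0, sd=1.0):
        ax = np.arange(pixel / 2, n * pixel, pixel)
        gx, gy = np.meshgrid(ax, ax)
        return pd.DataFrame(
            {"x_km": gx.ravel(), "y_km": gy.ravel(),
             "prediction": np.full(gx.size, pred), "sd": np.full(gx.size, sd)}
        )

    def test_single_pixel_support_is_identity(self):
        df = self.grid(n=4)
        m = VariogramModel("exponential", 1.0, 0.0, 5.0)
        table, _ = snr_grid(df, m, [1.0], 1.0)
        assert (table["B"] == 1).all()
        assert np.allclose(table["noise"], 1.0)
        assert np.allclose(table["snr"], 2.0)

    def test_uncorrelated_noise_shrinks_as_sqrt_b(self):
        df = self.grid(n=8)
        m = VariogramModel("exponential", 1.0, 0.0, 5.0)  # pure nugget
        table, summary = snr_grid(df, m, [1.0, 2.0, 4.0, 8.0], 1.0)
        med = summary.set_index("support_km")["snr_median"]
        for support in (2.0, 4.0, 8.0):
            b = support**2
            assert med[support] / med[1.0] == pytest.approx(np.sqrt(b), rel=0.01)

    def test_perfectly_correlated_errors_constant_snr(self):
        df = self.grid(n=8)
        table, summary = snr_grid(df, RHO_ONE, [1.0, 4.0, 8.0], 1.0)
        med = summary.set_index("support_km")["snr_median"]
        assert med[4.0] == pytest.approx(med[1.0], rel=1e-10)
        assert med[8.0] == pytest.approx(med[1.0], rel=1e-10)

    def test_support_below_pixel_rejected(self):
        df = self.grid(n=4)
        m = VariogramModel("exponential", 1.0, 0.0, 5.0)
        with pytest.raises(ValueError, match="smaller than pixel"):
            snr_grid(df, m, [0.5], 1.0)
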