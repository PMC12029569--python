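"""Fraction-bound transform and Hill KD fits."""

import numpy as np
import pytest

from g4probe.binding import TitrationSeries, fit_hill, fit_titration, fraction_bound, hill
from g4probe.errors import FitError, InputError
from g4probe.synth import default_titration_grid, gen_titration


def series_from(kd_molar=5e-9, n=1.0, noise=0.0, seed=0, grid=None,
                i_bound=None, **kw):
    df, truth = gen_titration(
        kd_molar, n_hill=n, noise_rel=noise, seed=seed, grid=grid, **kw
    )
    return TitrationSeries(
        df["titrant_conc_molar"].to_numpy(), df["intensity"].to_numpy(),
        i_bound=i_bound,
    ), truth


class TestFractionBound:
    def test_endpoints_and_midpoint(self):
        c = np.concatenate([[0.0], np.geomspace(1e-9, 100e-9, 9)])
        i = np.array([1.0, 1.2, 1.5, 2.0, 2.5, 2.8, 2.95, 2.99, 3.0, 3.0])
        s = TitrationSeries(c, i)
        alpha = fraction_bound(s)
        assert alpha[0] == 0.0
        assert alpha[-1] == pytest.approx(1.0)
        mid = TitrationSeries(c, i, i_bound=3.0)
        assert fraction_bound(mid)[4] == pytest.approx(0.75)

    def test_no_plateau_and_no_i_bound_is_an_error(self):
        c = np.concatenate([[0.0], np.geomspace(1e-9, 100e-9, 9)])
        i = np.linspace(1.0, 3.0, 10)  # still rising at the last point
        with pytest.raises(InputError, match="plateau"):
            fraction_bound(TitrationSeries(c, i))

    def test_first_point_must_be_zero_titrant(self):
        with pytest.raises(InputError):
            TitrationSeries(np.linspace(1e-9, 9e-9, 6), np.ones(6))


class TestFitHill:
    def test_noiseless_recovery_is_exact(self):
        """With the true saturation intensity supplied, a noiseless series
        returns the generator KD to numerical precision."""
        s, truth = series_from(kd_molar=5e-9, n=1.0, i_bound=5.0)
        alpha, fit = fit_titration(s)
        assert fit.converged
        assert fit.kd_molar_equivalent == pytest.approx(5e-9, rel=1e-6)

    def test_plateau_normalization_bias_is_small(self):
        """With i_bound taken from the plateau (the default), the noiseless
        recovery is biased by the unreached asymptote but stays within 15%."""
        s, _ = series_from(kd_molar=5e-9, n=1.0)
        _, fit = fit_titration(s)
        assert fit.kd_molar_equivalent == pytest.approx(5e-9, rel=0.15)

    def test_alpha_is_half_at_kd(self):
        assert hill(np.array([5e-9]), 5e-9, 1.0)[0] == pytest.approx(0.5)
        assert hill(np.array([5e-9]), (5e-9) ** 1.5, 1.5)[0] == pytest.approx(0.5)

    def test_n_fixed_mode(self):
        s, _ = series_from(kd_molar=5e-9, n=1.5, i_bound=5.0)
        _, fit = fit_titration(s, n_fixed=1.5)
        assert fit.n_hill == 1.5
        assert fit.kd_molar_equivalent == pytest.approx(5e-9, rel=1e-6)
        assert fit.kd == pytest.approx((5e-9) ** 1.5, rel=1e-5)

    def test_scale_equivariance(self):
        s, _ = series_from(kd_molar=5e-9, n=1.5, noise=0.01, seed=4)
        alpha = fraction_bound(s)
        fit1 = fit_hill(s.titrant_conc, alpha, n_fixed=1.5)
        fit2 = fit_hill(s.titrant_conc * 1000.0, alpha, n_fixed=1.5)
        assert fit2.kd_molar_equivalent == pytest.approx(
            1000.0 * fit1.kd_molar_equivalent, rel=1e-6
        )

    def test_saturated_series_rejected(self):
        c = np.concatenate([[0.0], np.geomspace(1e-9, 100e-9, 9)])
        alpha = np.concatenate([[0.0], np.full(9, 0.99)])
        alpha[0] = 0.9  # everything near 1: no transition inside range
        with pytest.raises(FitError, match="transition"):
            fit_hill(c, alpha)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_hill(np.array([0, 1, 2, 3, 4.0]), np.linspace(0, 1, 5))

    def test_depletion_flag_set_below_tenth_of_probe(self):
        grid = np.concatenate([[0.0], np.geomspace(0.01e-9, 150e-9, 15)])
        s, _ = series_from(kd_molar=0.5e-9, n=1.0, grid=grid)
        _, fit = fit_titration(s)  # probe at 100 nM
        assert fit.depletion_flag
        # KD = 50 nM has not saturated by 150 nM, so the true i_bound is
        # supplied rather than estimated from a plateau
        s2, _ = series_from(kd_molar=50e-9, n=1.0, i_bound=5.0)
        _, fit2 = fit_titration(s2)
        assert not fit2.depletion_flag

    @pytest.mark.parametrize("kd_nm", [2.16, 4.6, 8.34])
    def test_median_recovery_on_default_grid(self, kd_nm):
        """<= 2% noise, default 0-150 nM grid: median relative KD error < 5%."""
        recovered = []
        for seed in range(60):
            s, _ = series_from(kd_molar=kd_nm * 1e-9, n=1.5, noise=0.02, seed=seed)
            _, fit = fit_titration(s)
            recovered.append(fit.kd_molar_equivalent)
        med = np.median(recovered)
        assert abs(med - kd_nm * 1e-9) / (kd_nm * 1e-9) < 0.05

    def test_picomolar_kd_needs_an_extended_grid(self):
        """A 30 pM KD saturates the default grid (the generator warns); a
        log grid reaching 10 pM makes it recoverable."""
        _, truth = gen_titration(0.03e-9, n_hill=1.5, seed=0)
        assert "grid_warning" in truth
        grid = np.concatenate([[0.0], np.geomspace(0.01e-9, 150e-9, 15)])
        recovered = []
        for seed in range(30):
            s, truth = series_from(
                kd_molar=0.03e-9, n=1.5, noise=0.02, seed=seed, grid=grid
            )
            assert "grid_warning" not in truth
            _, fit = fit_titration(s)
            recovered.append(fit.kd_molar_equivalent)
        med = np.median(recovered)
        assert abs(med - 0.03e-9) / 0.03e-9 < 0.05

    def test_alpha_transform_equals_direct_intensity_fit_with_exact_plateau(self):
        """With exact I_free/I_bound the α route and an intensity-space fit
        give the same KD."""
        from lmfit import Model

        df, _ = gen_titration(5e-9, n_hill=1.0, noise_rel=0.005, seed=9,
                              i_free=1.0, i_bound=5.0)
        c = df["titrant_conc_molar"].to_numpy()
        y = df["intensity"].to_numpy()
        s = TitrationSeries(c, y, i_free=1.0, i_bound=5.0)
        fit_alpha = fit_hill(c, fraction_bound(s), n_fixed=1.0)

        def intensity_model(c, kd, i_free, i_bound):
            return i_free + (i_bound - i_free) * hill(c, kd, 1.0)

        m = Model(intensity_model)
        p = m.make_params(kd=5e-9, i_free=1.0, i_bound=5.0)
        p["kd"].set(min=1e-300)
        p["i_free"].set(vary=False)
        p["i_bound"].set(vary=False)
        out = m.fit(y, p, c=c)
        assert fit_alpha.kd_molar_equivalent == pytest.approx(
            float(out.params["kd"].value), rel=1e-6
        )
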