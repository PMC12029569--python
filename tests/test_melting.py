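"""Folded-fraction conversion, Boltzmann Tm fits, ΔTm and S factor."""

import numpy as np
import pytest

from g4probe.errors import FitError, InputError
from g4probe.melting import (
    MeltingCurve,
    boltzmann,
    delta_tm,
    fit_boltzmann,
    folded_fraction,
    fretmc_summary,
    s_factor,
)
from g4probe.synth import default_melting_grid, gen_melting_plate


def make_curve(tm=60.0, dt=2.0, a1=0.1, a2=1.1, noise=0.0, seed=0, grid=None):
    t = default_melting_grid() if grid is None else grid
    y = boltzmann(t, tm, dt, a1, a2)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, t.shape)
    return MeltingCurve(temperatures=t, signal=y, sample_id="test")


class TestFoldedFraction:
    def test_linear_map(self):
        t = np.linspace(20, 90, 10)
        c = MeltingCurve(t, np.linspace(1, 3, 10))
        ff = folded_fraction(c)
        assert ff.theta[0] == 0.0 and ff.theta[-1] == 1.0
        assert ff.theta[4] == pytest.approx((c.signal[4] - 1) / 2)
        assert (ff.cd_min, ff.cd_max) == (1.0, 3.0)

    def test_extrema_map_to_zero_and_one(self):
        c = make_curve()
        ff = folded_fraction(c)
        assert ff.theta.min() == 0.0 and ff.theta.max() == 1.0

    def test_idempotent(self):
        c = make_curve()
        once = folded_fraction(c)
        twice = folded_fraction(
            MeltingCurve(once.temperatures, once.theta)
        )
        assert np.allclose(once.theta, twice.theta)

    def test_constant_signal_is_no_transition(self):
        c = MeltingCurve(np.linspace(20, 90, 12), np.ones(12))
        with pytest.raises(InputError, match="no transition"):
            folded_fraction(c)

    def test_folded_high_orientation_puts_folded_at_one(self):
        rising = make_curve()  # FAM-style: signal rises on melting
        ff = folded_fraction(rising, orientation="folded_high")
        assert ff.theta[0] > 0.9 and ff.theta[-1] < 0.1


class TestFitBoltzmann:
    def test_noiseless_recovery_is_exact(self):
        fit = fit_boltzmann(make_curve(tm=60.0, dt=2.0))
        assert fit.converged
        assert fit.tm == pytest.approx(60.0, abs=1e-6)
        assert fit.slope == pytest.approx(2.0, abs=1e-6)

    def test_midpoint_at_tm_for_normalized_curve(self):
        ff = folded_fraction(make_curve(tm=57.0, dt=3.0))
        fit = fit_boltzmann(ff)
        mid = boltzmann(fit.tm, fit.tm, fit.slope,
                        fit.lower_asymptote, fit.upper_asymptote)
        assert mid == pytest.approx(
            (fit.lower_asymptote + fit.upper_asymptote) / 2
        )
        assert np.interp(fit.tm, ff.temperatures, ff.theta) == pytest.approx(
            0.5, abs=0.01
        )

    def test_orientation_invariance(self):
        rising = make_curve(tm=55.0, dt=2.5, a1=0.1, a2=1.1)
        falling = make_curve(tm=55.0, dt=2.5, a1=1.1, a2=0.1)
        assert fit_boltzmann(rising).tm == pytest.approx(
            fit_boltzmann(falling).tm, abs=1e-6
        )

    def test_median_recovery_under_noise(self):
        """Known Tm in [40, 80] °C, 2% amplitude noise: median error < 0.3 °C."""
        errors = []
        for seed, tm in enumerate(np.linspace(40, 80, 30)):
            fit = fit_boltzmann(make_curve(tm=tm, noise=0.02, seed=seed))
            assert fit.converged
            errors.append(abs(fit.tm - tm))
        assert np.median(errors) < 0.3

    def test_tm_outside_range_flagged(self):
        grid = np.arange(20.0, 50.0, 0.5)
        fit = fit_boltzmann(make_curve(tm=49.0, dt=3.0, grid=grid))
        assert fit.tm_in_range  # inflection inside
        # truncated far below the transition: fit may run but flags range
        grid2 = np.arange(20.0, 40.0, 0.5)
        fit2 = fit_boltzmann(make_curve(tm=60.0, dt=3.0, grid=grid2))
        assert not (fit2.converged and fit2.tm_in_range)


class TestDeltaTmAndSFactor:
    def test_delta_tm_arithmetic_and_antisymmetry(self):
        a = fit_boltzmann(make_curve(tm=66.0))
        b = fit_boltzmann(make_curve(tm=60.0))
        assert delta_tm(a, b) == pytest.approx(6.0, abs=1e-6)
        assert delta_tm(a, b) == pytest.approx(-delta_tm(b, a))
        assert delta_tm(a, a) == 0.0

    def test_parent_to_capped_derivative_shift(self):
        parent = fit_boltzmann(make_curve(tm=60.0))
        derived = fit_boltzmann(make_curve(tm=43.4))
        assert delta_tm(derived, parent) == pytest.approx(-16.6, abs=1e-6)

    def test_unconverged_input_rejected(self):
        import dataclasses

        good = fit_boltzmann(make_curve())
        bad = dataclasses.replace(good, converged=False)
        with pytest.raises(FitError):
            delta_tm(good, bad)

    @pytest.mark.parametrize(
        "tm_comp,expected_s",
        [(54.0, 1.0), (44.0, 0.0), (49.0, 0.5)],
    )
    def test_s_factor_endpoints_and_ratio(self, tm_comp, expected_s):
        res = s_factor(44.0, 54.0, tm_comp, competitor="X")
        assert res.s_factor == pytest.approx(expected_s)
        assert res.delta_tm_reference == pytest.approx(10.0)

    def test_absent_ligand_stabilization_is_an_error(self):
        with pytest.raises(FitError, match="stabilization absent"):
            s_factor(44.0, 44.2, 44.1)

    def test_s_factor_invariant_to_affine_signal_rescaling(self):
        tms = {"F21T": 44.0, "F21T+PhenDC3": 61.0, "AT14": 47.0}
        curves, _ = gen_melting_plate(tms, noise_sd=0.005, seed=11)

        def summarize(scale, offset):
            fits = {}
            for c in curves:
                scaled = MeltingCurve(
                    c.temperatures, scale * c.signal + offset,
                    sample_id=c.sample_id,
                )
                cond = c.sample_id.split("|")[0]
                fits.setdefault(cond, []).append(fit_boltzmann(scaled))
            return fretmc_summary(fits)["s_factor"].iloc[0]

        assert summarize(1.0, 0.0) == pytest.approx(
            summarize(37.5, 120.0), abs=1e-6
        )

    def test_fretmc_summary_requires_reference_conditions(self):
        fits = {"AT14": [fit_boltzmann(make_curve())]}
        with pytest.raises(InputError, match="missing required condition"):
            fretmc_summary(fits)


def test_curve_validation():
    with pytest.raises(InputError):
        MeltingCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0]))  # < 10 pts
    t = np.linspace(20, 90, 12)
    with pytest.raises(InputError):
        MeltingCurve(t[::-1], np.ones(12))
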