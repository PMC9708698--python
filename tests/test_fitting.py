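"""Recovery fits, exchange fits, leakage correction, MC error propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iminoex.core_model import RelaxationRates, intensity_ratio
from iminoex.fitting import (
    FitFailure,
    IntensitySeries,
    average_intensity_fit,
    average_kex_over_residues,
    control_exchange_ratio,
    correct_leakage,
    estimate_noise_sigma,
    fit_exchange_rate,
    fit_inversion_recovery,
    fit_saturation_recovery,
    monte_carlo_kex,
)
from tests.conftest import FIVE_DELAYS


def make_transfer(kex, rates, delays=FIVE_DELAYS, i0=1.0, noise_sd=0.0, **kw):
    return IntensitySeries(
        residue=kw.pop("residue", "X"),
        condition=kw.pop("condition", "in_vitro"),
        delays=delays,
        intensities=i0 * intensity_ratio(delays, kex, rates),
        noise_sd=noise_sd,
        **kw,
    )


class TestNoiseSigma:
    def test_constant_trace_zero(self):
        assert estimate_noise_sigma(np.full(100, 3.7), slice(0, 50)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(7)
        trace = rng.normal(0.0, 1.0, 10000)
        assert estimate_noise_sigma(trace, slice(0, 10000)) == pytest.approx(1.0, abs=0.03)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.arange(10.0), slice(3, 4))


class TestRecoveryFits:
    recovery_delays = np.array([0.01, 0.05, 0.1, 0.3, 0.6, 1.2, 2.4, 4.8])

    @pytest.mark.parametrize("r1", [2.0, 0.4])
    def test_inversion_recovery_round_trip(self, r1):
        y = 1.3 * (1.0 - 2.0 * np.exp(-r1 * self.recovery_delays))
        s = IntensitySeries("G4", "c", self.recovery_delays, y)
        fit, err = fit_inversion_recovery(s)
        assert fit == pytest.approx(r1, rel=1e-6)
        assert err < 1e-4

    def test_saturation_recovery_round_trip(self):
        y = 0.8 * (1.0 - np.exp(-0.35 * self.recovery_delays))
        s = IntensitySeries("water", "c", self.recovery_delays, y)
        fit, _ = fit_saturation_recovery(s)
        assert fit == pytest.approx(0.35, rel=1e-6)

    def test_saturation_model_is_zero_at_t0(self):
        # under the saturation model the t=0 point carries no signal
        y = 1.0 - np.exp(-0.35 * np.array([0.0, 0.5, 1.0, 2.0]))
        assert y[0] == 0.0
        s = IntensitySeries("water", "c", np.array([0.0, 0.5, 1.0, 2.0]), y)
        fit, _ = fit_saturation_recovery(s)
        assert fit == pytest.approx(0.35, rel=1e-6)

    def test_flat_series_is_a_fit_failure(self):
        s = IntensitySeries("x", "c", self.recovery_delays, np.zeros(8))
        with pytest.raises(FitFailure):
            fit_inversion_recovery(s)

    def test_too_few_delays_rejected(self):
        s = IntensitySeries("x", "c", np.array([0.1]), np.array([0.5]))
        with pytest.raises(ValueError):
            fit_saturation_recovery(s)


class TestExchangeFit:
    @pytest.mark.parametrize("kex", [34.5, 0.9])
    def test_noiseless_round_trip_table_rates(self, kex, rates):
        # fast (U14 300 mM) and slow (G4 10 mM) regimes at the five delays
        res = fit_exchange_rate(make_transfer(kex, rates), rates)
        assert res.kex_point == pytest.approx(kex, rel=1e-4)

    def test_flat_ratios_give_zero_rate(self, rates):
        s = IntensitySeries("x", "c", FIVE_DELAYS, np.ones(5))
        assert fit_exchange_rate(s, rates).kex_point == 0.0

    def test_degenerate_relaxation_rates_use_limit_branch(self):
        r = RelaxationRates(R1a=1.0, R1w=1.0)
        s = make_transfer(5.0, r)
        assert fit_exchange_rate(s, r).kex_point == pytest.approx(5.0, rel=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(1e-6, 1e6), kex=st.floats(0.1, 40.0))
    def test_invariant_to_intensity_scaling(self, scale, kex):
        rates = RelaxationRates(R1a=2.0, R1w=0.4)
        base = fit_exchange_rate(make_transfer(kex, rates), rates).kex_point
        scaled = fit_exchange_rate(make_transfer(kex, rates, i0=scale), rates).kex_point
        assert scaled == pytest.approx(base, rel=1e-8)


class TestLeakageCorrection:
    scrambled = np.array([1, 2, 4, 3, 0])  # delays stored ascending, recorded scrambled

    def test_printed_multiplier_set(self, rates):
        s = make_transfer(5.0, rates, acquisition_order=self.scrambled)
        out = correct_leakage(s, 0.16)
        mult = out.intensities / s.intensities
        expected = 1.0 / (1.0 - 0.16 * self.scrambled / 4.0)
        assert np.allclose(mult, expected)
        assert set(np.round(1.0 / mult, 10)) == {1.0, 0.96, 0.92, 0.88, 0.84}

    def test_zero_loss_is_identity(self, rates):
        s = make_transfer(5.0, rates, acquisition_order=self.scrambled)
        assert np.array_equal(correct_leakage(s, 0.0).intensities, s.intensities)

    def test_correction_follows_acquisition_not_delay_order(self, rates):
        s = make_transfer(5.0, rates, acquisition_order=self.scrambled)
        out = correct_leakage(s, 0.16)
        # the longest delay (0.1 s) was recorded first -> untouched
        i_longest = np.argmax(s.delays)
        assert out.intensities[i_longest] == s.intensities[i_longest]
        # the shortest delay (0.001 s) was recorded second -> 1/0.96
        i_shortest = np.argmin(s.delays)
        assert out.intensities[i_shortest] == pytest.approx(
            s.intensities[i_shortest] / 0.96
        )

    def test_total_loss_rejected(self, rates):
        s = make_transfer(5.0, rates, acquisition_order=self.scrambled)
        with pytest.raises(ValueError):
            correct_leakage(s, 1.0)

    def test_decayed_then_corrected_recovers_undecayed_rate(self, rates):
        ideal = make_transfer(12.5, rates, acquisition_order=self.scrambled)
        decay = 1.0 - 0.16 * self.scrambled / 4.0
        decayed = IntensitySeries(
            "x", "c", ideal.delays, ideal.intensities * decay,
            acquisition_order=self.scrambled,
        )
        corrected = correct_leakage(decayed, 0.16)
        res = fit_exchange_rate(corrected, rates)
        assert res.kex_point == pytest.approx(12.5, rel=1e-10)


class TestMonteCarlo:
    def test_zero_noise_means_point_estimate(self, rates):
        res = monte_carlo_kex(make_transfer(6.7, rates), rates, seed=1)
        assert res.kex_sd == 0.0
        assert res.kex_mean == res.kex_point

    def test_fixed_seed_bit_identical(self, rates):
        s = make_transfer(6.7, rates, noise_sd=0.02)
        a = monte_carlo_kex(s, rates, seed=42)
        b = monte_carlo_kex(s, rates, seed=42)
        assert (a.kex_mean, a.kex_sd) == (b.kex_mean, b.kex_sd)

    def test_mean_tracks_truth_within_error(self, rates):
        rng = np.random.default_rng(5)
        s = make_transfer(6.7, rates, noise_sd=0.0)
        noisy = IntensitySeries(
            "x", "c", s.delays,
            s.intensities + rng.normal(0, 0.01, len(s)),
            noise_sd=0.01,
        )
        res = monte_carlo_kex(noisy, rates, n_mc=50, seed=6)
        assert res.kex_mean == pytest.approx(6.7, abs=3 * max(res.kex_sd, 1e-6))
        assert res.n_mc == 50 and not res.flagged


class TestParameterRecovery:
    def test_bias_and_coverage_over_kex_range(self):
        # 200 seeded series across the study's rate range at realistic noise:
        # median |relative bias| < 5%, ~68% 1-sd coverage (+-10 points)
        rates = RelaxationRates(R1a=2.0, R1w=0.4)
        rng = np.random.default_rng(2024)
        kex_grid = np.linspace(0.5, 40.0, 200)
        bias, covered = [], 0
        for kex in kex_grid:
            ideal = intensity_ratio(FIVE_DELAYS, kex, rates)
            noisy = IntensitySeries(
                "x", "c", FIVE_DELAYS,
                ideal + rng.normal(0, 0.01, 5), noise_sd=0.01,
            )
            res = monte_carlo_kex(noisy, rates, n_mc=50, seed=rng)
            bias.append(abs(res.kex_point - kex) / kex)
            if abs(res.kex_mean - kex) <= res.kex_sd:
                covered += 1
        assert np.median(bias) < 0.05
        assert 0.58 <= covered / len(kex_grid) <= 0.78


class TestAveraging:
    def test_identical_series_match_individual_fit(self, rates):
        s = make_transfer(6.7, rates)
        combined = average_intensity_fit([s, s, s], rates)
        single = fit_exchange_rate(s, rates)
        assert combined.kex_point == pytest.approx(single.kex_point, rel=1e-10)

    def test_average_of_two_rates_lies_between(self, rates):
        s1 = make_transfer(1.0, rates, residue="a")
        s9 = make_transfer(9.0, rates, residue="b")
        res = average_intensity_fit([s1, s9], rates)
        assert 1.0 < res.kex_point < 9.0

    def test_empty_list_rejected(self, rates):
        with pytest.raises(ValueError):
            average_intensity_fit([], rates)

    def test_mismatched_delay_grids_rejected(self, rates):
        s1 = make_transfer(2.0, rates)
        s2 = make_transfer(2.0, rates, delays=FIVE_DELAYS * 2.0)
        with pytest.raises(ValueError):
            average_intensity_fit([s1, s2], rates)

    def test_residue_average_forced_arithmetic(self):
        from iminoex.fitting import KineticResult

        results = [
            KineticResult("a", "c", k, k, 0.1) for k in (2.0, 4.0, 6.0)
        ]
        mean, sd = average_kex_over_residues(results)
        assert (mean, sd) == (pytest.approx(4.0), pytest.approx(2.0))
        # order invariance
        mean_r, sd_r = average_kex_over_residues(results[::-1])
        assert (mean_r, sd_r) == (mean, sd)
        single = average_kex_over_residues(results[:1])
        assert single == (2.0, 0.0)


class TestControlRatio:
    def test_equal_intensities_give_unity(self):
        assert control_exchange_ratio(2.0, 2.0) == (1.0, 0.0)

    def test_transfer_at_100ms_matches_model(self):
        # on-resonance intensity generated by the transfer model itself
        r = RelaxationRates(R1a=3.0, R1w=0.4)
        i0 = 5.0
        i_on = i0 * intensity_ratio(0.1, 5.0, r)
        ratio, _ = control_exchange_ratio(i_on, i0)
        assert ratio == pytest.approx(0.154, abs=5e-4)

    def test_quotient_rule_propagation(self):
        ratio, sd = control_exchange_ratio(4.0, 8.0, on_sd=0.4, off_sd=0.8)
        expected = 0.5 * np.sqrt((0.4 / 4.0) ** 2 + (0.8 / 8.0) ** 2)
        assert (ratio, sd) == (pytest.approx(0.5), pytest.approx(expected))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            control_exchange_ratio(1.0, 0.0)
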