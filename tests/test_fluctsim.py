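"""Brownian-dynamics trace generator and curve-noise layer."""

import numpy as np
import pytest
from scipy.integrate import quad

from wntflux.correlate import multitau_correlate
from wntflux.fluctsim import (
    DiffusingSpecies, add_curve_noise, analytic_correlation, simulate_trace,
)
from wntflux.models import FcsModel


def gaussian_axis_integral(width, box, power=1):
    """Integral of exp(-2 p x^2 / width^2) over one box axis."""
    return quad(lambda x: np.exp(-2.0 * power * x * x / width ** 2),
                -box / 2, box / 2)[0]


def box_mean_weight(volume, box):
    """Mean detection weight of a uniformly distributed particle in the box."""
    return (gaussian_axis_integral(volume.w0, box) ** 2
            * gaussian_axis_integral(volume.z0, box) / box ** 3)


class TestSimulateTrace:
    def test_no_emitters_all_zero(self, volume):
        tr = simulate_trace([], volume, bin_width=1e-4, duration=0.05, seed=0,
                            channels=["g", "r"])
        assert all(np.all(c == 0) for c in tr.counts.values())

    def test_zero_brightness_channel_stays_dark(self, volume):
        sp = DiffusingSpecies(D=10.0, mean_count=50.0, brightness={"g": 10.0, "r": 0.0})
        tr = simulate_trace([sp], volume, bin_width=1e-4, duration=0.2, seed=1)
        assert tr.counts["g"].sum() > 0
        assert tr.counts["r"].sum() == 0

    def test_seed_determinism(self, volume):
        sp = DiffusingSpecies(D=30.0, mean_count=80.0, brightness={"g": 20.0},
                              triplet_fraction=0.1)
        a = simulate_trace([sp], volume, bin_width=5e-5, duration=0.3, seed=42)
        b = simulate_trace([sp], volume, bin_width=5e-5, duration=0.3, seed=42)
        assert np.array_equal(a.counts["g"], b.counts["g"])

    def test_mean_rate_matches_detection_integral(self, volume):
        # empirical mean count rate against the closed-form spatial average
        # of the Gaussian detection profile over the periodic box
        box = 12 * volume.w0
        n_eff = 5.0
        mean_count = n_eff * box ** 3 / volume.v_eff
        sp = DiffusingSpecies(D=50.0, mean_count=mean_count, brightness={"g": 30.0})
        rates = []
        for seed in range(4):
            tr = simulate_trace([sp], volume, box=box, bin_width=2e-5,
                                duration=2.0, seed=seed)
            rates.append(tr.mean_rate_khz()["g"])
        expected = 30.0 * round(mean_count) * box_mean_weight(volume, box)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - expected) < 3.0 * max(se, 0.15)

    def test_amplitude_and_decay_time_laws(self, volume):
        # G(first lag) - 1 ~ 1/N_eff (after finite-lag decay correction) and
        # the empirical half-decay lag ~ tau_D = w0^2/(4D) within 15%
        box = 12 * volume.w0
        n_eff = 5.0
        D = 20.0
        tau_d = volume.w0 ** 2 / (4 * D)
        sp = DiffusingSpecies(D=D, mean_count=n_eff * box ** 3 / volume.v_eff,
                              brightness={"g": 40.0})
        amps, halves = [], []
        for seed in range(3):
            tr = simulate_trace([sp], volume, box=box, bin_width=5e-5,
                                duration=6.0, seed=seed + 10)
            curve = multitau_correlate(tr, "g", "g")
            model = FcsModel(N=n_eff, F=(1.0,), tau=(tau_d,),
                             structure_param=volume.structure_param)
            # divide out the model decay factor to extrapolate to zero lag
            g_decay = (model(curve.lags[:2]) - 1.0) * n_eff
            amps.append(np.mean((curve.G[:2] - 1.0) / g_decay))
            amp0 = curve.G[0] - 1.0
            below = np.nonzero(curve.G - 1.0 <= amp0 / 2)[0]
            halves.append(curve.lags[below[0]])
        amp_mean = np.mean(amps)
        se = np.std(amps, ddof=1) / np.sqrt(len(amps))
        # box truncation raises the effective amplitude by a few percent
        assert abs(amp_mean - 1.0 / n_eff) < 3 * max(se, 0.012 / n_eff)
        assert np.median(halves) == pytest.approx(tau_d, rel=0.30)

    def test_colabeled_species_cross_correlate(self, volume):
        box = 12 * volume.w0
        mean_count = 5.0 * box ** 3 / volume.v_eff
        pair = [
            DiffusingSpecies(D=20.0, mean_count=mean_count,
                             brightness={"g": 20.0, "r": 0.0}, colabel_id="c"),
            DiffusingSpecies(D=20.0, mean_count=mean_count,
                             brightness={"g": 0.0, "r": 20.0}, colabel_id="c"),
        ]
        tr = simulate_trace(pair, volume, bin_width=5e-5, duration=4.0, seed=7)
        amp_g = multitau_correlate(tr, "g", "g").G[0] - 1
        amp_r = multitau_correlate(tr, "r", "r").G[0] - 1
        amp_c = multitau_correlate(tr, "g", "r").G[0] - 1
        assert amp_c == pytest.approx(amp_g, rel=0.10)
        assert amp_c == pytest.approx(amp_r, rel=0.10)

    def test_invalid_arguments(self, volume):
        sp = DiffusingSpecies(D=1.0, mean_count=1.0, brightness={"g": 1.0})
        with pytest.raises(ValueError):
            simulate_trace([sp], volume, bin_width=-1e-4, duration=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_trace([sp], volume, duration=-1.0, seed=0)
        with pytest.raises(ValueError, match="10 w0"):
            simulate_trace([sp], volume, box=volume.w0, duration=1.0, seed=0)

    def test_resolution_guard_warns(self, volume):
        sp = DiffusingSpecies(D=100.0, mean_count=5.0, brightness={"g": 5.0})
        with pytest.warns(UserWarning, match="guard"):
            simulate_trace([sp], volume, bin_width=1e-3, duration=0.1, seed=0)


class TestCurveNoise:
    def test_zero_sigma_identity(self, lag_grid):
        model = FcsModel(N=5, F=(1.0,), tau=(1e-3,))
        curve = analytic_correlation(model, lag_grid)
        noisy = add_curve_noise(curve, 0.0, seed=1)
        assert np.array_equal(noisy.G, curve.G)

    def test_seed_determinism(self, lag_grid):
        model = FcsModel(N=5, F=(1.0,), tau=(1e-3,))
        curve = analytic_correlation(model, lag_grid)
        a = add_curve_noise(curve, 0.01, seed=3)
        b = add_curve_noise(curve, 0.01, seed=3)
        assert np.array_equal(a.G, b.G)

    def test_monte_carlo_sd_converges_to_sigma(self):
        model = FcsModel(N=5, F=(1.0,), tau=(1e-3,))
        lags = np.geomspace(1e-5, 1e-1, 10)
        curve = analytic_correlation(model, lags)
        sigma = 0.02
        reps = np.array([add_curve_noise(curve, sigma, seed=s).G for s in range(1000)])
        sd = reps.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - sigma) < 0.05 * sigma * 3)

    def test_callable_sigma_model(self, lag_grid):
        model = FcsModel(N=5, F=(1.0,), tau=(1e-3,))
        curve = analytic_correlation(model, lag_grid)
        noisy = add_curve_noise(curve, lambda lags: 0.01 / np.sqrt(lags / lags[0]),
                                seed=0)
        assert noisy.sigma[0] > noisy.sigma[-1]
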