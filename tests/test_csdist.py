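"""c(s) inversion, standard-condition transforms and peak quantification."""

import numpy as np
import pytest
from scipy.optimize import brentq

from wntflux.csdist import (
    CsDistribution, apparent_mass, diffusion_from_s_ffr, fit_cs,
    quantify_peaks, s20w,
)
from wntflux.sedsim import (
    SedSpecies, Solvent, WATER_20C, simulate_sv, svedberg_diffusion,
)


def implied_ffr(s, M, vbar=0.73, solvent=WATER_20C):
    """Frictional ratio consistent with a species' Svedberg diffusion."""
    target = svedberg_diffusion(s, M, vbar, solvent)
    return brentq(lambda f: diffusion_from_s_ffr(s, f, solvent, vbar) - target,
                  1.0, 4.0)


class TestStandardConditions:
    def test_water_identity(self):
        assert s20w(5.0, WATER_20C) == pytest.approx(5.0)

    def test_viscosity_scaling(self):
        doubled = Solvent(density=WATER_20C.density,
                          viscosity=2 * WATER_20C.viscosity)
        assert s20w(3.0, doubled) == pytest.approx(6.0)

    def test_culture_medium_hand_formula(self):
        med = Solvent(density=1.005, viscosity=1.05)
        vbar = 0.73
        expected = 5.0 * (1.05 / 1.002) * \
            ((1 - vbar * 0.99823) / (1 - vbar * 1.005))
        assert s20w(5.0, med, vbar) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_buoyancy_rejected(self):
        with pytest.raises(ValueError):
            s20w(5.0, Solvent(density=1.5, viscosity=1.0), vbar=0.73)


class TestApparentMass:
    def test_sphere_inverts_svedberg_exactly(self):
        # a compact sphere (f/f0 = 1) closes the Svedberg loop
        M = 30.0
        s_star = brentq(
            lambda s: svedberg_diffusion(s, M) - diffusion_from_s_ffr(s, 1.0),
            0.5, 10.0)
        assert apparent_mass(s_star, 1.0) == pytest.approx(M, rel=1e-9)

    def test_monotone_in_ffr(self):
        masses = [apparent_mass(7.0, f) for f in np.linspace(1.0, 2.0, 11)]
        assert np.all(np.diff(masses) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            apparent_mass(-1.0, 1.2)
        with pytest.raises(ValueError):
            apparent_mass(5.0, 0.8)


def gaussian_dist(centers, weights, sigma=0.3, ffr=1.3):
    s = np.arange(1.0, 15.0 + 0.025, 0.05)
    c = np.zeros_like(s)
    for mu, w in zip(centers, weights):
        c += w * np.exp(-0.5 * ((s - mu) / sigma) ** 2)
    return CsDistribution(s_grid=s, c=c, ffr=ffr, lambda_reg=0.0,
                          baseline=0.0, rmsd=0.0)


class TestQuantifyPeaks:
    def test_single_peak_covers_everything(self):
        q = quantify_peaks(gaussian_dist([5.0], [1.0]))
        assert len(q.peaks) == 1
        assert q.peaks[0]["relative_area"] == pytest.approx(1.0)
        assert q.peaks[0]["s_peak"] == pytest.approx(5.0, abs=0.05)
        assert q.peaks[0]["s20w"] == pytest.approx(q.peaks[0]["s_peak"])

    def test_two_equal_peaks_split_evenly(self):
        q = quantify_peaks(gaussian_dist([4.0, 10.0], [1.0, 1.0]))
        rel = sorted(p["relative_area"] for p in q.peaks)
        assert rel == pytest.approx([0.5, 0.5], abs=1e-3)

    def test_partition_sums_to_one(self):
        dist = gaussian_dist([3.0, 6.0, 11.0], [0.5, 1.0, 0.8])
        ranges = [(1.0, 4.5), (4.5, 8.0), (8.0, 15.0)]
        q = quantify_peaks(dist, ranges=ranges)
        assert sum(p["relative_area"] for p in q.peaks) == pytest.approx(1.0, abs=1e-9)

    def test_empty_distribution_degenerate(self):
        dist = gaussian_dist([5.0], [0.0])
        q = quantify_peaks(dist)
        assert q.degenerate and q.peaks == []

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            quantify_peaks(gaussian_dist([5.0], [1.0]),
                           ranges=[(2.0, 6.0), (5.0, 9.0)])


# shared small-but-valid scan geometry for inversion tests
SMALL_TIMES = np.arange(1, 13) * 600.0
SMALL_RADII = np.linspace(6.0, 7.2, 240)


class TestFitCs:
    def test_noiseless_single_species_exact_at_true_ffr(self):
        sp = SedSpecies(s=5.0, M=90.0, signal=1.0)
        exp = simulate_sv([sp], radii=SMALL_RADII, times=SMALL_TIMES,
                          noise_sigma=0.0)
        ffr_true = implied_ffr(5.0, 90.0)
        dist = fit_cs(exp, np.arange(3.0, 7.0 + 0.05, 0.1), ffr=ffr_true,
                      lambda_reg=0.0)
        assert dist.rmsd < 1e-8
        q = quantify_peaks(dist)
        assert q.peaks[0]["s_peak"] == pytest.approx(5.0, abs=0.1)
        assert q.peaks[0]["apparent_mass"] == pytest.approx(90.0, rel=0.02)

    def test_noiseless_single_species_with_ffr_search(self):
        sp = SedSpecies(s=5.0, M=90.0, signal=1.0)
        exp = simulate_sv([sp], radii=SMALL_RADII, times=SMALL_TIMES,
                          noise_sigma=0.0)
        dist = fit_cs(exp, np.arange(3.0, 7.0 + 0.05, 0.1), ffr_bounds=(1.1, 2.0))
        assert dist.ffr == pytest.approx(implied_ffr(5.0, 90.0), abs=0.05)
        q = quantify_peaks(dist)
        assert q.peaks[0]["s_peak"] == pytest.approx(5.0, abs=0.1)

    @pytest.mark.parametrize("s_true", [2.8, 4.1, 7.0, 9.6])
    def test_recovers_printed_sedimentation_coefficients(self, s_true):
        # masses on the common shape class anchored at 9.6 S = 200 kDa
        M = 200.0 * (s_true / 9.6) ** 1.5
        exp = simulate_sv([SedSpecies(s=s_true, M=M)], radii=SMALL_RADII,
                          times=SMALL_TIMES, noise_sigma=0.0)
        grid = np.arange(max(0.5, s_true - 2.5), s_true + 2.6, 0.2)
        dist = fit_cs(exp, grid, ffr=implied_ffr(s_true, M), lambda_reg=0.0)
        q = quantify_peaks(dist)
        best = max(q.peaks, key=lambda p: p["area"])
        assert best["s_peak"] == pytest.approx(s_true, abs=0.2)
        assert best["apparent_mass"] == pytest.approx(M, rel=0.10)

    def test_pure_noise_yields_near_empty_distribution(self):
        grid = np.arange(2.0, 10.0 + 0.2, 0.4)
        areas = []
        for seed in range(20):
            exp = simulate_sv([], radii=SMALL_RADII, times=SMALL_TIMES,
                              noise_sigma=0.01, seed=seed)
            dist = fit_cs(exp, grid, ffr=1.3)
            areas.append(dist.total_area)
        # reference loading is 1 signal unit
        assert max(areas) < 0.02

    def test_regularization_reduces_peak_count(self):
        species = [SedSpecies(s=5.0, M=90.0, signal=0.5),
                   SedSpecies(s=8.0, M=170.0, signal=0.5)]
        exp = simulate_sv(species, radii=SMALL_RADII, times=SMALL_TIMES,
                          noise_sigma=0.01, seed=3)
        grid = np.arange(2.0, 12.0 + 0.05, 0.1)
        n_peaks = []
        for lam in [0.0, 0.05, 5.0]:
            dist = fit_cs(exp, grid, ffr=1.35, lambda_reg=lam)
            from scipy.signal import find_peaks
            idx, _ = find_peaks(dist.c, prominence=0.02 * max(dist.c.max(), 1e-12))
            n_peaks.append(len(idx))
        assert n_peaks[0] >= n_peaks[1] >= n_peaks[2]

    def test_too_few_scans_rejected(self):
        exp = simulate_sv([SedSpecies(s=5.0, M=90.0)], radii=SMALL_RADII,
                          times=np.arange(1, 6) * 600.0)
        with pytest.raises(ValueError, match="10 scans"):
            fit_cs(exp, np.arange(3.0, 7.0, 0.1))

    def test_coarse_grid_rejected(self):
        exp = simulate_sv([SedSpecies(s=5.0, M=90.0)], radii=SMALL_RADII,
                          times=SMALL_TIMES)
        with pytest.raises(ValueError, match="resolution"):
            fit_cs(exp, np.arange(1.0, 12.0, 1.0))
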