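# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the known limitations of the package.  It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Fluorescence fluctuation arm

### Forward model

Fluorescence from a dilute solution of diffusing emitters observed through
a 3D-Gaussian confocal volume `W(r) = exp(-2(x^2+y^2)/w0^2 - 2z^2/z0^2)`
fluctuates as molecules enter and leave.  The correlation function of an
`n`-component mixture is

    G(tau) = 1 + (1/N) T(tau) sum_i F_i (1 + tau/tau_i)^-1
                                       (1 + tau/(s^2 tau_i))^-1/2,
    T(tau) = 1 + (T_f/(1-T_f)) exp(-tau/tau_T),

with `N` the mean particle number in `V_eff = pi^(3/2) w0^2 z0`, fractions
`F_i` on the simplex, diffusion times `tau_i = w0^2/(4 D_i)`, structure
parameter `s = z0/w0`, and a multiplicative fast dark-state (triplet)
term.  The axial factor uses `tau_i` per component — the standard form of
this model family; a variant that pins the axial time to the fastest
component is available behind `strict_tau1_axial` for comparison, since
that spelling also circulates in print.

`N` is defined operationally as `1/(G(0+)-1)` of the fitted model; no
separate gamma-factor convention is introduced.  `CPM = <I>/N` (kHz per
molecule); hydrodynamic size ratios follow Stokes-Einstein,
`R_a/R_b = D_b/D_a`.

### Brownian-dynamics trace generator

`simulate_trace` moves point emitters through a periodic cube (default
edge `12 w0`) with per-axis step variance `2 D dt`, weights them by
`W(r)`, applies two-state Markov blinking (stationary dark fraction `T_f`,
relaxation `tau_T`, exact per-bin transition probabilities), and draws
Poisson photon counts per bin.  Species sharing a `colabel_id` ride the
same trajectories — that, and nothing else, produces cross-correlation.
What it does *not* emulate: detector afterpulsing and dead time, spectral
crosstalk (a hook exists but defaults to zero), photobleaching kinetics
(only an optional linear intensity decay for QC testing), and background.
Passing tests therefore validate the estimator chain under the model's own
assumptions, not robustness to instrument artifacts.

Finite-box truncation of the Gaussian detection profile raises the
effective correlation amplitude by a few percent at the default box size;
the trace-level tests compare against closed-form truncated-box integrals
rather than the infinite-volume limit.

### Correlators

`direct_correlate` is the literal lagged time average with symmetric
normalization (means taken over the overlapping samples only); the
brute-force double-loop oracle in the tests is the same formula computed
independently.  `multitau_correlate` uses the conventional m = 16 channels
per octave with pairwise rebinning and symmetric normalization at every
level; below one octave it equals the direct estimator exactly.  The
zero-lag (shot-noise) point is never reported.

### Fitting

Bounded nonlinear least squares (scipy `least_squares`, TRF) on an
internal parameterization that enforces the constraints by construction:
log-amplitude, stick-breaking fractions, log diffusion time plus positive
log-increments (fast-to-slow order), triplet fraction in [0, 0.5], triplet
time at least five-fold faster than the fastest diffusion time.  Weights
are `1/sigma^2` whenever the curve carries uncertainties, plain residuals
otherwise.  Initialization is deterministic: `N` from the first lag
points, diffusion-time splits log-spaced around the observed half-decay
lag, three starts for two components; the best fit is kept.  Noiseless
round trips recover generating parameters to ~1e-6 relative or better.
Model order can be chosen by nested F-tests (alpha = 0.05) with a 0.02
minimum-fraction floor.

Cross-correlation curves are fitted with their diffusion times pinned to
the geometric mean of the two autocorrelation fits (`fix_tau`): on an
uncorrelated curve a free fit can push the diffusion time below the first
lag, where the zero-lag amplitude is unidentifiable and can explode.  RCA
is then `amp_c/amp_r` for reference channel g (the fraction of green
molecules in double-labeled complexes under ideal labeling); the reference
convention is an explicit argument and is recorded in outputs, because the
instrument software's normalization is not otherwise pinned down.

### Windowed population analysis

Long records are cut into 10-s windows; each window is correlated and
fitted independently (two components + triplet), bleach-QC'd (linear-trend
decay > 20% of the initial level fails a channel), classified at the CPM
threshold 7.0 kHz/molecule — the boundary value belongs to the *high*
class — and histogrammed in 3.5-CPM bins anchored at zero (only the width
is prescribed; the origin is fixed at zero by convention).  Slow-diffusion
distributions are compared with the Wilcoxon rank-sum test (exact
distribution for tie-free samples with min group size <= 10, tie-corrected
normal approximation otherwise; the method used is reported), class counts
with two-sided Fisher's exact tests (probability-mass criterion,
verified against exhaustive hypergeometric enumeration) under Bonferroni
adjustment `min(1, m p)`, and grouped RCA samples with one-way ANOVA +
Tukey HSD (zero pooled variance is flagged and p reported as NaN).

### Study-condition defaults (FCS)

| parameter | value | note |
| --- | --- | --- |
| w0 | 0.2 um | calibration beam waist; typical for the instrument class, config-overridable |
| structure parameter | 5 | same status |
| D_fast / D_slow | 12.6 / 0.09 um^2/s | embryo two-component mobility |
| fractions | 19% / 81% | fast / slow |
| N | 5 | particles in V_eff; plausible for mRNA-injected embryos |
| triplet | T_f = 0.15, tau_T = 4 us | ordinary GFP blinking scale |
| curve noise | 1% of G(0)-1, constant per lag | a clean 10-s window on a bright sample |
| lag grid | 160 points, 2 us - 10 s | spans triplet to slow diffusion |
| window populations | 40% high-CPM (10.5 +- 1.5 kHz, log-normal slow D around 0.03 um^2/s); low-CPM 3.5 +- 1.5 kHz, broad mobility | bright windows uniformly slow; sFRP2 scenario removes them |

## Sedimentation arm

### Lamm solver

`dc/dt = -(1/r) d/dr [r (s w^2 r c - D dc/dr)]` with no-flux walls.
Discretization: vertex-centered finite volumes on a uniform radial grid —
end nodes own half cells so the walls sit exactly at the ends of the grid
regardless of resolution (a cell-centered variant moves the walls by
dr/2, which dominates the error budget).  Face fluxes are second-order
central at cell Peclet number |Pe| <= 2 and Scharfetter-Gummel
(exponentially fitted upwind) beyond, where central fluxes oscillate;
SG costs O(Pe^2) artificial diffusion, which is why it is not used
globally.  Time stepping is Crank-Nicolson with four implicit-Euler
startup steps (Rannacher smoothing of the discontinuous initial loading);
scan times are hit exactly by splitting each interval.  The target step is
`min(scan_interval/2, dr/2v_max, dr^2/2D)`.  Discrete sector mass
(`sector_mass`) is conserved to machine precision by construction;
profiles change by < 0.1% of loading when the spatial step is halved at
the default 400-point grid.

### c(s) inversion

For each grid value `s_k`, the shared-shape scaling

    D(s) = (sqrt(2)/18 pi) kT eta^(-3/2) (f/f0)^(-3/2)
           ((1 - vbar rho)/(vbar s))^(1/2)

supplies the diffusion coefficient; the unit-loading Lamm solutions form
the design matrix (trapezoid quadrature weights, so c(s) has units of
signal per Svedberg).  The distribution solves a non-negative linear
least-squares problem with a second-difference Tikhonov penalty, reduced
via normal equations and Cholesky so the active-set NNLS runs on a small
square system; a constant baseline is co-fitted as an unpenalized +-
column pair.  The frictional ratio is optimized in an outer bounded 1-D
search minimizing the unregularized residual; the final penalty strength
is set by the discrepancy principle (chi^2 within `1 + 1/sqrt(n)` of the
lambda = 0 fit), overridable.

Only data inside a radial fitting window enter the fit (default: the
window excludes 4% of the column at the meniscus and 8% at the base, as
in routine sedimentation-velocity practice).  The Lamm solutions are
always computed over the whole cell.  Without the window the pelleting
pile-up at the base — the most D-sensitive, least model-robust part of the
signal — dominates chi^2 and can displace peak positions by several tenths
of a Svedberg.

Peaks are local maxima above 5% prominence with valley-to-valley
integration ranges (outermost ranges extend to the grid edges), parabolic
sub-grid position refinement, trapezoidal areas, and relative areas
normalized by the whole-distribution area (a full partition sums to 1).
Each peak also carries `s20,w` (viscosity/buoyancy standardization to
water at 20 C; the identity transform at the default solvent) and the
apparent molar mass from the fitted `f/f0` via the Svedberg closure.

### Study-condition defaults (AUC)

42,000 r.p.m., 20 C, water-like solvent (0.99823 g/mL, 1.002 cP), vbar
0.73 mL/g for all species, radial window 6.0-7.2 cm on 400 points, 40
scans every 300 s, Gaussian detection noise with sigma 1% of unit total
loading, s-grids at 0.1 S resolution spanning each scenario's species.
None of the geometry or the scan schedule is printed in the source study;
these are ordinary values for the instrument class.

Mixture scenarios place all species in one hydrodynamic shape class —
`M(s) = 200 (s/9.6)^(3/2)`, anchored at the smallest HMW assembly (9.6 S
at its trimer-scale 200 kDa) — so that the single-`f/f0` assumption of the
c(s) model holds exactly for the ground truth and the mass closure is a
genuine round trip.  The two printed apparent masses of the
conditioned-medium mixture (~150 and ~200 kDa) imply mutually
inconsistent frictional ratios (1.45 vs 1.29) and are themselves outputs
of a single-`f/f0` analysis, so they cannot both serve as exact generator
inputs; the anchor was placed on the assembly whose mass the validation
checks.  Consequently the afamin-complex species carries the
closure-implied 124.5 kDa and its fitted apparent mass reports ~125 kDa,
not ~150.  Monomer calibration runs (GFP 2.8 S / 30 kDa, GFP-WntD 4.1 S /
61 kDa) keep their printed masses, which are sequence-anchored.

The mock-treated composition is 13.8% albumin-bound dye (4.2 S), 35.1%
afamin complex (7.0 S), and 51.1% HMW split evenly over 9.6 / 11.8 /
14.0 S assemblies ("widely distributed"); afamin depletion shifts the
7.0 S share to 14.1% and the HMW share to 69.6%.  The Fzd8-CRD and sFRP2
scenarios transfer area into new 6.0 S and 5.4 S complex peaks, the
latter matching its published HMW end point (33.6%).

## Problem sizes

The default validation runs use 20 synthetic curves of 160 lags for the
FCS recovery; single SV runs of 40 scans x 400 radii inverted on 51-161
point s-grids; 10 measurements per RCA group; 40 windows per population
condition.  These sizes give Monte-Carlo errors comfortably below the
tolerances being checked while keeping a full validation run in the
minutes range on one CPU.

## Known limitations

* The c(s) model omits time- and radius-invariant systematic noise
  components (TI/RI); only a constant baseline is co-fitted, because the
  synthetic data carry no systematic noise.  Meniscus position is treated
  as known, not fitted.
* On mixtures whose species genuinely differ in shape, the single fitted
  `f/f0` is a compromise and the residual surface over `f/f0` is shallow;
  peak *positions* stay robust but apparent masses inherit the compromise
  (the reason the generator uses a common shape class).
* A free-amplitude fit of an uncorrelated cross-correlation curve is
  unidentifiable; the pinned-time cross fit is the supported route to RCA.
* The trace generator's box truncation and finite bin width bias
  amplitudes and fast decays at the percent level; tests account for this
  explicitly rather than hiding it in tolerances.
* Windowed analysis treats windows as independent measurements; no
  spatial structure within an embryo is modeled — conditions are
  categorical labels.
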