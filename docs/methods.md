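# Methods

This note documents the models implemented in `codexfit`, their
assumptions, the numerical choices behind them, and what the synthetic
fixtures do and do not establish about real data.

## The CODEX forward model

### Recoupled-CSA phase

The motionally averaged ³¹P shift tensor of a fluid-phase phospholipid
is treated as axially symmetric about the local membrane normal, with
anisotropy δ_cs = δ∥ − δ_iso in ppm (stored signed, as reported by
sideband analysis; the sideband fit itself cannot determine the sign
and assigns it by convention, positive by default).  Under MAS at rate
ν_r the instantaneous anisotropic frequency of a tensor whose unique
axis sits at polar angle β, azimuth γ in the rotor frame is

    ω(t) = ω_δ · ½(3 cos²θ(t) − 1),
    cos θ(t) = cos θ_m cos β + sin θ_m sin β cos(ω_r t + γ),

with θ_m the magic angle and ω_δ = 2π δ_cs ν_L (ν_L the Larmor
frequency in Hz/ppm).  One CODEX recoupling period consists of N π
pulses spaced t_r/2 apart (N = 3 in the experiments this package
models), lasting N t_r/2, during which the sign of the integrand
toggles at each pulse:

    Φ(β, γ) = ∫₀^{N t_r/2} s(t) ω(t) dt,   s(t) = (−1)^⌊2t/t_r⌋.

The integral is evaluated per half-rotor segment by the trapezoidal
rule (64 steps per rotor period by default — resolving the ω_r and
2ω_r modulation at 4 kHz with headroom).  The isotropic shift is
excluded from the integrand: for odd N its toggled integral over one
period does not vanish, but it is identical in the dephasing and
rephasing periods (mixing times are integer rotor multiples, so both
periods start at the same rotor phase) and cancels exactly in the
phase difference that the signal depends on.  Finite-pulse effects, rf
inhomogeneity, homonuclear couplings and transverse relaxation during
recoupling are not modelled; relaxation enters only through the
ensemble echo-survival weight below.

### Diffusion on the sphere and the decay

The pure-exchange (reference-compensated) CODEX signal of one vesicle
is E(t_m) = ⟨cos(Φ(n̂₀) − Φ(n̂_{t_m}))⟩, with n̂₀ powder-averaged and
n̂_{t_m} distributed according to the Green's function of isotropic
diffusion on the sphere.  The Green's function is diagonal in Legendre
order l with eigenvalue decay exp(−l(l+1) d_ang t).  The implementation
expands the orientational phase correlation

    C(u) = ⟨cos(Φ(n̂₀) − Φ(n̂_u))⟩,   u = n̂₀ · n̂_u,

(averaged over a 2000-point equal-area spiral powder grid and over the
azimuth of the displacement ring at each u) on Gauss–Legendre nodes in
u and projects it onto Legendre polynomials, giving coefficients a_l
for l ≤ L (default L = 40).  The decay is then

    E(t_m) = Σ_l a_l exp(−l(l+1) d_ang t_m),
    d_ang = D_lat/r² + k_B T/(8π η r³).

The a_l depend only on the tensor, the spinning conditions and the
quadrature — not on r, D_lat or t_m — and are cached, which is what
makes ensemble sums, least-squares fits and bootstraps cheap.  a_0 is
the infinite-time plateau |⟨e^{iΦ}⟩|² (the powder average fixes the
baseline, so it is never a fit parameter), and the truncation tail
1 − Σ_l a_l is carried in the result metadata; exceeding the configured
tolerance (default 10⁻³) flags a convergence warning.  E(0) = 1 and the
d_ang = 0 limit are returned exactly (they are the physical delta-
function limits that a truncated expansion only approximates).  At the
default resolution the tail is ~10⁻¹², and the dominant numerical error
is powder-grid discretization: halving/doubling all resolution knobs
moves E by ≲2×10⁻³ at 400 orientations and correspondingly less at the
default 2000.

Whole-vesicle tumbling is included in the mixing-time propagator by
summing its Stokes–Einstein–Debye rate into d_ang (so 6 d_ang = 1/τ_c
identically); a configuration switch (`include_tumbling=False`) drops
the tumbling term from the propagator for comparison, since published
descriptions of the method do not state unambiguously whether tumbling
enters the mixing propagator or only the echo-survival weight.  The
deterministic result is validated against Monte-Carlo random walks on
the sphere (independent phase integrator, tangent-plane Gaussian steps)
to within 1% over r = 50–500 nm and D_lat = 10⁻¹³–10⁻¹¹ m²/s.

Non-axial tensors (η ≠ 0) are supported by the phase integrator and the
sideband simulator but not by the vesicle decay model, whose
orientation bookkeeping maps membrane normals to (β, γ) only — complete
only for axial symmetry.  Motionally averaged fluid-lipid tensors are
axial to good approximation, which is why η defaults to 0 everywhere.

### Ensemble over the size distribution

The number-weighted DLS distribution P(r) is combined into signal
weights w(r) ∝ P(r) · 8π r² · exp(−τ_echo/τ_c(r)): the 8π r² factor
counts ³¹P nuclei in both leaflets, and the echo-survival factor
suppresses small vesicles whose transverse magnetization dephases
during the recoupling periods (at the defaults, an r = 50 nm vesicle
contributes < 10⁻³ of the weight of an r = 500 nm vesicle).  τ_echo
defaults to N t_r (two recoupling periods of N t_r/2 each; 0.75 ms at
4 kHz with N = 3) and is configurable because published sequences
differ in whether the z-filter is counted.  The temperature and
viscosity entering τ_c are those of the NMR experiment, not of the DLS
measurement.  DLS exports are optionally resampled onto a log-spaced
radius grid (60 points over 20–1000 nm) by linear interpolation of the
cumulative distribution — stable quadrature over the ~1.5 decades such
exports span.  No multilamellarity correction is applied: the model
consumes the DLS distribution as the true distribution, which is
appropriate when interior vesicles are small enough to be suppressed
by the echo-survival weight.

## Fitting D_lat

The fit minimizes Σ(E_obs − A·E_pop(t_m; D))² over D (bounded
10⁻¹⁴–10⁻¹⁰ m²/s, optimized in log₁₀ D) and a free amplitude
A ∈ (0, 1.2].  A absorbs the normalization of experimental series
(commonly normalized to one resonance, so per-resonance scale is not
1); the plateau is supplied by the powder average.  The trust-region
solver starts from the best point of a 12-point log-spaced grid over D.
An estimate pinned at either search bound is flagged unconverged with a
diagnostic (flat data pin at the lower bound).

The 95% CI is a residual bootstrap: residuals are leverage-rescaled
(r_i/√(1−h_ii), leverages from the linearized model at the point
estimate) to restore the variance the fit absorbed, resampled with
replacement, added to the fitted curve, and each synthetic set is
refit.  For the short decay series typical of these experiments
(~8 points, 6 residual degrees of freedom) the plain 2.5/97.5
percentile interval of the refit D values systematically undercovers,
because the noise level estimated from so few residuals is itself
uncertain; the package therefore reports the expanded percentile
interval — percentile deviations from the point estimate inflated by
√(n/(n−1)) · t_{0.975,n−p}/z_{0.975} — the standard small-sample
correction for percentile bootstrap CIs.  Calibration is verified by
simulation: at σ = 0.02 on 8 mixing times, nominal-95% intervals cover
the generating D_lat in 90–99% of 200 replicates.  Bootstrap runs are
deterministic under a fixed seed (mandatory in the CLI).

Each resonance is fit independently; no global multi-resonance fit is
attempted.  T₁ (inversion recovery, M₀(1 − 2a e^{−t/T₁})) and T₂
(Hahn echo, M₀ e^{−τ/T₂}) are ordinary bounded nonlinear least squares
with closed-form-initialized starts.

## Sideband manifolds

For slow-MAS spectra the one-pulse propagator of a crystallite is
exp(iφ(t)) with φ the running integral of the anisotropic MAS
frequency; φ is periodic over a rotor cycle (the anisotropic frequency
averages to zero exactly at the magic angle), and averaging over each
crystallite's rotor phase makes the observed sideband intensities the
powder average of the squared Fourier magnitudes |c_k|².  Parseval
then guarantees Σ_k I_k = 1.  The simulator integrates φ on 256 points
per rotor period, takes an FFT, and powder-averages over a 987-point
spiral grid (≥ 232 orientations keeps per-sideband error below 0.5%,
verified against a brute-force FID-propagation oracle).  δ_cs (and
optionally η) is extracted by least squares between observed and
simulated manifolds renormalized over their common orders; a
centerband-only manifold is rejected as unidentifiable.  Overlapping
manifolds of different resonances must be separated upstream; no
lineshape model is fitted.

## Transition temperatures

The gel–fluid transition is located as the maximum of the derivative of
a cubic smoothing spline through the normalized intensity series.  The
smoothing convention matters and is stated explicitly: the spline
minimizes p·Σ(y−f)² + (1−p)·∫f″², so p = 1 interpolates and the
default p = 0.975 maps onto a pure roughness-penalty weight
λ = (1−p)/p ≈ 0.0256 (logged at fit time, since implementations
disagree on which term p multiplies).  The derivative is taken
analytically from the spline coefficients and evaluated on a grid at
least 10× the input density; a derivative maximum on the range boundary
is flagged, and a monotone-decreasing series (no sigmoid rise) warns.
No two-state thermodynamic model is fitted — the transition temperature
is defined purely as the derivative maximum.  When a per-point pressure
series accompanies the curve (sealed rotor), the pressure at T_m is
interpolated onto the result.  The Clapeyron slope is the finite
difference (T_m,high − T_m,low)/(P_high − P_low).

## Sealed-rotor pressure and centrifugal force

Rotors sealed with helium at (P₀, T₀) follow constant-volume ideal-gas
scaling P = P₀·T/T₀ in absolute temperature; no real-gas correction is
applied (helium virial corrections are negligible at these
conditions).  The relative centrifugal force helper returns
(2πν)²r/g with g = 9.81 m/s²; the radius is an explicit argument, and
the conventional reference point for a 5 mm MAS rotor is its 3.3 mm
inner radius.

## Synthetic data

The generators produce exactly what the analysis stages assume: a
discretized lognormal number-weighted radius distribution (default
median 150 nm, geometric SD 1.5, 60 log-spaced points over 20–1000 nm —
shaped like a number-weighted DLS export of an extruded liposome
suspension), forward-model CODEX decays with additive i.i.d. Gaussian
noise on the normalized intensities (additive, matching the
least-squares objective; default series 1–128 rotor periods at 4 kHz),
logistic melt curves (width parameter = 10–90% rise span), and
mono-exponential relaxation series.  All generators are pure functions
of parameters and seed.

What passing tests therefore establish: the estimator recovers the
parameters of data generated by its own forward model, its bootstrap is
calibrated against its own noise model, and the forward model agrees
with independent stochastic simulation of the same physics.  What they
do not establish: correctness of the forward model's physical
assumptions for a given real sample — unilamellarity of the vesicles,
accuracy of the DLS distribution, axial symmetry of the averaged
tensor, additivity and normality of the experimental noise, and the
absence of coherent artifacts (spinning instability, B₁ droop) are
assumptions the user must justify experimentally.

## Problem sizes and tolerances

Default forward model: 2000 powder orientations, L = 40, 64 time steps
per rotor period, 48-node displacement quadrature.  Tests and the
calibration studies run reduced configurations (400 orientations,
L = 30, 32 steps, 36 nodes; 20-point radius grids), at which the
forward-model discretization floor is ~2×10⁻³ in E — an order of
magnitude below the 1–1.5% oracle tolerances and the noise levels those
studies inject.  Monte-Carlo cross-checks use 3×10⁴ walkers (standard
error ~4×10⁻³ per point).  The bootstrap coverage study uses 200
replicates × 200 resamples at σ = 0.02.
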