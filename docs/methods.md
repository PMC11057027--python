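# Methods

## Lumped thermal model

The sample (a ~100 nm amorphous-ice film on a laser-heated support, held at
100 K) is treated as a single thermal mass:

    m c(T) dT/dt = P_abs(t) − k (T − T_bath)

`P_abs(t)` is the absorbed laser power as a piecewise-constant multiple of the
hold power, `k` a linear loss coefficient. Integration is done in specific
enthalpy H rather than temperature: H(T) is strictly monotone (solid branch
∫c dT, a flat latent segment of width L at 273.15 K, then a liquid branch), so
melting — the enthalpy method — is just a region of the same scalar ODE, with
melt fraction φ = (H − H_sol)/L clipped to [0, 1]. The ODE is solved with
LSODA at rtol 1e-8 per pulse segment; the output grid resolves every segment
with ≥ 50 points and a ≤ 20 ns step.

**Calibration.** Only two parameter combinations matter: the steady state
fixes P_abs = k (T_plateau − T_bath), and the rectangular-pulse rise time to
the melting point is exactly t = (m/k)∫ c(T)/(T_plateau − T) dT, which inverts
in closed form for k. Defaults: plateau 280 K, rise 11 μs, bath 100 K. The
calibration is verified against the integrator (crossing within 2%).

**Defaults with units.** Solid c(T) piecewise linear, 0.8 J/(g·K) at 100 K to
2.1 J/(g·K) at 273.15 K; liquid c = 4.2 J/(g·K); L = 334 J/g — textbook ice
values, all overridable. The effective mass m is a free normalization (k and
P_abs scale with it).

**Metrics.** The average heating rate is (T_hi − T_lo)/Δt between the first
crossings of T_lo = 100 K and T_hi = 273 K (crossings by linear interpolation
on the solver grid) — i.e. the time-average of dT/dt over that stretch, which
is the reading of "average simulated rate" that reproduces 1.6 × 10⁷ K/s =
173 K / ~10.8 μs for the rectangular pulse. The melting time runs from pulse
onset to φ = 1; in the zero-latent-heat limit it degenerates to the
melting-point crossing.

**Known limitations.** A single-mass model has no lateral heat diffusion into
the support. Two visible consequences:

- With the plateau only ~7 K above the melting point, the net power available
  during melting under hold power alone is k·(280 − 273.15), so a rectangular
  pulse needs ~90 μs to finish melting — it stalls at the melting plateau for
  the rest of its 30 μs duration. Spiked pulses that supply the latent heat
  during the spike melt in hundreds of nanoseconds, as they should.
- The model overstates the average heating rate of intense short spikes. For
  the 17.5×/450 ns pulse it yields ~1.1 × 10⁹ K/s, a factor ~3–4 above the
  value a spatially resolved treatment assigns to the same pulse. The two
  constraints "melts completely within 600 ns" and "average rate ≈ 3 × 10⁸ K/s"
  cannot coexist in any lumped model: delivering the ~586 J/g of sensible plus
  latent heat within 600 ns forces the 100→273 K traversal in ≲ 260 ns, i.e. a
  rate ≥ ~7 × 10⁸ K/s. The melting-time bound is the physically robust
  prediction; spike-pulse rate values should be read as upper bounds.

## Crystallization kinetics

Transformed fraction by the Kolmogorov/JMAK extended-volume construction for
continuous nucleation with isotropic interface growth,

    X(t) = 1 − exp(−K_d ∫ J(T(τ)) [U(t) − U(τ)]^{n−1} dτ),  U(t) = ∫ u(T(s)) ds,

K₃D = 4π/3 with n = 4 (bulk), K₂D = π with n = 3 (surface mode, since surface
nucleation likely dominates in thin films; per-area J basis). Both integrals
are trapezoidal on the trajectory grid; the τ-integrand vanishes identically
for τ > t after clipping U(t) − U(τ) at zero, so one vectorized row-wise
trapezoid yields X at every grid time. Discretization error scales as
(Δt/t)²; the constant-T closed form 1 − exp(−(π/3)Ju³t⁴) is matched to 1e-6
and a seeded Monte-Carlo union-of-grains simulation (explicit Poisson
space-time nucleation, spherical growth, periodic voxel box) to 2%.

Crystallization is suppressed (J = u = 0) wherever the sample is fully molten
above 273.15 K: stable liquid does not freeze at 280 K. X is clipped
monotone; crystal melting (X decreasing) is deliberately not modelled, so X
is a "has ever crystallized" fraction.

**Rate tables.** J and u are log-linear interpolation tables, with
temperatures outside the table clamped to the endpoints (a warning is issued;
extrapolating log-rates diverges). Defaults, chosen once for qualitative
realism:

- log₁₀ J(T) single-peaked at 205 K (width 30 K, 6 decades per width²),
  collapsing to nothing at the melting point — fast nucleation deep in the
  supercooled regime, none near equilibrium.
- u(T) = mobility × driving force: a VFT-like mobility term
  log₁₀ u_mob = 1.8 − 460/(T − 118) frozen out toward the glass transition,
  times the undercooling factor 1 − exp(−(273.15 − T)/26) that vanishes at the
  melting point. The product rises ~17 decades from 140 K, peaks near
  250–260 K, and falls to zero at 273.15 K — the familiar shape of ice-growth
  velocity in supercooled water. The driving-force factor is load-bearing: a
  growth speed that stays large up to the melting point would crystallize the
  sample during any dwell at the enthalpy-method melting plateau, at every
  heating rate, which is thermodynamically wrong (no driving force at
  equilibrium) and would erase the critical-rate phenomenology.
- Absolute scale: only the combination global_scale·J·u^(n−1) matters, so a
  single `global_scale` on J is calibrated such that the critical heating rate
  at threshold X = 0.01 equals 1 × 10⁸ K/s. The ramp extended volume is linear
  in J, making this a closed-form rescaling.

**Ramps and the critical rate.** `fraction_at_ramp_rate` uses an idealized
linear ramp 100 → 280 K with instantaneous melt above 273.15 K (no latent
plateau), so the post-melt hold contributes nothing and the extended volume
obeys ext ∝ R^(−n) exactly. The critical rate is found by Brent root finding
on log R (1% tolerance, bracket 1e4–1e12 K/s). Consequently
R_c(f·J)/R_c(J) = f^(1/n) holds to the solver tolerance, and the 5 → 1.495
nucleation-to-critical-rate mapping is exact arithmetic.

**Threshold.** "Crystallization outrun" means final X < 0.01 — below the
weight resolution of the decomposition stage — shared by the kinetics and
analysis defaults; configurable.

## Diffraction model

Reference profiles are parametric (Gaussian peaks on an exponentially
decaying background) rather than measured: defaults place the low-T liquid
maxima at 1.70/3.05 Å⁻¹, the high-T liquid at 2.00/2.90 Å⁻¹ (first maximum
moves up with temperature, second slightly down), and the crystalline
component's Bragg rings at q = 2π/d of hexagonal ice (a = 4.52 Å, c = 7.36 Å:
1.61, 1.71, 1.82, 2.78, 3.27 Å⁻¹, σ = 0.025–0.03 Å⁻¹) on an amorphous-like
background. Peak widths are free parameters; the real reference line shapes
are recorded, not parametric, so no quantitative line-shape claim is made.
Amplitudes set the counting statistics: ~1000 counts at the first maximum per
unit exposure. The default q grid is 0.2–4.0 Å⁻¹ with 400 points.

The liquid at intermediate temperature is a convex blend
α(T)·high + (1 − α)·low with α linear in T between the 100 K and 280 K
references, clipped outside — a two-state interpolation, not a structural
model.

2-D rendering assigns each pixel the profile value at its radial q
(default 512², center at the geometric center, 0.011 Å⁻¹/pixel) and optionally
draws Poisson counts. Azimuthal averaging bins pixels by floor(r/Δr) with
Δr = r_max/n_bins and maps bin centers (i + ½)Δr back to q; the rule is
documented so the brute-force per-pixel oracle in the tests matches it
bin-for-bin. Detector effects (point spread, gain, ellipticity, beam stop)
are out of scope.

## Decomposition and trends

Profiles are fitted over q ∈ [0.8, 3.5] Å⁻¹ (excluding the beam-stop-adjacent
and high-q regions) as non-negative combinations of the three references by
NNLS. The system is whitened by counting-noise standard deviations — one
observed-count pass, then one reweighting step with model-predicted counts
(IRLS), which removes the low-count bias of observed-count variances; with
homoscedastic weighting the reported 3σ intervals covered the truth in only
~98% of Poisson replicates, versus ~99.5% with this estimator. Standard
errors come from σ̂²(AᵀA)⁻¹ of the whitened system with σ̂² the residual
mean square over n − n_active degrees of freedom. Weights are not constrained
to sum to one (counts scale with exposure); normalized weights are reported
alongside. No background component is included by default.

Weight-versus-rate trends use w(R) = a·exp(−R/ρ) + c (amplitude and offset
constrained non-negative for the crystalline component), fitted in units of
the median rate for conditioning. The critical rate inverts the crystalline
trend analytically: R_c = ρ·ln(a/(w₀ − c)).

`analyze_scan` fits the crystalline decay from the empirical weight maximum
onward, weighted by the per-point standard errors. The rising branch below
the maximum occurs where the sample crystallizes completely (see below) and
carries no information about the decay the exponential family describes.

## Synthetic experiments: what they emulate, and what not

For each target rate the generator builds the pulse the experiment would use:
a plain rectangular pulse at the bottom of the range, and leading spikes with
constant excess fluence (m − 1)·d = 16.5 × 450 ns hold-power·s above it, the
rate tuned by trading spike intensity m against duration d (rates between the
rectangular pulse and the weakest constant-fluence spike shrink the spike
integral at maximal duration). It then simulates T(t), integrates X(t), and
forms probe-window (10 μs, uniform) time averages: w_cryst = ⟨X⟩, the liquid
remainder split by the temperature blend α(T(t)) at each instant; the three
instantaneous coefficients sum to one before averaging. Mixture profiles get
Poisson noise per replicate (5 by default, exposure 0.5) from sub-seeds
spawned deterministically off the scan seed, so a fixed seed reproduces the
dataset bit for bit.

Two deliberate consequences of the probe-window average:

- **Measured weights understate final fractions.** A sample that finishes
  crystallizing midway through the window shows ⟨X⟩ well below X_final — the
  same reason a measured crystalline weight of ~0.11 is consistent with a
  final crystallized fraction several times larger.
- **The crystalline weight is non-monotone at the slow end.** Below
  ~5 × 10⁷ K/s the calibrated n = 4 kinetics crystallize the film completely
  (X_final = 1), and ⟨X⟩ then measures when crystallization finishes inside
  the window, which moves earlier — so ⟨X⟩ rises — as the rate grows. Strict
  monotonicity of the weights holds on the decay regime (≳ 6 × 10⁷ K/s), and
  the monotonicity tests run there.

**Labeled rate versus ramp rate.** Scan conditions are labeled by the
100→273 K average rate of their own pulse, but those trajectories decelerate
approaching the melting point (c(T) grows, the loss term grows), spending
more time per kelvin in the growth zone than a linear ramp at the same
average rate. A scan's ground-truth threshold crossing therefore sits ~30–40%
above the ramp-defined critical rate of the same kinetics. Analysis recovery
is judged against the scan's own encoded crossing
(`synthetic.true_threshold_crossing`); the ramp-defined anchor remains the
kinetics-level definition. Passing tests show the analysis recovers what the
generator put into the data — they do not show that the parametric profile
shapes, the two-state liquid blend, or the lumped thermal trajectories match
any real detector's output.

## Problem sizes

Defaults keep everything at desk scale: thermal ODE grids of 1.5–4 × 10³
points, O(N²)-vectorized Avrami curves at N ≲ 4 × 10³, 512² rendered images,
scans of 8 rates × 5 replicates (~1 s to generate), and a Monte-Carlo oracle
of 150 realizations × 64³ voxels (~7 s). The full test suite runs in about a
minute.
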