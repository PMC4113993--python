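# Methods

This note documents the models implemented in `flagsync`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Unit system

All lengths are μm, times s, viscosity Pa·s. Because
1 Pa·μm² = 10⁻¹² N = 1 pN, drag coefficients (Pa·s) times velocities
(μm/s) give force densities directly in pN/μm, and arclength integrals
give pN. Reduced forces `G = F/8πμ` carry μm²/s and are the quantity
used throughout; conversion to pN happens only at reporting time. The
test suite asserts this consistency explicitly.

## Stokeslet flow model and fitting

A flagellum's far flow is modelled as the field of a single point force:
`u(x) = (1/r)(I + r̂r̂)·G`, `r = x − x₀`. The three-dimensional kernel is
evaluated in the beating plane (z = 0); out-of-plane flow is ignored
because the consumed velocity fields are planar PIV-style snapshots.

**Fitting.** For fixed x₀ the model is linear in G, so every trial
position is scored with the exact linear least-squares G (2N×2 system).
The outer 2-D search over x₀ uses Nelder–Mead, multi-started from the
highest-speed grid points and a coarse scan around them: the near-field
exclusion disc creates local minima on its far side, and a single start
was observed to strand the optimiser there on a few percent of frames.
On noiseless model data the fit recovers (x₀, G) to machine precision;
an exhaustive 21×21 grid with exact linear solves serves as an
independent oracle for the objective minimum in the tests.

**Force modulation.** `|G|(t) = A₀(1 + A₁ sin(2πt/T + φ₀))` at fixed T is
linear in `(A₀, A₀A₁cos φ₀, A₀A₁sin φ₀)` and is fitted by one linear
least squares; A₁ is reported non-negative with φ₀ adjusted.

**Radial decay.** The time-averaged speed field is interpolated along a
ray and fitted log–log; an exact Stokeslet gives slope −1, a source
dipole −2. The default fit window (20–55 μm) sits inside the synthetic
grid and beyond the near field.

**Stiffness bound.** The flow from a neighbouring flagellum
(`u = G/r`) acting on a flagellum of length l exerts a torque
≈ `C⊥·u·l²/2`; equating to a rotational spring `k·α` and bounding α by
the observed α* gives `k > C⊥·u·l²/(2α*)`. With the slender-body C⊥ at
aspect ratio 80 and the measured G, r, l this is ≈ 3×10² pN·μm at α* = 1
(hence 3×10⁴ at α* = 0.01). The aspect ratio for C⊥ is fixed at 80, the
same value used for the force-density analysis.

## Resistive force theory

Force density `f = C⊥u⊥ + C∥u∥` per node, with tangents from centred
finite differences in arclength and node velocities from centred finite
differences in time (one-sided at the ends); total force by trapezoidal
quadrature. Known limitation, documented rather than corrected: the local
drag model overestimates force production during the recovery stroke,
where neighbouring filament segments shield each other.

The three waveform angles are measured at arclength fractions 1/6, 1/2
and 5/6 (proximal, mid, distal). Fixed fractions make the quantity
reproducible across cells; any other convention shifts the numbers but
not the systematics.

## Synthetic data

Generators are fully deterministic given a root seed; independent named
substreams are derived with a SHA-256 keyed `SeedSequence`.

- **Flow movies**: a point force on a closed loop (default: a 5 μm
  circle traversed once per beat, force tangent to the loop) with the
  measured modulation (A₀ = 1076 μm²/s, A₁ = 0.56, T = 1/33 s), sampled
  on a grid with additive isotropic Gaussian velocity noise (fraction of
  the RMS speed; the error structure of real PIV is not modelled). Grid
  points within 5 μm of any trajectory point are excluded once per movie,
  keeping frames congruent for time averaging; the far-field fit region
  is unaffected.
- **Waveforms**: a single-harmonic tangent-angle travelling wave
  `ψ(s,t) = ψ₀ + A(s/l)·sin(2π(s/Λ − t/T))` with a linearly growing
  amplitude envelope, positions by arclength integration of the unit
  tangent. This is a stand-in with the right qualitative asymmetry (the
  beat-averaged force is nonzero along the mean axis), not a fit to real
  beats. The emitted polyline is rescaled by ~10⁻⁵ so its chord length
  equals l exactly: discrete inextensibility is the invariant downstream
  stages rely on.
- **Phase pairs**: Δ(t) from the Adler integrator, split symmetrically,
  `φ₁,₂ = 2πω̄t ± πΔ`; the common mode is irrelevant to every statistic
  computed downstream. Beat times of the noisy phases are defined as
  first passages of the 2πk levels (running maximum), which is what a
  threshold detector with a refractory rule observes.
- **Section signals**: `s_i(t) = w(φ_i(t))` for a 2π-periodic waveshape
  with exactly one upward zero crossing per period (validated
  circularly); the default is a sinusoid. Only the functional role of
  the experimental interrogation regions — one section passage per
  beat — is emulated, not pixel intensities.

**What passing tests show.** Round-trip recovery on these generators
demonstrates correctness of the analysis chain under the stated
generative models (additive Gaussian noise, single-harmonic beats, exact
Adler dynamics). They do not certify performance under real-data
pathologies: tracking dropouts, non-stationary beat frequencies,
pixel-correlated PIV noise, or three-dimensional flagellar motion.

## Phase extraction and locking statistics

Crossing detection uses linear sub-sample interpolation and a refractory
window of half the median inter-crossing interval ("precisely once per
beat"). The continuous phase is piecewise linear, gaining exactly 2π per
crossing (asserted exhaustively in tests). With 5% signal noise at
1 kHz/33 Hz, beat-time jitter is ≈ 0.3 ms and the reconstructed Δ(t) of a
noise-free-dynamics pair is accurate to < 0.02 beats RMS; for a noisy
pair the dominant reconstruction error is the irreducible within-beat
phase diffusion (unobservable at one sample per beat), not the extraction.

**Slip detection.** The integer winding `n(t) = round(Δ − Δ_ref)` (Δ_ref
the circular mean of Δ mod 1) changes at candidate slips; a change must
persist for a hold time of **3 mean beat periods** to count, so brief
excursions that re-trap are not slips. The hold time is a declared
convention — nothing in the underlying dynamics singles out a value —
and slip counts at the default are validated against direct first-passage
counting on ground-truth Δ across 100 independent simulations.

## Stochastic Adler model

`Δ̇ = δν − 2πε sin 2πΔ + ξ`, `⟨ξξ'⟩ = 2T_eff δ`. Euler–Maruyama with
default dt = 10⁻⁴ s at ω̄ = 33 Hz (stability guard
dt ≤ 0.1/max(|δν|, 4π²|ε|); halving dt changes reported statistics by
less than their seed-to-seed spread). The integrator core is
numba-compiled; noise is drawn up front from a seeded Generator so
results are bit-reproducible.

**Noise-free bifurcation.** The mean drift rate of the deterministic
equation is `√(δν² − (2πε)²)` outside the locked regime and 0 inside, so
`δω/δω_far = √(1 − (2πε/δν)²)`. The square-root form is verified against
direct integration to 1% at 2πε/δν ∈ {0, 0.5, 0.9} (drift measured
between integer-winding crossings to avoid partial-cycle bias). With
noise the transition rounds and shifts: at the deterministic bifurcation
point the measured ratio is strictly positive, and it increases
monotonically with T_eff; this rounding is reproduced by simulation only,
with no closed-form slip-rate fit.

**Parameter inference.** Restricted to locked segments:

1. `T_eff = Var(δΔ)/(2dt)` from one-sample increments within segments —
   the noise is additive, so this estimator carries no linearization
   bias.
2. (ε, δν) from the exact stationary identities obtained by applying
   Itô's lemma to cos 2πΔ and sin 2πΔ:
   `δν E[sin] − 2πε E[sin²] = −2πT_eff E[cos]` and
   `δν E[cos] − 2πε E[sin·cos] = 2πT_eff E[sin]`, solved with empirical
   moments. The sign of ε (in-phase vs antiphase) emerges from the
   solve.

An Ornstein–Uhlenbeck linearization about the well minimum
(`r = 4π²ε cos 2πΔ₀`, `T_eff = C₀/τ_r` from the autocorrelation) is the
more familiar protocol and is retained as `autocorrelation` plus a
degenerate-case fallback, but it is measurably biased at realistic
parameters: the washboard well is anharmonic, locked-state variance
exceeds `T_eff/r` (by ~40% at δν/ω̄ = 0.058, T_eff/ω̄ = 0.005), and the
bias propagates into T_eff and δν. The moment-identity protocol recovers
(ε, δν, T_eff) with median errors of a few percent over 20 seeds at the
population-mean parameter scale; recovery, not agreement with any
per-cell number, is the validation.

A series that never locks cannot resolve ε; it is detected by the pooled
residual spread (a drifting Δ is near-uniform on the unit cell,
σ ≈ 0.29) and returns a drift-only δν estimate.

**Coupling law.** `|κ| = k·L⁻¹` is fitted through the origin in 1/L;
the free log–log slope is reported as a diagnostic of the hydrodynamic
1/L scaling.

**Noise from isolated beat periods.** For a noisy phase oscillator the
beat period is a first-passage time with `Var(T) = 2D/f̄³`, so
`D = Var(T)·f̄³/2` (beats²/s); a pair's T_eff is the sum of the two
cells' D. Validated against direct first-passage simulation to 15%.

## Fixture conditions for the scaling tests

The coupling-law and fluctuation-collapse fixtures fix `ε = 0.016·ω̄/L`
at L ∈ {0.85, 1.22, 1.69, 2.27} and need the pairs locked at every L, so
they use a small detuning (δν/ω̄ = 0.005; at the population-mean 0.058
the widest separation is past the bifurcation and never locks) and
T_eff/ω̄ = 0.001, which yields locked fluctuations of σ ≈ 0.04–0.06
beats — the experimentally observed scale. This matters because the
`Var(Δ) ∝ L` law and the `(Δ−Δ₀)/√L` collapse are harmonic-regime
(OU-linearization) results: at T_eff/ω̄ = 0.005 the widest-separation
fluctuations reach σ ≈ 0.13 beats, the anharmonic softening of the well
inflates the variance by tens of percent, and the collapse genuinely
degrades. That breakdown is a property of the model, not of the
implementation. The parameter-recovery test itself runs at the
population-mean triple (0.016, 0.058, 0.005), where the moment-based
inference is insensitive to the anharmonicity.

## Two-sphere compliant-orbit model

State (φ₁, r₁, φ₂, r₂); sphere positions on circles of radius rᵢ about
centres a distance d apart, both orbits counterclockwise (relative
handedness is a convention; nothing downstream depends on it). Forces:
tangential drive `8πμA₀(1 + A₁ sin(νφ + φ₀))` and radial spring
`−λ(r − r₀)`. Velocities: Stokes self-mobility `F/6πμa` plus the Oseen
tensor from the other sphere — point-force level, no reflections, no
Faxén corrections, consistent with the Stokeslet treatment of the flow
stage. λ = ∞ is integrated as a holonomic constraint (radii frozen,
velocities projected onto the orbit tangent). Integrator: classical
fixed-step RK4 at 1000 steps per revolution (500 minimum enforced;
step-halving changes the final phase difference by < 10⁻⁴ rad), with a
per-step sphere-overlap guard.

An isolated rower has period `T = (3πa r₀/2A₀)/√(1−A₁²)`; at the default
drive this gives 38.1 Hz rather than the 33 Hz beat frequency the sphere
radius was nominally chosen to match — the drag law or averaging behind
that calibration is not reconstructable from the stated parameters, so
the closed form is reported as-is and the discrepancy flagged rather
than tuned away.

The rescaled phase `Φ(φ) = 2π·[∫₀^φ dφ'/F(φ')]/[∫₀^{2π} dφ'/F(φ')]`
makes an isolated rower's phase advance uniformly; δ_rescaled = Φ(φ₁) −
Φ(φ₂) is the synchronization observable (the raw geometric δ oscillates
within a beat even for synchronized rowers). Simulation grid: λ ∈ {1, 5,
∞} pN/μm × (ν, φ₀) ∈ {(0,0), (1,0), (1,π/2), (2,0), (2,π/2)} at the
measured drive, plus a flagella-inspired run (λ = R/l³ = 0.05 pN/μm,
a = 0.1 μm, A₀ = 143 μm²/s). All compliant runs synchronize; rigid ones
do not — synchronization here is an orbit-compliance effect, essentially
independent of the force-modulation profile.

`measure_sync_rate` fits `log|δ_rescaled|` vs t over the decaying window
and converts via the small-angle identity ρ = 4π²ε to
`κ_sim = ρ/(4π²f̄)`; for the flagella-inspired configuration κ_sim agrees
with the closed form `κ_spheres = (27μπa²l²ω̄/2R)·L⁻¹` within a factor
of two (κ_sim ≈ 0.023 vs κ_spheres ≈ 0.014), the expected level of
agreement for a point-force model with an O(1) geometric prefactor.

Initial conditions default to δ(0) = 0.5 rad with both radii at r₀; the
grid's qualitative outcome (compliant → sync, rigid → no sync) is
insensitive to this choice.

## Problem sizes

Defaults are sized so the demo runs in seconds and the full test suite in
well under a minute after JIT compilation: flow movies of 2–3 beats at
~10³ fps on ~450-point grids; pair records of 60–100 s at 1 kHz
(dt = 10⁻⁴ s integration); rower runs of 2–5 s (≈ 100–150 beats) at 10³
steps per beat. Every estimate's tolerance was chosen at these sizes;
all scale in the usual √N way if longer records are needed.
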