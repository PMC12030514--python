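# Methods

## The release model

`relkin` models drug release from a hydrated polymer matrix as transport
of a density of states ρ(z, t) in a half-space z ≥ 0 whose surface z = 0
is a perfect sink (released drug is instantly carried away by the
dissolution medium):

    ∂ρ/∂t = D ∂²ρ/∂z² + V ∂ρ/∂z,   ρ(z,0) = ρ₀,  ρ(0,t) = 0,  ρ(∞,t) = ρ₀.

`D` (length²/h) is a diffusion-type coefficient and `V` (length/h) a
constant drift speed **toward** the interface; in the multifractal
reading of the polymer–drug system both parameterize a transition
between scale regimes, but mathematically the model is plain
advection–diffusion with an absorbing boundary. The sign convention
matters: with drift toward the sink the release rate saturates at a
positive plateau, which is the regime the model is meant to describe.
(The mirrored-axis form, ∂ρ/∂t + V ∂ρ/∂z = D ∂²ρ/∂z², describes drift
*away* from the sink and decays to zero release; both appear in the
literature because the axis orientation is a free choice.)

The substitution ρ = n·exp(−Vz/2D − V²t/4D) reduces the problem to the
heat equation for n; the sink condition is enforced by the method of
images (odd extension of the transformed initial data, implemented in
`initial_condition_extended`), and the heat-kernel convolution of that
extended data (`greens_convolution_density`) evaluates to the closed
form (`density_profile`)

    ρ(z,t) = (ρ₀/2)·[ erfc(−(z+Vt)/s) − e^{−Vz/D}·erfc((z−Vt)/s) ],  s = √(4Dt).

The release rate is the Fickian flux magnitude at the interface
(`release_rate`)

    I(t) = ρ₀·[ (V/2)(1+erf x) + √(D/πt)·e^{−x²} ],  x = √(V²t/4D),

which diverges like t^{−1/2} at t → 0⁺ (the initial gradient at the sink
is infinite), decreases monotonically, and saturates at ρ₀V. The
crossover between the diffusion-dominated and drift-dominated regimes is
t_e = 4D/V² (`characteristic_time`; undefined at V = 0, where the whole
solution collapses to the textbook half-space result ρ₀·erf(z/s) and
I = ρ₀√(D/πt)). For t ≪ t_e, I(t) ≈ ρ₀[√(D/πt) + V/2]
(`release_rate_short_time`).

Cumulative release has the exact antiderivative

    M(t) = ρ₀·[ (Vt/2)(1+erf x) + √(Dt/π)·e^{−x²} + (D/V)·erf x ]
           →  2ρ₀√(Dt/π)  as V → 0,

exposed as `cumulative_release_exact` and used wherever speed matters
(fitting, generation). `cumulative_release` itself integrates I(t) by
adaptive quadrature under the substitution t = u², which removes the
integrable singularity at the origin; the two routes agree to ~1e−8
relative and are cross-checked in the tests.

Evaluation at t = 0 is a domain error throughout rather than a large
number: the closed forms are genuinely singular there.

## The finite-difference oracle

`fdsolver` solves the same initial-boundary-value problem directly on a
uniform grid with a θ-scheme (explicit Euler for testability;
Crank–Nicolson with a sparse-LU tridiagonal solve as the default). It is
the independent check on every closed form: agreement is asserted for
the density field, the boundary flux against I(t) over
t ∈ [0.01, 10]·t_e (≤ ~4e−4 relative at the default resolution), and
the ρ₀V asymptote.

Numerical choices, and why:

- **Advection discretization.** Centered differences when the cell
  Péclet number V·dz/D ≤ 2, first-order upwind above. This keeps the
  scheme second-order in space on resolved grids (the regime every
  oracle comparison runs in) while remaining monotone if a caller
  supplies a coarse grid.
- **Startup.** ρ(z,0) = ρ₀ conflicts with ρ(0,t) = 0; Crank–Nicolson is
  A-stable but oscillates on discontinuous data, so the march begins
  with two backward-Euler steps (Rannacher smoothing).
- **Reported flux.** One-sided second-order gradient D(4ρ₁ − ρ₂)/(2dz)
  at the sink.
- **Mass balance.** Checked with scheme-consistent telescoped boundary
  fluxes (including the advective inflow at the far boundary), which
  makes the discrete balance exact to rounding (~1e−12 relative); the
  physical one-sided flux differs from the telescoped one by O(dz²) and
  is deliberately not used for the balance.
- **Domain size.** z_max ≥ 10√(D·t_max) + V·t_max so the far boundary is
  effectively at infinity; enforced at solve time.
- **Stability.** dt ≤ dz²/(2D + V·dz) enforced for the explicit scheme.
- **Helper `boundary_flux_at`.** Builds a grid scaled to the query time:
  the depletion layer grows like √(4Dt) while diffusion dominates but
  stops at the steady advective width ~4D/V beyond t_e, so the finer of
  the two scales is resolved (100 cells across it, 4000 steps by
  default).

## Dissolution pipeline

A staged paddle-apparatus run draws small aliquots at scheduled times
and replaces them with fresh medium. The drug carried out by earlier
aliquots is added back when cumulative release is computed:

    M_k = V_vessel·C_k + Σ_{i<k} v_aliquot·C_i   (within a stage).

Two-stage runs (2 h gastric pH 1.2 with aliquots at 0.5/1/2 h, full
medium change, hourly intestinal pH 6.8 aliquots to 12 h; 3 mL aliquots;
37 °C; 60 rpm) are assembled into one continuous percent-of-drug-content
profile: release accumulated in completed stages carries over across the
medium change. The tablet vessel volume is not fixed by the protocol
description this emulates; 900 mL (the compendial Apparatus II
convention) is the configurable default. The single-stage powder preset
uses 500 mL, 100 rpm, 3 mL aliquots every 5 min for 60 min.

Drug content used for normalization: 70 mg for free-drug tablets, and
150 mg × guest mass fraction for complex tablets (18.3% for the 1:1
complex, 30.9% for 2:1, from the packaged 2005/2007 IUPAC atomic-weight
table). The packaged reference profiles are stored directly in percent,
so every percent-level result is independent of this choice.

Profile statistics run on the shape-preserving monotone cubic (PCHIP)
interpolant: exact at knots, bounded by neighbouring knots, ties in time
rejected. `time_to_threshold` bisects the interpolant for the earliest
crossing (the 80% level is the pharmacopoeial near-total-release
criterion); note the crossing can fall between observations — the
fastest packaged profile reaches 80% at 3.85 h, inside its unobserved
2–5 h gap. `similarity_f1_f2` implements the regulatory difference and
similarity factors on the common time grid. Measured-profile soft
invariants (values within [0, 100.5]%, decreases ≤ 0.5 percentage
points) raise a `DataQualityWarning`, not an error — 0.5 points is a
measurement-noise allowance, and model-generated truth curves may
legitimately exceed 100%.

## Synthetic data

`generate_raw_run` is constructed as the exact inverse of the pipeline:
from a true cumulative curve it computes the vessel concentration each
aliquot would have seen (accounting for prior removals and the medium
change), maps concentrations to absorbances through a calibration line
(default identity slope at 233 nm — a placeholder, since percent-level
results cancel the scale), and applies multiplicative Gaussian readout
noise (default relative SD 2%, seeded `numpy` generator). Zero-noise
generation followed by the pipeline reproduces any monotone truth curve
at the sample times to < 1e−9 (property-tested), which is what makes
every reconstruction result an end-to-end computation rather than a
stored answer.

What the generator emulates: the staged schedule, aliquot/replacement
mass bookkeeping, and readout noise. What it does not: inter-tablet
variability, pH-dependent solubility, apparatus hydrodynamics, or
spectral interference — so green round-trip tests demonstrate the
arithmetic of the pipeline, not robustness to those real-world effects.

The packaged fixture table stores only the percentages actually reported
for the six formulations (five time points each on the
{0.5, 1, 2, 3, …, 12} h grid); unreported cells stay missing rather than
being imputed. The two gastric-stage points at 0.5/1 h are never
reported; when a fixture is used as a truth curve the generator
interpolates monotonically from 0% at t = 0, which only matters for
round-trip tests. A provenance file records a source note per cell,
including the two places where the source text's formulation label is
inconsistent and the values are attributed to K-1 F-4 by context.

## Fitting and identifiability

`fit_release_model` minimizes Σ(A·M(t_k; V, D) − y_k)² by bounded
least squares (trust-region reflective), best of `n_starts` start points
drawn log-uniformly inside the bounds from a seeded generator;
deterministic given the seed, bit-identical on repeat. Residuals are in
percent and unweighted by default. Fits on profiles with three or fewer
points beyond the gastric stage raise an `IdentifiabilityWarning`.

Two structural facts shape how results should be read:

1. **Exact gauge degeneracy.** A·M(t; V, D) is invariant under
   (V, D, A) → (cV, c²D, A/c) for every c > 0 — the length unit of the
   half-space is arbitrary and nothing in a release curve pins it down.
   A profile therefore determines exactly two quantities: the crossover
   time t_e = 4D/V² and the diffusive amplitude A·√D (equivalently the
   saturation rate A·V = 2·A√D/√t_e). `FitResult` exposes these as
   `characteristic_time`, `diffusive_amplitude` and `saturation_rate`;
   the raw (V, D, A) triple is one arbitrary point on a zero-residual
   ridge and should not be compared across fits. Noiseless synthetic
   profiles recover both invariants to ~1e−6 relative; V = 0 truths are
   identified exactly (the ridge degenerates and V̂ pins to the bound).
2. **No plateau in the model family.** Since I(∞) = ρ₀V > 0, cumulative
   release grows without bound (linearly at late times, like √t at
   V = 0). Measured tablet profiles that plateau near 100% are therefore
   approximated best by the V → 0 member, with modest fit quality — the
   constrained optimum for the fastest packaged profile is r² ≈ 0.50.
   The model describes the rising portion of a release curve, not
   exhaustion of a finite dose.

Amplitude is free because the semi-infinite matrix holds unbounded total
mass, so percent of dose cannot be normalized analytically; only the
shape of the release law is fit.

## Problem sizes and defaults

Oracle comparisons use ~100 cells across the depletion layer and 2–4k
time steps per solve; Green's-function quadrature uses absolute
tolerance 1e−8–1e−10 with analytically derived truncation windows;
Monte-Carlo recovery uses 50 replicates at 5% noise; pipeline-inversion
sweeps 20 random monotone curves; noise calibration uses 200 replicates.
These sizes were chosen so each check resolves the quantity it asserts
by a comfortable margin.

## Known limitations

- One spatial dimension; no swelling, erosion, or moving gel-layer
  boundary.
- The fitted (V, D, A) coordinates are gauge-dependent (see above).
- Calibration-line estimation from standards is out of scope; slope and
  intercept are inputs.
- Fractal-dimension estimation from data is not attempted; V and D are
  effective transport parameters.
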