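# Methods

## Model

The axoneme is treated as a planar Euler–Bernoulli beam of length L driven
by outer-arm dyneins. Its transverse displacement y(x, t) (μm) is small, so
the curvature is C ≅ ∂²y/∂x² and arc length coincides with the axial
coordinate x. Three ingredients build the model:

1. **Single-motor moment.** A dynein anchored on doublet n exerts a
   minus-end-directed force −F x̂ at arm vector
   aₙ = (0, −a sin θₙ, a cos θₙ), θₙ = (40n − 20)°, producing the moment
   aₙ × (−F x̂). Only the ẑ component bends the beat plane; the ŷ components
   of a fully active ring cancel against the bridge constraint. Summing the
   eight armed doublets gives Σ aₙ = a ẑ, i.e. uniform activity produces no
   beat-plane bending — bending requires *differential* activity across the
   axoneme, captured by the differential force density
   f = f_l − f_r (DM6-9 side minus DM1-4 side, pN/μm).

2. **Pair localization.** Two opposite-side dyneins at different axial
   positions sandwich a region of constant moment aF; through M = −κC the
   bend lies strictly between them and the curvature outside is exactly
   zero. With the default parameters (below) the curvature is
   aF/κ ≈ 2 × 10⁻⁴ μm⁻¹ — bends of physiological size need hundreds of
   motors per wavelength.

3. **Normal forces from gradients.** Adjacent same-side dyneins with
   unequal forces produce a net transverse force a ΔF/δ, which balances the
   resistive-force-theory drag −ξₙ ∂y/∂t.

Combining these gives the moment-density balance

    a ∂f/∂x = −ξₙ ∂y/∂t − κ ∂⁴y/∂x⁴            (motors = drag + elastic)

whose traveling-wave solution y = y₀ sin[2π(x/λ − νt)] carries
f = f₀ sin[2π(x/λ − νt) + φ] with φ = arctan(1/Ma),
Ma = νξₙλ⁴/((2π)³κ), and f₀ = (y₀ κ k³ / a)√(1 + Ma²), k = 2π/λ. The
amplitude f₀ is not part of the published closed form; it follows by
substituting the two sinusoids into the balance and matching the sin/cos
components (the test suite verifies the substitution symbolically with
sympy, independently of the numerical code).

### Assumptions

- Planar, small-amplitude beats (|∂y/∂x| ≲ 0.3 rad; the package warns
  beyond that). The tangent-angle generalization valid for small angles but
  large amplitudes is not implemented.
- Outer-arm dyneins only, spaced δ = 24 nm; inner arms are subsumed into
  the effective force density.
- No tangential drag, inter-doublet friction, or basal compliance — only
  the three moment densities above.
- The traveling-wave analysis assumes an effectively infinite axoneme
  (periodic domain); finite-length boundary layers are ignored.

## Parameters

| symbol | meaning                      | unit      | default | rationale |
| ------ | ---------------------------- | --------- | ------- | --------- |
| κ      | flexural rigidity            | pN·μm²    | 800     | measured for intact axonemes; ≥ 20 single microtubules |
| ξₙ     | normal drag per length       | pN·s/μm²  | *none*  | depends on medium/geometry; must be supplied |
| a      | moment arm                   | μm        | 0.03    | inter-doublet spacing scale; structure-dependent, free |
| δ      | dynein axial spacing         | μm        | 0.024   | outer-arm repeat |
| F      | single-dynein force          | pN        | 5       | upper end of single outer-arm measurements |
| L      | axoneme length               | μm        | 10      | *Chlamydomonas* scale (comparable to λ) |
| λ, ν   | beat wavelength, frequency   | μm, Hz    | 10, *none* | λ ~ 10 μm typical; ν varies by species/condition |

Units are fixed to pN/μm/s internally (Ma is exactly dimensionless in this
system); SI converters exist only at the I/O boundary. Angles in the arm
formula are degrees as written; every other phase is radians internally,
degrees in displayed output.

## Numerical choices

- **Spatial derivatives**: spectral (FFT) on periodic grids; Fornberg
  finite-difference stencils (4th-order accurate, one-sided closures at the
  boundaries) otherwise. The 3rd/4th derivatives of the balance are exact
  to rounding for band-limited periodic data.
- **Temporal derivative**: spectral when the time grid covers whole beat
  periods (`periodic_in_t`), 2nd-order central differences (one-sided at
  the ends) otherwise. The spectral route is what lets the analytic
  traveling-wave pair cancel in the residual to better than 10⁻⁶ relative;
  central differences alone plateau near 10⁻³ at 32 frames/period.
- **Integration constant**: inverting ∂f/∂x fixes f only up to a constant
  per time slice. On periodic domains the constant is set by zero spatial
  mean; on finite domains f is anchored at the base by the static balance
  f(0) = −(κ/a) y‴(0).
- **Quadrature**: trapezoidal cumulative sums everywhere (O(h²), exactly
  testable against closed forms). Point moments land on the nearest grid
  node, so pair scenarios need grid spacing ≤ half the motor separation.
- **Phase extraction**: argument of the cross-spectrum at the fundamental
  (dominant) spatial mode, summed coherently over frames; harmonics are
  ignored because the model's solutions are single-mode. Sign convention:
  `extract_phase(A, B)` > 0 means A leads B in +x.
- **Noisy data**: optional Savitzky–Golay pre-smoothing (default window 11
  samples, order 4) before differentiation; off by default because the
  spectral phase estimate only sees noise in the fundamental mode and is
  already robust at the 1%-noise scale.
- **Degenerate inputs**: all-zero fields raise a model-inconsistency error
  in phase extraction; a force-vs-amplitude phase outside (0, π/2] (which no
  traveling-wave solution can produce) does the same rather than returning
  a negative Ma. A standing (time-averaged) spatial component above 10% of
  the beating amplitude triggers a warning, since superposed static
  curvature confounds the phase analysis.

## Design choices made where the design was open

- **Sperm ↔ Chlamydomonas numbering.** Only two anchors are structurally
  fixed: sperm DM1 ↔ cDM5, and the bridge pairs {DM5, DM6} ↔ {cDM1, cDM2}
  as sets. No rotation or reflection of the 9-ring satisfies both — the two
  conventions' origins are offset by half a doublet spacing (rotating the
  axoneme 180° about its long axis lands each doublet *between* two
  positions of the other numbering). The shipped permutation table is
  therefore one consistent completion (ring reversal n ↦ 6 − n mod 9, with
  the images of DM4 and DM6 swapped), documented as a choice, not an
  established fact.
- **Full-ring moment sign.** With the right-handed convention used for the
  single-motor moment (ĵ × (−F î) = +F k̂), the fully active ring's moment
  is a ẑ × (−F x̂) = −aF ŷ. The package follows the algebra; the physically
  meaningful statement — the ẑ component is exactly zero, so a uniform ring
  bends nothing in the beat plane — is what the tests assert.
- **Unbalanced static pairs.** A pair with F_left ≠ F_right leaves a net
  moment distal to both motors; in statics that is a rigid-body rotation,
  not a bend. `pair_moment_profile` still returns the (well-defined)
  piecewise-constant moment, but the shape-producing path (`pair_bend`)
  refuses unbalanced pairs instead of guessing a distal shape.
- **Straight-region threshold**: |C| < 10% of the slice maximum, exposed as
  a parameter — any cutoff between "bend" and "straight" is a convention.
- **Model/Results shape**: the inverse problem is exposed statsmodels-style
  (`MachinModel(waveform, params).fit() → MachinResults` with `summary()`),
  since it is literally a mechanistic model fitted to waveform data; the
  forward building blocks remain importable functions.

## What the synthetic generator does and does not emulate

`synthetic.generate` produces exactly the structure the model assumes:
single-mode traveling sinusoids on periodic grids, optionally with additive
i.i.d. Gaussian noise (one explicitly seeded stream per call; default grid
128 points/wavelength × 32 frames/period, comfortably inside the
derivative-accuracy requirements and fast). Real beats are none of these
things: they are finite with basal/distal boundary conditions,
non-sinusoidal (notably the asymmetric wild-type *Chlamydomonas* beat,
whose static curvature component the package only warns about),
three-dimensional over long distances, and their noise is neither additive
nor white. Passing the recovery tests therefore demonstrates the
correctness of the inference machinery under the model's own assumptions —
not that Ma can be estimated to 5% from experimental kymographs.

## Problem sizes

The test suite and the reproduction script run on desk-scale grids — 128
points per wavelength × 32 frames per period for field computations, 2001
nodes for discrete pair scenarios, 20 noise realizations per condition for
the recovery studies — chosen because the quantities of interest (phases at
the fundamental mode, one-significant-figure curvatures) are already
converged far below their reported precision at these sizes.

## Known limitations

- Ma recovery assumes a single dominant spatial mode; multi-mode or
  frequency-modulated beats are outside the estimator's contract.
- At Ma ≫ 10² the phase saturates near 0 and the inversion Ma = 1/tan φ
  becomes ill-conditioned (a 0.5° phase error is a ~tenfold Ma error at
  Ma = 100); estimates there are qualitative.
- The localization report labels regions at a single frame; it does not
  track bend propagation over time.
- Fourth-derivative noise amplification means un-smoothed inference from
  experimentally noisy data degrades quickly above ~1% amplitude noise.
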