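# Methods

`tipwall` models tip growth of the *Ectocarpus* apical cell as the creep
of a thin viscoplastic shell under turgor. This note records the model,
the numerical choices, what the synthetic data emulate, and the design
decisions taken where the problem was genuinely open.

## Model

The cell is an axisymmetric surface described by its half-meridian:
arc length `s` from the tip, radius `r(s)`, normal angle `φ(s)`, and the
two principal curvatures `κ_s` (meridional) and `κ_θ = sin φ / r`
(circumferential, with the regular limit `κ_θ → κ_s` at the tip). For a
pressurized membrane of thickness `δ(s)` the in-plane stresses are

    σ_s = P / (2 δ κ_θ),     σ_θ = P (2 κ_θ − κ_s) / (2 δ κ_θ²),

so `σ_θ = σ_s` at the tip and `σ_θ = 2 σ_s` on a cylinder. The scalar
stress entering the yield criterion is the generalized plane-stress von
Mises form `σ_e = sqrt(σ_s² + σ_θ² − 2ν σ_s σ_θ)` with flow coupling
`ν = 1/2` for a transversely isotropic wall (AFM imaging shows the
cellulose microfibrils of the tip have no preferred in-plane direction).

The wall creeps as a Lockhart material: effective strain rate
`ε̇ = Φ (σ_e − σ_y)` above yield, zero below, distributed over the two
directions by the anisotropic flow rule
`ε̇_θ = ε̇ (σ_θ − ν σ_s)/σ_e` (and symmetrically for `ε̇_s`). Because
the surface expands only along its normal, `ε̇_θ = V_n κ_θ`, which gives
the simulated normal velocity

    V_n = Φ (σ_e − σ_y) (σ_θ − ν σ_s) / (σ_e κ_θ)        (σ_e > σ_y).

Conversely, if growth is *observed* to be self-similar (pure axial
translation at speed `v`, so `V_n = v cos φ`), the strain rate expected
from geometry alone is

    ε̇* = K κ_θ σ_e / (σ_θ − ν σ_s) · V_n,     K = 1 in µm/MPa/min,

and the claim "the wall has spatially constant plasticity" becomes the
claim that `ε̇*(s)` is an affine function of `σ_e(s)`: slope `Φ`,
abscissa-intercept `σ_y`. `lockhart_fit` is an ordinary least squares of
`ε̇*` on `σ_e` restricted to the yielding branch (points with `ε̇*` above
1% of its maximum; the threshold is relative because the printed
criterion is unit-ambiguous).

Turgor comes from incipient plasmolysis: the external osmolarity at
which half the cells plasmolyze estimates the shrunken cell's internal
osmolarity; multiplying by the measured volume-shrink ratio
`x = V_plasmo/V_normal ≈ 0.658` and converting by 410 mOsm L⁻¹ per MPa
against seawater (1100 mOsm L⁻¹) gives `P = (x·c_pl − 1100)/410 ≈ 0.495`
MPa. Note the subtraction amplifies relative errors in `c_pl` and `x`
about 6.4-fold into `P`; this is a property of the assay, not of the
estimator.

Wall thickness follows the Pearson-family gradient
`δ(s) = δ_max − (δ_max − δ_min)(1 + 3 (s/s_1/2)²)^(−1/2)`
(δ_min = 36.2 nm at the tip, δ_max = 591 nm, midpoint s_1/2 = 16.81 µm);
Gauss and Lorentz variants with the same three parameters are provided
for the family comparison. Apparent TEM thickness `w` measured on a
section at apparent inner radius `a` is corrected for off-meridian
sectioning by the exact circle-chord inversion
`δ = R − sqrt(a² + R² − (a+w)²)` with `R = 3.27` µm; the correction can
only reduce the apparent value.

## The self-similar (traveling-wave) shape

Self-similarity requires the flow-rule velocity field to equal
`v cos φ` at every point. At fixed `(P, Φ, σ_y, ν, v, δ(s))` this is one
scalar equation per point in the single unknown `κ_s`, which
`steady_state_profile` solves by bracketed root finding inside a
fixed-step RK4 integration of `dφ/ds = κ_s`, `dr/ds = cos φ`. The tip
curvature follows from a closed-form quadratic.

Two findings about this fixed point shaped the package:

* At the measured parameter point (Φ = 2.51×10⁻³ MPa⁻¹ min⁻¹,
  σ_y = 11.18 MPa, the fitted gradient, P = 0.495 MPa, v = 2.5 µm h⁻¹)
  the exact traveling wave is a dome of tip curvature 0.316 µm⁻¹ that
  flares into a trumpet approaching the marginal-stress radius
  `R_∞ = 2 σ_y δ_max / (√3 P) ≈ 15` µm, rather than closing onto a
  3.27 µm cylinder. On this shape the Lockhart regression returns
  exactly (2.51×10⁻³, 11.18) with r² = 1.000.
* No choice of `(Φ, σ_y)` yields an exactly steady *compact* cell of
  radius 3.27 µm with this thickness gradient: trajectories that close
  at small radius leave an early shank that still exceeds yield
  (`√3 P r / 2δ > σ_y` just behind the dome), which then creeps. The
  observed cell is therefore *approximately* self-similar — consistent
  with the cell's dome-weighted growth residual being small but nonzero —
  and the exact mathematical traveling wave of the model is the flared
  shape.

Consequently the simulator and Lockhart/bootstrap validation use the
traveling wave as the known ground truth (it is the one configuration
where the optimizer's target is exactly recoverable), while the
contour-measurement pipeline is exercised on a spherical-cap dome of tip
curvature 0.27 µm⁻¹ blended into the R = 3.27 µm cylinder, which carries
the observed peak effective stress `P/(2 δ_min κ_tip) ≈ 25 MPa`. The cap
dome, not being a mechanical steady state, also serves (with a uniform
0.25 µm wall, P = 0.2 MPa, v = 540 µm h⁻¹, flat-tipped, R = 3.9 µm) as
the pollen-tube contrast whose stress–strain relation is visibly not a
single Lockhart line.

## Simulator numerics

The contour is discretized at constant arc spacing `h` (default
0.05 µm). Each step: stresses → `V_n` → displacement `V_n dt` along the
outward normals → monotone-cubic (PCHIP) respline → resampling at `h`.
Numerical choices that matter, all found the hard way:

* **Stability.** Curvature-driven normal motion is diffusive with
  coefficient `D = max |∂V_n/∂κ_s|` (≈ 0.3 µm² min⁻¹ near the tip,
  larger on wide flanks). The step enforces the explicit-scheme limit
  `dt ≤ cfl · h²/(2D)` (cfl = 0.8), measured each step by a vectorized
  perturbation. The nominal 1 nm-per-step tip calibration is kept as an
  upper bound on the tip advance.
* **Resampling.** An ordinary interpolating cubic spline overshoots
  grid-frequency wiggles by ~25% per knot-phase crossing and therefore
  *amplifies* them without bound over tens of thousands of resampling
  passes; PCHIP never overshoots and damps them.
* **Apex handling.** The tip point is re-located every step as the
  axial intercept of the even quartic `x = a + b r² + c r⁴` fitted
  through the near-tip points; a pinned tip point carrying its own
  velocity estimate accumulates a sub-nanometre ordering bias against
  its neighbours and eventually folds the apex. The tip curvature in
  `geometry_from_points` comes from the same symmetric fit idea
  (mirrored central differences through the axis).
* **Moving window.** With `s_window` set, the profile is truncated a
  fixed meridional distance behind the current tip each step, the rear
  is replenished along the end tangent when the shank is static, and the
  rearmost 4 µm follow the kinematic translation field `V_n(0) cos φ`
  instead of the flow rule. The far flank cannot influence the dome
  (material advects backwards out of the window) but would otherwise
  dominate the stability limit.

Self-similarity of a run is scored by
`rD = Σ w(s) d(s) / Σ w(s)` with `d(s)` the planar distance between
same-`s` points of the final contour and the initial contour translated
at the *expected* speed (`v · elapsed`), and the dome-focused weight
`w(s) = exp(−(s/1 µm)² ln 2)`; `log(rD)` is the natural logarithm. The
weight's printed sign is corrected here: a weight growing with `s²`
would be dominated by the far shank, the opposite of "maintain the dome
shape". Because the reference is translated at the expected speed, rD
penalizes both shape distortion and rate error. A 25 µm run of the
traveling wave at `h = 0.05` µm reproduces `log(rD) ≈ −8` and a
simulated duration of 10.0 h.

`optimize_parameters` descends on `log(rD)` by compass search in
`log(Φ), log(σ_y)` (probe step 0.05, deterministic order Φ then σ_y,
step halving on failure). The surface is a narrow diagonal valley — the
rate-matching condition `Φ(σ_e−σ_y) ≈ const` — where finite-difference
gradients are unreliable; starting from the Lockhart regression, as the
study did, the search confirms the start as the optimum.

## Deposition flux

Conservation of wall volume in the frame travelling with the tip gives
the deposition rate (wall volume per surface area per time)

    D(s) = v_m dδ/ds + δ (ε̇_s + ε̇_θ),
    v_m = v sin φ,   ε̇_s = V_n κ_s,   ε̇_θ = V_n κ_θ,

with `dδ/ds` taken analytically from the fitted gradient. The
*kinematic* strain rates are used (they are what mass conservation
derives); they equal the constitutive ones only where growth is exactly
self-similar. This makes the global identity
`∫ D · 2πr ds = 2πR δ(s_end) v` hold to quadrature accuracy, and
`→ 2πR δ_max v` once the profile extends far enough for `δ` to saturate
(the Pearson tail is long: 99% of δ_max is only reached near s ≈ 900 µm).
With the gradient, deposition peaks at the base of the dome (s ≈ 4–5 µm)
and persists far into the shanks; with a uniform wall it peaks ~3 µm
from the tip and vanishes behind the dome. Both per-area and per-length
(`D·2πr`) columns are reported since the two conventions differ.

## Synthetic data

Every pipeline input can be generated with known ground truth
(`SynthesisSpec`; one mandatory seed, per-generator independent
substreams, byte-identical reruns). Defaults are the measured apical-cell conditions:

* **Contours** — 17 cells, hand-tracing emulated by sampling the truth
  meridian every 0.2 µm over ±15 µm and jittering 0.05 µm (≈ one pixel)
  along the local normal. The auto-chosen smoothing-spline penalty
  estimates the tracing noise from second differences (calibrated for
  noise acting along the normal). The pooled windowed mean curvature
  (window 0.2 µm, step 0.05 µm, both sides of every cell pooled) is
  low-passed at 0.5 µm before reconstruction; its residual grid-scale
  sampling noise would otherwise dominate the stress–strain scatter,
  while genuine curvature features are several µm wide.
* **Thickness** — 2500 points over 15 cells spanning ±70 µm; each cell
  is sectioned at one meridian offset `|N(0, 0.8 µm)|` (bias inverted
  exactly by the correction), carries a lognormal per-cell wall-scale
  factor (σ = 0.04; real cells differ in overall thickness, and this
  shared factor is what makes δ_min and δ_max co-vary across bootstrap
  replicates), and multiplicative lognormal measurement noise (σ = 0.08,
  matching the ~0.04 µm residual error of the fit).
* **Plasmolysis** — binomial counts, logistic response of width
  150 mOsm L⁻¹ around c_pl = 1980, 10 osmolarities × 150 cells × 3
  experiments; volume pairs for the shrink ratio (n = 9, 4% cv). The
  auxin condition uses the c_pl consistent with P = 0.186 MPa and a
  growth-rate factor of 2.0 (the factor implied jointly by the auxin
  plasticity values and turgor).
* **Beads** — surface beads advect along `ds/dt = v sin φ` in the tip
  frame (they stop once they reach the static shank, so frames are
  45 min apart to catch several displacements); angular noise rotates
  each observed inter-frame displacement (sd 0.52 rad, the measured
  angular spread). True crossing angle: π/2.
* **FRAP** — 6 pre-bleach frames, bleach at t = 0, 50 recovery frames at
  1 s; exponential recovery per zone (τ fastest in zone C at the dome
  base, all τ within the identifiable half of the 50 s window),
  multiplicative spontaneous photobleaching shared with the unbleached
  reference, drifting background, Gaussian noise at SNR 10.

What passing on these data does **not** show: robustness to tracing
errors that are correlated along a contour, to non-axisymmetric cells,
to TEM section curvature (the correction assumes a locally cylindrical
cell, which is wrong within the dome), or to FRAP recoveries that are
not single-exponential.

## Problem sizes used by tests and the acceptance script

Bootstrap: 150 replicates in the test suite, 3000 in the acceptance
script. Simulations: tests run 2–8 µm of growth at 0.15 µm spacing;
the acceptance script optimizes over 12 µm at 0.15 µm spacing and then
runs the full 25 µm at 0.05 µm spacing (~600 recorded frames). These
sizes are the package's own defaults for desk-scale reproduction; all
scale up by configuration.

## Known limitations

* The strict flow rule admits no exactly steady compact cell at the
  measured gradient (see above); the simulator's validated ground truth
  is the flared traveling wave, and compact-cell runs are meaningful
  only dome-locally (which the rD weight enforces).
* `(Φ, σ_y)` are practically identifiable only along the rate-matching
  valley from rD alone; the Lockhart regression supplies the missing
  direction. This mirrors the elongated valley of the parameter-scan
  heatmap.
* The flow-rule domain requires `κ_s < (2−ν) κ_θ`; measured (noisy)
  profiles occasionally violate it pointwise, and the pipelines mask
  such points rather than abort (`mask_invalid=True`).
* Turgor inherits a ~6.4× error amplification from the osmotic
  subtraction; expect ±8% scatter on P at the assay's sample sizes.
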