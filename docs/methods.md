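# Methods

## Acquisition model

The simulator produces per-view detector intensities
`I = (1 − B)·P + S (+ Poisson)` where `P = I₀ exp(−∫μ dl)` is the
ray-traced primary fluence, `S` a smooth scatter field, and `B` the
blocker indicator. Geometry is a circular full-fan orbit: source radius
`sad` (default 1000 mm), flat centered detector at `sdd` (default
1500 mm), detector rows along the rotation axis z (the blocker motion
direction), angles in degrees with view 0 at 0°. Indices are 0-based,
strip intervals half-open, and the axial coordinate of row r is
`(r + 0.5)·pitch` from the row-0 edge.

Line integrals use an exact Siddon-style traversal (per-voxel intersection
lengths); the same kernel generates the ART system-matrix rows, so
simulation and reconstruction share one projector by construction.

### Scatter generator

Scatter is modeled as the scatter-to-primary-ratio (SPR)-scaled Gaussian
low-pass of the fluence deficit `I₀ − P`, normalized so
`mean(S)/mean(P) = SPR` over the object shadow (pixels with >10% deficit).
Defaults: SPR 1.0 (a realistic mid-size-object value without an
anti-scatter grid), blur σ = 40 mm at the detector. This generator has the
two properties the correction method assumes — slow variation along the
detector and across adjacent views — and a closed-form oracle (a blurred
step edge is an erf profile), which is why it is used instead of a
transport simulation. What it does **not** emulate: object-dependent
scatter kernels, beam hardening, detector glare/lag, half-fan geometries.
Tests passing on it show the estimator recovers any smooth low-frequency
field from moving blocked samples; they do not certify performance on the
high-frequency tails real scatter can have near dense anatomy.

### Blocker

Strips are specified in detector-plane millimetres (projected), with
`projected_strip_width`/`physical_strip_width` converting through
`sdd / source-to-blocker distance`; "pitch" is read as the unblocked gap,
so equal width and gap blocks half the rays. Motion is a triangular wave
of the pattern offset (default amplitude = one strip period, period
40 views). A `coverage` interval models the finite blocker board — strips
exist only inside it, and it moves with the offset. Masks come in two
variants: `blocked`, and `eroded` with a 2-pixel penumbra margin per band
side (the paper-level sources do not state how near-edge pixels are
excluded; 2 px removes the partial-shadow pixels of the simulator and of
a ±1 px detection error).

## Edge detection

*Two-point*: threshold crossings of 5-column-median axial profiles at two
probe columns, straight line through each pair, mismatch in crossing
counts is a hard error carrying the view index. A `+Δ` row fault can be
injected at the second probe in a seeded fraction of views to study error
propagation (`Δ/(c₂−c₁)` rows per column of tilt).

*Minimum envelope + adaptive threshold*: the envelope is the pointwise
minimum of the adjacent views' profiles (each row is blocked in at least
one member when the motion covers the strip period). The per-row threshold
is `t(z) = S(z) + α (U(z) − S(z))` with `S` the moving-average-smoothed
envelope (window = half a strip period) and `U` the local unblocked level.
`U` is estimated by a grey closing over one strip period: a plain running
maximum latches onto bright rows where the object shadow falls off axially
and misclassifies their dim unblocked neighbours, while the closing fills
the (narrower) blocked bands, recovers the unblocked level even for bands
truncated at the detector edge, and ignores narrow bright outliers.
α defaults to 0.5 (midway between the scatter and total levels); band
boundaries from threshold runs are refined per column within ±3 rows and
fitted with least-squares lines.

## Scatter estimation

Per lateral column, the eroded blocked-band samples of the neighbor views
are pooled and fitted with cubic B-splines on uniform clamped knots by
ridge-stabilized normal equations (relative ridge 1e-8, two iterative
refinement steps against the unridged system, so the solution matches a
QR solve to better than 1e-8; for a linear least-squares problem a direct
solve is the one-step limit of any Newton iteration). Columns sharing a
sampling pattern are solved jointly in one multi-RHS call.

Numerical choices:

* knots span the **sampled** axial range, not the full detector — with
  full-range knots any view whose bands do not reach one detector end is
  rank-deficient by construction; an unsupported basis function raises an
  error naming the empty knot span;
* K defaults to (sampled span / strip period) + 4;
* evaluation clamps to the outermost sample (end-value extrapolation);
* fields are smoothed laterally with an 11-column moving average
  (the axial fits are per-column; the lateral dimension is otherwise
  independent);
* `n_adjacent` is odd, the window is centered (shifted at scan ends), and
  an angular span cap rejects neighbor sets wider than `max_span_deg`
  (default 3°, the regime where scatter is effectively common across the
  members). `n_adjacent = 1` reproduces the single-view estimate
  bit-for-bit.

Correction computes `p̃ = −ln(max(I − S, 10⁻⁶ I₀)/I₀)` on unblocked
pixels, counts floor clamps, warns when scatter exceeds the total on a
majority of pixels, and (by default) excludes one extra guard pixel on
each side of a blocked band from the reconstruction-valid mask, so a
±1 px detection error cannot feed a scatter-only pixel to ART.

## Reconstruction

Zero-initialized volume; per iteration one sequential Kaczmarz sweep over
all valid rays (views in bit-reversed order so successive views are
maximally separated, rays row-major within a view; relaxation λ = 0.5),
non-negativity clamp, then up to `tv_steps` (default 10) steepest-descent
steps on the isotropic TV functional. The TV value uses
`Σ (sqrt(|∇μ|² + δ²) − δ)` with δ = 1e-8, so a constant volume evaluates
to zero exactly while the gradient stays smooth. The TV step length is
`tv_step_scale` (default 0.2) times the norm of the preceding ART update
(adaptive-steepest-descent coupling), safeguarded by halving-on-increase
so the TV value never rises across a call. Stopping: residual RMS below a
user ε when given, otherwise a plateau (relative change < 1e-4); three
consecutive passes with the residual growing by more than 1% abort with
the residual trace. Iteration counts, λ, ε and the TV schedule are not
prescribed by the method's sources; the defaults above are this package's
choices and are exposed in the configuration.

## Evaluation

`HU = 1000 (μ − μ_water)/μ_water` with μ_water = 0.02 mm⁻¹ (config
exposed). ROI statistics use the population STD (divide by N), RMSE is
the per-voxel root mean square CT-number difference against the rasterized
ground-truth phantom, which plays the role of the diagnostic-CT benchmark.
Reports are tidy tables with columns ROI, method, mean, STD, RMSE.

## Fixtures and problem sizes

All canned fixtures use a desk-scale scan — 60 views over 360°, a 144×144
detector at 2 mm pitch, a 64³ reconstruction grid at 3 mm — sized so a
full pipeline runs in tens of seconds and the complete comparison
(no-correction / SVSC / MVSC) in about a minute. Two consequences of the
coarser-than-clinical view spacing are deliberate fixture choices:

* a 5-view neighbor set spans 24°, so the fixtures raise `max_span_deg`
  to 30°; this is valid here because the simulator's scatter varies slowly
  with gantry angle by construction, whereas a clinical 670-view scan
  satisfies the default 3° cap with the same 5 views;
* the blocker motion period is shortened (20 views; boundary fixture:
  8 views with amplitude two periods) so adjacent views' offsets differ by
  whole pixels and the multi-view sampling gain is realized with 60 views.

Simulation runs on its own grid (128×128×96 at 2.5 mm, axially extended
beyond the detector field of view), not on the reconstruction grid:
reconstructing on a different discretization than the one that generated
the data avoids the inverse crime, and full axial coverage removes
bright partial-path rows at the detector margins that are artifacts of a
truncated volume rather than of the scene.

The three fixtures: **clean** (water cylinder with central air insert,
full blocker coverage), **boundary** (short, axially offset cylinder whose
shadow extends past the blocker board in the lowest-offset view, so that
view must extrapolate exactly where the scatter transitions), and
**robustness** (wide 95 mm-radius cylinder with ~1.2:1 blocked/unblocked
contrast at the center, probes 20 columns apart near the bright edge, and
a +3-row fault injected at the second probe in 10% of views). The
two-point threshold (0.11·I₀) sits between the blocked and unblocked
levels at all columns of that phantom.

## Known limitations

Full-fan geometry only (half-fan lateral detector offsets are an
extension point); monochromatic beam, no detector blur or lag; the
scatter generator is phenomenological (see above); straight blocker
edges; the ray tracer is exact for the voxel decomposition, but a
voxelized curved boundary limits agreement with analytic chord integrals
to roughly the voxel-to-diameter ratio (≈0.8% of the peak integral on a
64³ grid, a few % for rays tangent to the surface) — a property of any
piecewise-constant rasterization, not of the projector.
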