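# Methods

## Geometry and model

All computations assume an ideal point X-ray source at distance `S`
above a flat detector, with the central beam perpendicular to the
detector through the image center. Heights are measured from the
detector toward the source, lengths in millimetres, magnification as a
percentage factor `F = 100·S/(S − H)` (100 = life size).

### Marker height from the projected ellipse

A sphere of radius `r` at height `H` and radial distance `ρ` from the
central beam casts an elliptical shadow. The package inverts the
measured long axis `b` and measured radial displacement of the ellipse
center `a₀` through the closed form

```
H = S − sqrt( r²(1 + 2S²/b²) + (2rS/b)·sqrt(r²S²/b² + a₀²) )
```

On the central beam this is the exact inverse of the tangent-cone
projection; off-axis it is a very close approximation (the package's
own exact forward projector puts the inversion error below 0.03 mm for
heights 100–500 mm and offsets up to 200 mm, comfortably within the
0.5 mm envelope the tests assert). The measured displacement is itself
magnified, so the solver iterates

```
disp_n = disp_0 · (S − H_n)/S ;  H_{n+1} = H(b, disp_n)
```

until the factor changes by less than `tol` (default 1e-4 percent
points) between passes. The map is strongly contractive — two to three
passes suffice in practice — and at least one pass is always performed,
so a zero-displacement measurement converges after the single mandatory
pass. `max_iter` defaults to 100 and exists only to bound pathological
inputs; non-convergence raises with the last iterate attached.

### Pipeline

Stages of `run_pipeline`:

1. **Scalar measurements from landmarks.** Lateral: `a = |A−B|`,
   signed hip-center gap `c = x_C − x_D`, marker-to-hip-midline
   distance `d = |x_B − (x_C+x_D)/2|`. A.p.: `h = |O−P|`, lateral
   offset `i = |x_P − x_O|` with its patient side, inter-hip distance
   `m = |x_Q − x_R|` (zero `m` is rejected as degenerate).
2. **Marker heights per view** via the iterative solver: the a.p. view
   yields `H_ECM`; the lateral view yields the lateral marker height,
   used only to calibrate lateral distances.
3. **Distance calibration.** The paper plane of each distance is not
   the same: `d` and `c` are divided by the lateral marker factor (the
   marker is the only calibrated object in that view), `i` and `h` by
   the a.p. marker factor, and `m` — which lies in the hip plane being
   solved for — by the hip-plane factor through an **outer fixed
   point**: start from the a.p. marker factor, compute `m_cal`, `α`,
   `y_correction`, `H_Hip`, `F_Hip`, and repeat until `|ΔF_Hip| <
   1e-4`. This mirrors the inner displacement iteration and converges
   in a handful of passes.
4. **Rotation estimate** `α = asin(|c_cal|/m_cal)` (degrees at the
   interface, radians internally); `|c_cal| > m_cal` raises, as it
   signals gross mis-landmarking.
5. **Direction resolution.** The offset direction in the lateral view
   follows from the offset side and the facing direction (offset toward
   the patient's right is toward the source iff the patient faces
   left). The rotation direction is not directly observable from the
   stated landmark set; the package infers it from the horizontal order
   of the projected hip centers: with images viewed from the source,
   *the right hip projecting at greater image-x than the left hip means
   rotation toward the source*, a relation that is independent of the
   facing direction (derived analytically from the rotation geometry;
   verified by the forward simulator round trip). An override flag
   exists for cases where the operator knows the direction.
6. **Correction** `y_correction = (d_cal + s·sin(α)·i_cal)/cos(α)`,
   `s = s_offset·s_rotation` with +1 toward the source. Flipping both
   directions leaves the result unchanged (sign-product symmetry).
7. **Result** `H_Hip = H_ECM − y_correction`, `F_Hip = 100·S/(S −
   H_Hip)`; a hip plane outside `[0, S)` raises an
   inconsistent-geometry error naming the stage.

Degenerate perfect lateral (`c = 0`): `α = 0` and the rotation
direction is set to `toward_source`; the choice is inert because the
correction reduces to `y_correction = d_cal`.

### Uncorrected-error simulation

The standard model fixes empirical mean measurements (S = 1150,
r = 12.5, a.p. ellipse axis k = 35, a.p. marker displacement h = 10,
d = 110, m = 150 mm; lateral entries a = 200, b = 35 mm are carried for
completeness but do not enter the error computation). `d` is treated as
the already-calibrated true marker-to-hip-plane distance — the
interpretation under which the zero-rotation factor evaluates to 123.45
and the whole published error grid reproduces cell-for-cell.

For rotation `α` and offset `i` (toward-source branch), the naive
pipeline still reports `F_ref = F(H_ECM − d)` while the true rotated
geometry has distance `y_rot = (d + i·sin α)/cos α` and factor
`F_rot = F(H_ECM − y_rot)`; the error is `F_ref − F_rot` in absolute
factor points and as a percentage of `F_ref`. Report rounding matches
the published precision: factor 2 dp, absolute errors 3 dp, relative
errors 1 dp. The grid spans 0–30° in 1° steps × offsets {0, 20, 60} mm.

Consistency across modules is a test invariant: on a synthetic scene
whose rotated lateral image measures exactly `d = 110`, the uncorrected
pipeline's deviation from scene truth equals the simulated error cell
to 1e-6, and the corrected pipeline cancels it.

## Synthetic-data generator

`forward.generate_case` draws scenes uniformly from ranges centred on
the standard model: inter-hip distance 140–160 mm, marker-to-hip-plane
distance 90–130 mm, lateral offset 0–60 mm, rotation 0–30° (the range
the correction claims to handle), hip-plane height 190–250 mm, lateral
pivot height 280–350 mm, modest beam-centering offsets; facing, offset
side and rotation direction are drawn uniformly. Seeds are mandatory
and cases are bit-identical for identical seeds.

Two projection fidelities are generated:

- **paper_model** — the measurement model the correction formulas
  assume exactly: per-point pinhole in the a.p. view, weak perspective
  at the marker plane in the lateral view (so rotated in-plane
  trigonometry is undistorted by depth), and the marker ellipse axis
  obtained by numerically inverting the height formula (Brent's method,
  1e-12) at the true radial displacement. Under this fidelity the
  corrected pipeline recovers truth up to iteration tolerance; the
  tested <0.1% round-trip bound is therefore a check of the whole
  chain's internal consistency, not of robustness to unmodelled physics.
- **full_pinhole** — exact per-point pinhole projection and tangent-cone
  sphere shadows in both views. This includes the depth–magnification
  coupling that the trigonometric correction ignores; residuals
  (typically a few tenths of a percent, up to ~1% at 30° rotation with
  large offsets) are reported, not asserted, except at zero rotation
  where recovery is still better than 0.1%.

The rotation pivot defaults to the inter-hip midpoint and is
configurable, since real pelvic rotation has no single well-defined
axis; `paper_model` results are pivot-independent, `full_pinhole`
results are not.

What the generator does **not** emulate: landmark identification noise,
ellipse-fitting error, detector tilt, finite focal spots, scatter, and
anatomical asymmetry of the two hips. Passing round-trip tests
therefore demonstrate the correctness of the geometry and correction
algebra, not clinical accuracy on real films.

## Numerical choices

- Angles are degrees at every interface, radians internally.
- The a.p. image x-axis convention (patient-right at negative x) is a
  config flag; the lateral facing field ties the two views together.
- Factor/height conversions are exact algebraic inverses (tested to
  1e-9 relative).
- Rounding of reported tables uses Python's banker's rounding at the
  stated precision; the reproduction tests confirm this matches the
  published grid for every cell.
- Fixed-point tolerances (inner 1e-4 on the factor, outer 1e-4 on
  F_Hip) follow the method's definition; both are configurable and the
  cross-module tests tighten them to 1e-11 where exact agreement is
  asserted.

## Known limitations

- The closed-form height inversion is approximate off-axis; the error
  is negligible at clinical displacements but grows with very large
  offsets (>300 mm).
- Beam-divergence effects in the lateral view (hips at different
  depths with the pelvis off the central beam) masquerade as a small
  spurious rotation; with a centred beam or small offsets the induced
  factor error is well below 0.1%.
- The rotation-direction inference assumes a known image orientation
  (viewed from the source); a mirrored display flips the rule, which is
  why an override flag is provided.
- Only rotation about the vertical axis is modelled; pelvic tilt and
  obliquity are out of scope.
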