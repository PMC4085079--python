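# Methods

## Model

`figdig` treats a digitized figure as an affine image of an ideal chart.
The user supplies four calibration pixels — p₁, p₂ on the y-axis with
values y₂, y₁ and p₃, p₄ on the x-axis with values x₁, x₂ — defining
axis vectors a = p₁ − p₂ and b = p₄ − p₃. A clicked pixel p₅ is written
as p₂ + kₐ·a plus a displacement parallel to b (and symmetrically for the
x-axis), i.e. its position is measured along each axis by intersecting
lines through p₅ parallel to the *other* axis. Eliminating the parallel
displacements gives closed forms for the span fractions kₐ, k_b with the
shared denominator a₁b₂ − a₂b₁, and the data coordinates follow by linear
interpolation of the axis values (geometric interpolation on a log
y-axis).

The model's only assumptions are that the figure's distortion is affine
(any composition of rotation, anisotropic scaling, shear, translation)
and that both axes are linear or log-linear with equidistant scales.
Under those assumptions the transform is exact: applying any invertible
affine map to all five pixels changes kₐ, k_b only through floating-point
rounding (verified to 1e−9 relative in the tests, and exactly for integer
translations). Nonlinear warp (lens distortion, wavy scans) and
interrupted or non-equidistant axes are outside the model; for such
figures the raw-pixel fallback (below) lets the user apply their own
correction.

## Degenerate inputs and numerical choices

- **Collinearity.** The exact solvability condition a₁b₂ ≠ a₂b₁ is
  meaningless for floats; a calibration is rejected as `CollinearAxesError`
  when |det| ≤ 1e−12·‖a‖·‖b‖. The relative form makes the test
  independent of image resolution. Near-singular calibrations that pass
  produce valid but noise-amplifying transforms; the clicking-error
  estimate reflects that amplification.
- **Zero-length axes and zero spans** (p₁ = p₂, p₃ = p₄, y₁ = y₂ or
  x₁ = x₂) are rejected rather than silently producing constant output:
  a zero span can only be a calibration mistake.
- **Log y-axis** requires y₁, y₂ > 0 (`LogDomainError` otherwise); only
  the y-axis supports log scaling (x is typically time in the intended
  applications). A log x-axis can be handled by swapping axes externally.
- **Extrapolation** beyond the calibrated span (kₐ, k_b outside [0, 1])
  is allowed without warning — figures routinely show data beyond the
  calibration ticks.
- **Inverse map.** `data_to_pixel` inverts the 2×2 affine system by its
  adjugate (exact closed form) and returns sub-pixel positions; rounding
  to screen pixels is left to callers so the inverse stays exact for
  round-trip testing.
- **Output rounding** is fixed-point, half away from zero, computed on
  the shortest decimal representation of each float so that 0.1 rounds
  as "0.1". Output is always re-rendered from full-precision values when
  the format or accuracy changes.

## Clicking error

`x_err = |x₁−x₂|/‖b‖` and `y_err = |y₁−y₂|/‖a‖` are the data-unit
gradients of the transform for orthogonal axes: a one-pixel deviation
along an axis moves the output by at most that amount. For skewed axes
the true gradient differs by the skew factor, but the estimate remains
the right order of magnitude. y_err is reported as undefined for log
axes, where the per-pixel effect depends on position. The reference
frame used throughout (spans 18 and 9 units over 400 and 300 px) gives
x_err = 0.045 and y_err = 0.03.

## Session semantics

Only raw pixels are stored; data coordinates are derived on demand. The
first four captured clicks fill the intercept slots p₁…p₄ in order, later
clicks are data points. Resetting the axes clears the intercept slots but
keeps the data clicks, so re-calibrating (e.g. after noticing a bad axis
click) re-transforms the whole data set; clearing the data set keeps the
calibration. Edits (insert/delete/overwrite) address points by 0-based
capture index. While calibration is incomplete, output falls back to the
raw pixels of *all* captured clicks — intercept slots included, since
without a complete axes definition nothing privileges them — flagged as
raw. Axis values may be set before or after clicking; derivation is a
pure function of (intercepts, values, points).

Sessions persist as UTF-8 text: an `axes: y2 y1 x1 x2 scale` header, an
`intercepts: k` header (so partially calibrated sessions round-trip),
then one `col row` pair per line with repr-precision floats, giving a
bit-exact save/load cycle. Bare pair lists load with the same
first-four-as-intercepts rule.

## Synthetic fixtures

The fixture generator builds charts whose data are known exactly, so the
whole pipeline is testable without external data. The default chart has
a y-axis spanning 0–9 over 300 px and an x-axis spanning 0–18 over
400 px with a shared origin pixel, carrying ten integer-coordinate
points (x = 0…18 step 2, starting at (0, 3)). Three scenarios mirror the
distortions a scanned page suffers: `plain` (identity), `rotated` (18°
counter-clockwise) and `rotated_skewed` (the same rotation composed with
a horizontal shear, factor 0.2 — a visible but comfortably invertible
default). The translation is chosen so the distorted chart sits on a
positive canvas with a 60 px margin.

Simulated clicks are the exact distorted pixels plus independent uniform
noise in ±noise_px per component, then rounded to the integer grid.
Uniform box noise models hitting any pixel in a small neighbourhood of
the target; it is deliberately not Gaussian. Rounding can be disabled to
obtain sub-pixel "perfect" clicks for exactness checks.

What the fixtures do **not** emulate: marker-centre ambiguity (real
markers are many pixels wide), anti-aliased axis lines, JPEG artefacts,
nonlinear warp, and operator bias. Passing the recovery tests therefore
shows the *transform* is correct under affine distortion, not that a
human digitizing a noisy scan achieves these error levels.

## Problem sizes and test design choices

Property suites use 1000 random well-conditioned calibrations
(|det| > 0.05·‖a‖·‖b‖, so the 1e−12 closed-form-vs-generic-solver
comparison is meaningful) and fixed seeds throughout. The distortion
robustness check compares RMS recovery error over 200 replicates of
0.5 px click noise per scenario, with rounding disabled: the default
truth points lie exactly on the undistorted chart's integer pixel grid,
so grid rounding would cancel the noise in the plain scenario only — an
alignment artifact that would distort the comparison rather than inform
it. The log-recovery check uses a two-decade axis over 600 px, where the
worst-case 1 px deviation moves y by ln(100)/600 ≈ 0.77 % relative; on
spans much shorter than that a two-decade log axis cannot keep relative
error under 1 %.

## Known limitations

- Affine distortion only; no detection of whether a figure violates the
  assumption (compare recovered values of known ticks to check).
- No automatic axis, curve or point detection: every point is clicked.
- Interactive capture works on an image file per window, not on the raw
  screen, and needs a GUI matplotlib backend; headless environments are
  directed to batch mode.
- Tick rendering in fixtures draws label glyphs undistorted (only their
  anchor positions are warped).
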