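# Methods

## Problem and model

Daily MVCT imaging on a helical tomotherapy unit delivers a small but
non-negligible dose with the treatment-energy beam (nominal 3.5 MV,
single 400 × 4 mm² field, SAD 85 cm, all MLC leaves open, 10-s gantry
period). `mvctdose` estimates that dose in three steps.

**Delivery discretization.** The continuous helical delivery is
approximated as *n* discrete beams at equally spaced isocenters along
the rotation axis, with gantry angles stepping by 360/*b* degrees
(*b* = 8 beams per rotation by default). The isocenter interval is the
couch travel per rotation divided by *b*: 0.05 / 0.10 / 0.15 cm for the
fine / normal / coarse pitches (couch travel 0.4 / 0.8 / 1.2 cm per
rotation). The machine prescribes dose by irradiation time
*T* = (scan length)/(couch travel per rotation) × (period per rotation);
monitor units are assigned by the convention 40 MU per 60 s, shared
equally over the *n* beams. A static plan (fixed gantry, moving couch)
is discretized the same way with per-beam time = interval / couch speed.
Isocenters are cell-centered (first at start + interval/2), which makes
*n* = 48 for a 4.8-cm normal-pitch scan and *n* = 30 for the 6-cm
calibration scan without endpoint ambiguity. The initial gantry angle
and rotation sense are configurable (the delivery hardware does not
expose them); both default choices are irrelevant on cylindrically
symmetric phantoms.

**Single-beam dose.** Each discrete beam is evaluated with a factorized
divergent-beam model on voxel centers:

    D(x) = MU · (Dose/MU)_Ref · PDD(d_rad)/PDD(d_ref) · OCR_x(x_iso) · OCR_y(y_iso) · (SAD/t)²

* `d_rad` — radiological depth: the density line integral from the source
  to the voxel, computed by exact voxel traversal (Siddon-style
  incremental stepping); this carries all heterogeneity handling.
* `x_iso`, `y_iso` — off-axis offsets back-projected to the isocenter
  plane along the divergent fan (lateral offset × SAD/t, with *t* the
  distance from the source along the beam axis). The two off-center
  ratios are treated as separable and depth-invariant after projection;
  the commissioning measurement provides them at a single depth (1.5 cm).
* the inverse-square factor is referenced to the isocenter plane
  (unity at t = SAD, where the PDD was commissioned at SSD = SAD).
* voxels with zero upstream radiological depth (air before the phantom)
  receive zero dose.

The plan dose is the element-wise sum over beams (Σᵢ Dᵢ). This engine is
deliberately primary-only: it reproduces the properties the delivery
discretization exercises — MU linearity, couch-speed and pitch scaling,
divergence, depth attenuation, heterogeneity via radiological depth —
but transports no scattered energy beyond what the measured profile
tails carry. Consequences are listed under *Limitations*.

**Output calibration.** Absolute dose is tied to a chamber measurement
in the reference condition: a 6-cm static scan at 0.1 cm/s from gantry
0° on the half ("split") cheese phantom, chamber at 1.5 cm depth. The
plan is computed with an output factor of 1 cGy/MU; the calibration
factor is (Dose/MU)_Ref = D_meas / D_calc, after which recomputing the
reference plan reproduces the measurement (an exact fixed point, by
linearity). The factor 1.0 doubles as the "uncalibrated" sentinel.

## Beam commissioning data

Measured curves load from two-column CSV (position_cm, value; `#`
comments; duplicates averaged; rows re-sorted). Interpolation is
piecewise linear — commissioning film is densely sampled and
higher-order fits risk penumbra overshoot — and extrapolation clamps to
the terminal node value, never below zero; a terminal 0 node forces a
zero tail. PDD curves are normalized to maximum 1.0, off-axis curves to
1.0 on the central axis. Curves are renormalized once at load; after
manual curve adjustment (the commissioning loop pairs curve perturbation
with a strict <3% point-dose tolerance check, `within_tolerance`), the
user re-normalizes explicitly.

### Synthetic beam model

So the package runs without machine data, `synthesize_beam_model`
generates an analytic model:

* PDD ∝ (1 − e^(−k·d/b)) · e^(−μ·d) on a 0.1-cm grid over 0–35 cm, with
  the build-up rate k solved (Brent) so the peak sits exactly at the
  build-up depth b; default b = 0.8 cm and μ = 0.045 cm⁻¹, representative
  of a ~3.5-MV beam (shallower peak and slightly faster fall-off than a
  6-MV treatment beam).
* OCR_x / OCR_y are flat-topped error-function profiles with half-widths
  20 cm and 0.2 cm and penumbra scales σ_x = 0.3 cm, σ_y = 0.1 cm
  (film-scale primary penumbras). They reach floating-point zero a few σ
  outside the field edge, giving the beam finite extent.

The generator is deterministic and emulates the *shape* of film-derived
commissioning curves, not their scatter content: a film profile measured
in phantom at depth carries low-amplitude scatter tails extending
centimeters off-field, which the pure-erf profiles omit. Tests that pass
on the synthetic model therefore validate geometry, scaling and
calibration logic; they say nothing about scatter-dependent effects
(scan-length dependence of the central dose, off-field dose bath,
longitudinal thread ripple — see Limitations).

## Phantoms

Phantoms are density lattices (relative to water, air = 0) with IEC-style
axes: y = couch travel, z vertical (gantry 0° beam travels along −z).
Membership for generators and masks is by voxel-center test. Default
spacing is 0.25 cm — at most half the 0.4-cm field length, which is the
resolution driver. Generators: the 30-cm-diameter cylindrical
water-equivalent dosimetry phantom (optionally split in half, as
positioned for chamber calibration on the couch), rectangular slabs, and
box-insert heterogeneous variants (e.g. lung-like 0.25-density inserts).
Rasters round-trip as NRRD (SimpleITK); masks as NRRD label maps or JSON
index lists.

Point doses are trilinear samples; a chamber-style reading averages ≥9
samples over a 0.44-cm segment along IEC-Y, emulating the A1SL
collector length.

## Reporting

Per-organ outputs are the maximum voxel dose per fraction, its total
over the fractionation scheme, and the total as a percentage of the
prescribed dose. Totals are computed from unrounded per-fraction values
and rounded (2 decimals) only at display — rounding first does not
commute with multiplying by 30–40 fractions. Survey-level summaries
average the display-rounded columns, matching how published tables are
summarized. DVHs are cumulative ("volume fraction receiving ≥ dose"),
voxel-count weighted, monotone non-increasing with value 1 at zero dose.
Whether a near-maximum (e.g. D_0.03cc) would be preferable to the voxel
maximum is a reporting-convention question; the voxel max is used.

## Numerical choices

* Ray tracing: Amanatides–Woo incremental traversal with exact per-voxel
  segment lengths; verified against a 10⁴-step midpoint-rule oracle to
  10⁻³ cm. Rays are clipped to the grid box; ties at voxel corners
  resolve in axis order (x, y, z), which only permutes zero-length
  segments.
* Dose accumulates in float64 at voxel centers; the per-beam kernel and
  the ray tracer are numba-compiled. Voxels where either off-center
  ratio is zero skip the ray trace.
* Curve interpolation inside the kernel is binary-search linear with
  terminal clamping, bit-identical to the public curve evaluation.
* Problem sizes: validation-style simulations run on the 0.25-cm cheese
  phantom (128 × 80 × 128 voxels, ~0.07 s per beam on one core); unit
  tests use 0.5–1.0-cm lattices where only geometry or linearity is at
  stake.

## Limitations

* **No scatter transport.** Scan-length effects on the central dose
  (a few percent in measured data) appear only through profile tails;
  with the tail-free synthetic model they are absent.
* **Helical thread ripple is overstated off-axis.** With couch travel
  0.8 cm per rotation and a 0.4-cm field, an off-axis point is dosed
  from only the gantry directions whose longitudinal profile covers its
  y position. With the synthetic (tail-free, σ_y = 0.1 cm) profile this
  produces an azimuthal ripple of several percent at r = 5 cm that does
  not shrink with finer angular sampling; real measured profiles with
  scatter tails spanning the 0.8-cm helical period smooth it. The
  rotational-symmetry acceptance property documents this: it fails by
  design honesty under the synthetic model.
* OCR separability and depth-invariance are assumed; no depth-resolved
  profile data are modeled.
* Couch and bore attenuation, detector response, electron transport and
  real patient CT import are out of scope.
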