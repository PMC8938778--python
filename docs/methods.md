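# Methods

## Problem

Kinetic modelling of dynamic PET needs an arterial input function (AIF),
usually read off the images from a small artery (internal iliac, carotid:
5–10 mm inner diameter). At PET's 4–7 mm spatial resolution the partial
volume effect (PVE) spills most of such a vessel's signal into its
surroundings, so the uncorrected image-derived AIF can underestimate the
true blood curve by half or more, corrupting every downstream rate
constant.

## Conservation-of-activity (CoA) correction

A calibrated scanner conserves total activity: blurring moves counts but
does not destroy them. The CoA corrections therefore sum the activity in
an enlarged spill-out region `V_SO` that encloses the true vessel volume
`V_A` plus all of its blurred signal, and re-assign it to `V_A`:

* zero background:
  `C_corr = C_SO · V_SO / V_A`
* uniform background (subtracted over the annulus `V_SO − V_A`, with the
  background level `C_BKG` read from a ring just outside `V_SO`):
  `C_corr = (C_SO·V_SO − C_BKG·(V_SO − V_A)) / V_A`
* artery and vein sharing one spill-out region: the background-subtracted
  total `C_SO·V_SO − C_BKG·(V_SO − V_A − V_V)` is apportioned between the
  two vessels in proportion to their image-derived signals `C_A·V_A` and
  `C_V·V_V`; the artery share is divided by `V_A`, the vein share
  (complementary fraction) by `V_V`.

All three are pure per-frame linear operations in the measured
concentrations; no temporal smoothing is applied. Design choices where the
equations are silent:

* **Pre-arrival frames** with `C_A·V_A + C_V·V_V = 0` return 0 for both
  corrected values rather than raising on the 0/0 apportioning — there is
  no signal to apportion before tracer arrival.
* **Negative corrected values** (noisy tails after background subtraction)
  are preserved by default so that zero-mean noise leaves the AUC
  unbiased; a `clamp_negative` flag is available.
* **The vein curve** uses the complementary apportioning fraction over
  `V_V` — the symmetric completion of the artery formula, noted in the
  result diagnostics.
* **Opposite-signed noisy signals** in a frame are apportioned by the
  signed products as measured (with the optional clamp); the package makes
  no stronger claim for that regime.

### Recovery-coefficient baseline

The classical comparator divides the true-region mean by a recovery
coefficient RC(d, FWHM): the fraction of a unit cylinder's in-plane
profile, convolved with a 2-D Gaussian of the scanner's FWHM, that falls
inside the true cross-section. It is computed by numerical integration on
a fine grid (cell size `min(d, FWHM)/60` by default; agreement with a 10×
finer quadrature is ~4·10⁻⁵). The correction `C_A / RC` is deliberately
background-blind — that is the method under comparison. Its documented
failure mode follows directly: once the true activity drops below
background, spill-in dominates the measured mean and the RC-corrected
curve saturates near `C_BKG·(1−RC)/RC + C_true`, i.e. stays inflated above
truth. The analytic cylinder RC is a clean stand-in for tabulated
phantom-derived coefficients, not a reproduction of any published table.

## Digital flow phantom

The generator emulates a flow phantom in which four tubes (25.4, 12.7,
9.5, 6.35 mm ID, spaced 63.5 mm apart) carry one and the same input
function through a uniform background compartment, plus a companion
6.35 mm venous tube 20 mm from the smallest artery, fed through a dilution
buffer. Default parameters:

| parameter | default | note |
|---|---|---|
| delivered activity | 22 MBq | 0.5 mL/s × 50 s from a 53 MBq / 60 cc syringe |
| flow rate | 10 mL/s | constant volumetric flow through all tubes |
| mixing-chamber volume | 150 mL | free parameter, see below |
| venous buffer volume | 500 mL | vein peak ≈ 58% of arterial, delayed |
| background | 1.4 kBq/cc | typical soft-tissue level at ~60 min p.i. |
| PSF FWHM | 6 mm | isotropic Gaussian, image-space PVE surrogate |
| grid | 1 mm isotropic, 310×100×60 mm | tubes ≥ 3·FWHM from every edge |
| frames | 15 × 20 s | dynamic acquisition scheme |
| tracer half-life | 109.77 min (¹⁸F) | images decay-corrected by default |

The arterial curve is the analytic response of a single well-mixed
chamber: inflow `A/T` during the `T = 50 s` injection, flushed at flow
`Q`, giving `C(t) = A/(TQ)·(1 − e^{−Qt/V})` then washout. Mass balance
`Q·∫C dt = A` holds by construction and is asserted to 0.1%. The chamber
volume is a shape parameter only (the hardware's transfer function is
unknown); 150 mL makes the curve peak near 40 kBq/cc and fall below the
1.4 kBq/cc background within the 5-minute acquisition, which is what the
recovery-coefficient failure-mode demonstration requires. No quantitative
claim is made about any physical chamber. The venous curve is the
arterial one convolved with the buffer's impulse response
`(Q/V)e^{−Qt/V}` (AUC-preserving, peak-lowering).

Rendering: fine curves (0.5 s bin midpoints) are averaged over each frame
window; tube cross-sections are rasterized with fractional occupancy (3×3
subsampling); the background fills the rest; each frame volume is blurred
with the isotropic Gaussian PSF. Tubes span the full field of view along
z, so the 3-D blur of the z-invariant field equals the in-plane 2-D blur
broadcast along z, which is how it is computed (`nearest` edge handling is
exact for the uniform background at the borders and mass-conserving for
tubes kept away from the edges). Optional Gaussian noise with
`σ = scale·sqrt(max(value, floor)/frame_duration)` mimics the
count-statistics penalty of short frames; the default is noiseless, which
is the regime in which the conservation oracles are defined. The whole
simulation is a pure function of `(PhantomSpec, seed)`.

**What the phantom does not model:** sinogram-domain physics (attenuation,
scatter, randoms, Poisson reconstruction noise and its correlations),
reconstruction artefacts at very low counts, spatially varying PSF, flow
non-uniformity inside tubes. Passing the conservation oracles shows the
equations are exact for Gaussian image-space blur with conserved counts —
the stated operating assumption — not that scanner data will match to the
same tolerance.

## Region scheme

True-size cylindrical ROIs are placed along each tube (length 20 mm;
replicate segments supported, with standard errors across segments). The
spill-out cylinder adds 15 mm to the vessel radius; the background ring
extends a further 10 mm. For the artery/vein pair a single combined
spill-out cylinder is centred between the tubes; its default radius is
25 mm, chosen so that the boundary clears each tube by more than
2·FWHM — the same containment margin the single-tube regions satisfy. (A
2 cm diameter cylinder cannot enclose two tubes 2 cm apart; the radius is
the package's own choice and is configurable.) Volumes are analytic
(`π r² L`), as they would be measured on CT.

Extraction is the occupancy-weighted mean per frame. Fractional weights
are the default; binary voxel-centre masks mimic clinical contouring. On
the blurred images the two agree within a few percent. On *unblurred*
rasterized data the occupancy-weighted mean carries a sub-voxel edge bias
(edge voxels hold `c·occ`, and weighting by `occ` yields
`Σocc²/Σocc < 1`) of 3–9% at 1 mm voxels; the conservation readout
(total activity / volume) is exact there, and the mean readout converges
as the voxel shrinks. This matters only for the no-blur identity checks,
not for the corrections, which operate on smooth blurred fields.

## Validation arithmetic

AUC is the rectangle rule `Σ value·duration` (kBq·s/cc) so that framed
curves and bin-averaged reference curves compare consistently; fine
reference curves are averaged onto the 20 s scheme before any comparison
(a transient narrower than a frame aliases down — the binned curve is what
the scanner can see). The model AUC is `A/Q`: every tracer atom crosses a
tube cross-section exactly once, so the curve shape drops out. Percent
improvement is reported as the difference of absolute percent errors, in
percentage points. Decay correction scales by `2^{(t_mid − t_ref)/T_half}`
at frame midpoints (unbiased for linear in-frame variation). The
HU-per-(kBq/cc) factor assumes contrast agent and tracer share one
dilution volume, stated in the output metadata.

## Irreversible two-tissue compartment model

`C_T = (1−v_b)·K1·[k3/(k2+k3) + k2/(k2+k3)·e^{−(k2+k3)t}] ⊛ Cp + v_b·Cp`,
with K1 in mL/cc/min, k2, k3 in 1/min, `v_b` fixed at 0 by default (the
three-parameter form). Internal computation converts rates to the curve's
second-based grid at the module boundary. The convolution uses the exact
discretization of a first-order compartment for piecewise-linear input
(run as an IIR filter), with `k2+k3 = 0` degenerating to pure integration;
against a stiff (Radau) integration of the ODE system the forward curves
agree to ~10⁻⁷ relative.

Fitting is bounded trust-region least squares (`scipy.optimize.
least_squares`, bounds `[0, 5]` per parameter, tolerances 10⁻¹²) from
three default starting points spanning slow and fast kinetics; the best
local optimum is kept and non-convergence is flagged on the result, never
raised. Weights are uniform by default with a frame-duration option.
Standard errors come from the Jacobian at the optimum. Parameter-recovery
checks use 20-minute curves (the patient-scan horizon); on a 5-minute
horizon, draws with small `k2+k3` are weakly identified and recovery
tolerances would reflect the experiment design rather than the optimizer.

## Problem sizes used in tests and the acceptance script

Default phantom renders (310×100×60 voxels × 15 frames) take a couple of
seconds each; the test suite renders a handful of phantoms and the
acceptance script two (with and without background). Parameter-recovery
sweeps use 50 log-uniform draws on 1 s grids. These sizes make the whole
validation reproducible on a laptop in about a minute.

## Known limitations

* Image-space Gaussian blur is the PVE model; no iterative-reconstruction
  or time-of-flight behaviour is simulated.
* The background ring can pick up spill-out from a neighbouring tube if
  regions are drawn larger than the defaults; the phantom's 63.5 mm
  spacing keeps this negligible (≳ 7σ separation), but the effect (slight
  background overestimation → slight undercorrection) is inherent to the
  region scheme.
* The artery/vein apportioning assumes both vessels' spill is fully
  contained in the combined region and that their image-derived signals
  are proportional to their true totals; strongly asymmetric blur or
  contact between vessels would violate it.
* DICOM reading covers per-frame series with standard geometry and frame
  timing tags only; NIfTI + JSON sidecar is the canonical interchange.
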