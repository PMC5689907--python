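# Methods

This note documents the models, conventions and numerical choices in
`dapcal`, and what the synthetic-data studies do and do not show about
real measurements.

## Calibration model

The chamber charge, corrected for air density, is proportional to the
dose-area product in water over the sensitive disc:

    DAP_w = M_LAC,cor · N_D,w,LAC · k_s · k_pol · k_elec
    DAP_w = D_w,CAX · ∬_A R(r) dr

All interfaces fix the units: mGy and nC, distances in cm for radii and
areas (cm^2), mm for pixel/voxel pitches, temperature in °C, pressure
in kPa.  k_TP is referenced to 20 °C and 101.325 kPa.  Coefficients are
reported to 1 decimal in mGy cm^-2 nC^-1 and percentages to 1 decimal,
with half-up rounding (`dapcal._rounding`); uncertainties to two
significant figures.

## Synthetic field model

No raw scans or electrometer logs ship with the package, so a
closed-form field stands in for the measured beams.  A cone field is

    R(r) = (1 − f_t) · ½ erfc((r − a)/(√2 σ)) + f_t · exp(−λ·max(0, r−a))

with radius `a`, penumbra width `σ` (default 3 mm), out-of-field
plateau `f_t` (default 4%, the level measured for 1 × 1 cm^2 6 MV beams
at d_max; it rises to ~8% at 30 cm depth) and tail decay `λ` (default
0, i.e. a flat plateau).  Square fields use the product of per-axis
erfc edges.  The form is a stand-in chosen to reproduce a flat top, an
error-function penumbra and a non-zero out-of-field plateau — the three
features that control the disc integral; it is not a claim about any
particular linac.  Because it is closed-form, quadrature of the formula
serves as an independent oracle for the grid and profile integrators.

The film generator inverts the analysis model exactly: PV =
2^16·10^−(OD_pre + ΔOD(D) + ε), with ΔOD(D) the numerical inverse of
the calibration polynomial, ε Gaussian in OD space, and dust as salt
noise in PV space (default fixture density 3 × 10^-4 ≈ tens of specks
per scan — the artefact the 30 × 30 median filter removes).  Pixel
values are kept as floats in memory; quantization to uint16 happens
only on TIFF export.

The voltage-series generator uses M(U) = M_sat/(1 + s/U), which makes
1/M *exactly* linear in 1/U — the ion-chamber regime a Jaffe plot
assumes — so the Jaffe fit must recover k_s = 1 + s/U_op to machine
precision, a sharp correctness check.  The default slope s = 0.36 V
reproduces the reference dataset's intercept (0.9991 at +400 V, k_s =
1.0009).

## Film pipeline conventions

* Grid pitch from scanner resolution: pitch = 25.4/dpi mm.
* Median filter: `scipy.ndimage.median_filter`, reflect padding.  The
  window should correspond to ~2.5 mm (30 px at 300 dpi); tests on
  coarser synthetic grids scale it accordingly.
* Registration: rigid (translation + rotation) transform estimated from
  ≥ 2 fiducial-mark pairs (scikit-image Euclidean transform), bilinear
  resampling.  Film in a flatbed scanner cannot change scale, so
  similarity terms are excluded.  Interpolation order is configurable.
* Beam centre: intensity centroid of the above-50%-of-maximum region of
  a lightly median-filtered map — robust to dust, and coincides with
  the penumbra midpoint for symmetric fields.  (The centre definition
  is a design choice; nothing in the protocol prescribes one.)
* Negative net-OD from noise is clamped to 0 before the dose curve
  (the polynomial is not defined below 0); the clamp count is recorded.
* The net-OD → dose polynomial is strictly increasing on
  [0, ΔOD(2.8 Gy)]; values beyond the fitted domain raise by default
  (`extrapolation refused`) with an explicit clamp option.
* Two-exposure combination: the high-MU map is divided by the MU ratio,
  translated so beam centres coincide, and the pointwise maximum taken.
* CAX normalization averages a 2 mm-radius central disc (configurable).

## Disc integration

* 2D method: pixels whose centres fall inside r_LAC contribute their
  full area.  At ≤ 0.1 mm pitch the boundary error is < 0.02%; the
  0.5 mm test fixtures stay below 0.1% against quadrature oracles.
* Annular method: boundaries at sample midpoints, first annulus from 0,
  outermost clipped at r_LAC so the annuli tile the disc exactly
  (areas sum to πr_LAC² to 1e-9 relative).  Each half-profile is
  integrated independently; the mean and sample SD over half-profiles
  are reported.  Mean-of-integrals (not integral-of-mean-profile) is
  used, matching per-detector spreads quoted in practice.
* r_LAC = 4.08 cm (81.6 mm electrode) is primary; the vendor's
  52.25 cm² sensitive area differs slightly from π·4.08² = 52.30 cm²
  and is carried only as a nominal constant.

## Correction factors

* Jaffe fit: normalized 1/M vs 1/U, restricted to U ≥ 100 V (general
  recombination is linear only above ~100 V for this chamber;
  configurable), k_s = 1/intercept.
* Two-voltage method: TRS-398 pulsed-beam quadratic coefficients,
  k_s = a0 + a1(M1/M2) + a2(M1/M2)², M1 at the operating voltage.  The
  coefficient table is shipped as an editable constant with a unit test
  asserting each row sums to 1 within 0.001.
* k_pol uses absolute charges with the routine polarity in the
  denominator.
* Volume averaging: k_vol = 1/mean(R) over the chamber's 2.4 cm cavity
  length, computed by trapezoid integration of the interpolated
  profile; for a parabolic profile this reproduces the closed form
  1/(1 − kL²/12).
* Angular response: broad beams are modelled linearly (0.05%/deg, the
  empirical rate); fields smaller than the sensitive area additionally
  grow as 1/cos α from the geometric increase of irradiated air volume.

## Uncertainty budget

Quadrature combination of k = 1 relative components, with two
deliberate linear exceptions that mirror worst-case practice: the
out-of-field film energy-response allowance adds linearly (2% + 5% =
7%), and in-/out-of-field film terms combine linearly weighted by each
region's share of the integral.  The ±0.02 cm jaw tolerance is
interpreted as a standard uncertainty per side, giving √2·(0.02/4.00) =
0.7% for a 4 × 4 cm² field area; a strict "95% coverage → k = 2"
reading would halve it, and the tension is inherent in how such
tolerances are quoted.

## MicroCT geometry QC

In-plane 20 × 20 block averaging (1.64 mm at the 0.082 mm voxel size)
suppresses noise at full axial resolution; each coarse column is
thresholded at 50% between per-column air/body plateau levels (medians
of the two half-range classes — scale-invariant and noise-robust,
reducing to the nominal 0/2200 on clean data) with linear sub-voxel
interpolation.  Columns with four crossings yield body (outer-edge) and
gap (inner-edge) thicknesses; columns with exactly two crossings report
a zero gap (no detectable cavity); any other count is excluded and
counted.  A linear regression of the gap mid-plane against each lateral
coordinate flags systematic tilt (smallest p-value reported).  The
synthetic generator anti-aliases edges by partial-volume weighting, so
recovery bias stays below half a voxel at any sub-voxel edge phase.

## Synthetic-recovery studies and their scope

`experiments.recovery_experiment` runs 200 seeded end-to-end
calibrations: star-pattern profiles of the 5 cm cone field with 1%
per-point scan noise (renormalized at the CAX; this reproduces the ~1%
per-half-profile integral spread seen with real detectors), 0.2% linac
output reproducibility on the CAX dose, 0.07% charge reproducibility.
Only the *statistical* budget rows are resampled per run — systematic
terms (film energy response, depth misalignment, stopping-power data)
are biases that repetition cannot reveal, and leaving them out is what
makes "≥95% of runs within the 1.3% combined budget" the correct
expectation rather than an accident.  Passing therefore demonstrates
the pipeline's internal consistency and noise propagation, not the
absence of systematic error in a real beam.

`experiments.geometry_recovery` uses a 6 mm gap radius instead of the
full 42 mm electrode so the volume fits in seconds of compute; the edge
analysis is identical at any radius.  Problem sizes throughout the test
suite (0.25–1 mm film pitches, 12 cm extents, 200-run ensembles) were
chosen so the whole suite completes in well under a minute while every
tolerance stays dominated by physics, not discretization.

## Known limitations

* The field model is analytic; scanner lateral-response artefacts,
  multichannel film dosimetry and Monte Carlo spectra are out of scope.
* The calibration curve is an input (fitting it is not implemented).
* Printed reference values carry their published rounding: the cone
  column's coefficient (163.7) and the 10 MV broad column (157.3) are
  not exactly reproducible from their rounded inputs and are therefore
  used only as inputs to comparison ratios, never re-derived.
* k_Q beam-quality conversion and primary-standard dosimetry are not
  modelled; energy dependence is predicted from s_w,air ratios only.
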