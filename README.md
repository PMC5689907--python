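# dapcal

Dose-area-product (DAP_w) commissioning analysis for large-area
plane-parallel ionization chambers in megavoltage photon beams.

## The problem

Point-dose measurements in small photon fields (stereotactic cones,
1 x 1 cm^2 MLC fields) are plagued by volume averaging and lateral
alignment uncertainty.  An alternative is the dose-area product in
water,

    DAP_w = ∬_A D_w(r) dr = D_w,CAX · ∬_A R(r) dr ,

measured with a large-area plane-parallel chamber (LAC) whose sensitive
disc (radius r_LAC = 4.08 cm for a PTW 34070-type Bragg Peak chamber)
exceeds the beam cross-section.  The chamber reading relates to DAP_w
through a calibration coefficient,

    DAP_w = M_LAC,cor · N_D,w,LAC · k_s · k_pol · k_elec ,

where M_LAC,cor is the collected charge corrected for air density
(k_TP) and the k_i are the usual influence-quantity corrections.

`dapcal` implements every analysis step needed to commission such a
chamber, for medical physicists and dosimetry-lab scientists:

* **film_dosimetry** — EBT3-style net-optical-density protocol:
  30 x 30 median filter, OD = −log10(PV/2^16), fiducial-mark rigid
  registration, a 5th-order net-OD→dose polynomial, two-exposure
  (low/high MU) combination, CAX normalization;
* **dose_integration** — the relative dose integral ∬ R dr over the
  sensitive disc from 2D film maps (pixel sum) and from star-pattern
  scanned profiles (annular area-weighted average, Eq. above), with
  shift-sensitivity analysis;
* **chamber_corrections** — k_TP, Jaffe-plot and TRS-398 two-voltage
  saturation corrections, polarity correction, NE2571 volume-averaging
  correction, a 1/cos(α) angular-response model, linearity/
  reproducibility QA statistics;
* **dap_calibration** — DAP_w and N_D,w,LAC arithmetic, energy-response
  prediction from Spencer–Attix stopping-power ratios s_w,air;
* **uncertainty_budget** — quadrature combination, regional film
  uncertainties, field-area propagation;
* **geometry_qc** — microCT edge analysis of the electrode gap
  (block averaging, 50% threshold crossings, thickness statistics);
* **synthetic_data** — seeded generators for every input (fields, film
  scans, profiles, chamber readings, voltage series, CT volumes) with
  known ground truth.

## Worked example

Recompute a broad-field calibration coefficient from its measured
pieces (CAX dose 7.998 mGy/MU, dose integral 52.01 cm^2, 523.6 nC
collected over 200 MU, k_s = 1.001, k_pol = 0.999):

```python
>>> import dapcal as dc
>>> dap = dc.compute_dap(7.998, 52.01)          # mGy cm^2 / MU
>>> cs = dc.CorrectionSet(k_s=1.001, k_pol=0.999)
>>> n = dc.calibration_coefficient(dap, 200.0, 523.6, cs)
>>> round(dap, 1), round(n, 1)
(416.0, 158.9)
```

416.0 mGy cm^2/MU is the dose-area product delivered per monitor unit;
158.9 mGy cm^-2 nC^-1 is the calibration coefficient that converts the
corrected chamber charge back into DAP_w.  The same chain works on
synthetic data with known truth:

```python
>>> spec = dc.FieldSpec("cone", 5.0, penumbra_sigma=3.0, tail_frac=0.04)
>>> field = dc.make_field(spec, extent=12.0, pitch=0.5)
>>> profiles = dc.sample_profiles(field, n_directions=4, step=0.5, detector_fwhm=3.0)
>>> integral = dc.integrate_annular(profiles, r_lac=4.08)
>>> round(integral.value, 2)
21.21
```

The same operations are exposed on the command line, e.g.

```sh
dapcal calibrate --dcax 7.998 --integral 52.01 --mu 200 --charge 523.6 \
    --ks 1.001 --kpol 0.999
dapcal simulate readings --seed 1 --out sim/
dapcal corrections jaffe --in sim/readings.json
```

## Layout

```
src/dapcal/       library modules (one per analysis stage) + CLI
tests/            pytest suite incl. acceptance checks
scripts/          acceptance.py
docs/methods.md   model, conventions, numerical choices, limitations
```
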