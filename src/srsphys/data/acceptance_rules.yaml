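# Default acceptance rule set for the 3 MV self-shielded SRS platform.
# Rule kinds: within_abs, within_pct, max_abs_or_pct, le, ge, info.
version: 1
rules:
  - metric: pdd_100mm_pct
    description: Photon energy via PDD at 100 mm depth, 25 mm field, SSD 450 mm
    nominal: 40.0
    tolerance: 2.0
    kind: within_abs
    units: "%"
  - metric: dose_rate_mu_per_min
    description: Dose rate at isocenter
    nominal: 1500.0
    tolerance: 10.0
    kind: within_pct
    units: MU/min
  - metric: calibration_cgy_per_mu
    description: Absolute calibration at dmax, SAD 450 mm, 25 mm collimator
    nominal: 1.0
    tolerance: 2.0
    kind: within_pct
    units: cGy/MU
  - metric: linearity_pct
    description: Dose-monitor linearity, 2-1000 MU
    nominal: 3.0
    kind: le
    units: "%"
  - metric: reproducibility_pct
    description: Dose-monitor reproducibility (2 MU or 2%, whichever greater)
    nominal: 2.0
    kind: le
    units: "%"
  - metric: reproducibility_100mu_pct
    description: Reproducibility of 100 MU delivery (dosimetry acceptance)
    nominal: 1.0
    kind: le
    units: "%"
  - metric: orientation_dose_stability_cgy
    description: Max dose deviation vs reference orientation at 100 MU (2 MU or 3%)
    nominal: 100.0
    tolerance: 2.0
    tolerance_pct: 3.0
    kind: max_abs_or_pct
    units: cGy
  - metric: symmetry_pct
    description: Beam symmetry, 25 mm collimator
    nominal: 2.0
    kind: le
    units: "%"
  - metric: field_size_error_mm
    description: Radiation field size minus stated collimator size
    nominal: 0.0
    tolerance: 0.25
    kind: within_abs
    units: mm
  - metric: penumbra_10cm_mm
    description: 80-20% penumbra at 100 mm depth
    nominal: 4.0
    kind: le
    units: mm
  - metric: ionization_ratio
    description: Accelerating potential via ionization ratio I20/I10
    nominal: 0.505
    tolerance: 0.05
    kind: within_abs
    units: ""
  - metric: leakage_patient_plane_pct
    description: Leakage in the patient plane relative to the primary beam
    nominal: 0.1
    kind: le
    units: "%"
  - metric: leakage_housing_mr_per_hr
    description: Leakage outside the housing at 1 m
    nominal: 3.0
    kind: le
    units: mR/hr
  - metric: gantry_isocentricity_mm
    description: Axial/oblique gantry isocentricity (mechanical; metadata only)
    nominal: 1.0
    kind: info
    units: mm
  - metric: laser_collimator_center_mm
    description: Laser position on collimator center (mechanical; metadata only)
    nominal: 1.0
    kind: info
    units: mm
  - metric: kv_imaging_quality
    description: kV imaging QA metrics (metadata only, not computed here)
    kind: info
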