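# srsphys

Dosimetry, radiation-protection and QA analysis for a self-shielded 3 MV
stereotactic radiosurgery (SRS) platform with eight circular collimators
(4–25 mm diameter at a 450 mm source–axis distance).

The package is written for the medical physicist commissioning or
periodically checking such a machine: it models the machine's beam data,
computes point doses and monitor units, extracts beam-profile metrics from
1-D scans, derives shielding workloads and survey annual doses, evaluates
conformality indices, and runs a tolerance-table acceptance check.

## The model

Point dose for one beam at position **x** in a water-equivalent phantom:

```
D(x) = MU · C · OCR(coll, d_eff, OAD) · TMR(coll, d_eff) · OF(coll) · (450/SAD_x)²
```

where `C` is the absolute calibration (1 cGy/MU at d_max, SAD 450 mm, 25 mm
collimator), `d_eff` the water-equivalent depth along the central axis to the
projection of **x**, `OAD` the off-axis distance scaled to the isocenter
plane, and `SAD_x` the source-to-projection distance. The inverse gives the
monitor units for a prescription:

```
MU = D_rx / (isodose · TMR · OF · C · (450/SAD)²)
```

Around this core: PDD↔TMR conversion (inverse-square, scatter-free),
50%-crossing field size and 80–20% penumbra from scan profiles,
the workload → utilization → allowable-rate chain for radiation protection
(annual dose = rate × use factor × duty cycle × work hours, at
100 mR = 1 mSv), analytic tenth-value-layer shield thickness
(−log₁₀(attenuation) × TVL), and volume-ratio conformality indices.

## Worked example

```python
from srsphys import *
from srsphys.shielding_survey import WorkloadModel, rad_on_hours
from srsphys.synthetic import SyntheticBeamParams, make_profile, make_survey_table

# Monitor units for 2,500 cGy to the 80% isodose, 25 mm collimator,
# 10 cm deep (TPR ~ 0.5, OF = 1):
mu = compute_mu(2500, 0.80, tmr=0.5, of=1.0, sad=450)      # -> 6250.0 MU

# The annual radiation-protection chain for 2,250 patients/year:
m = WorkloadModel(np_patients=2250, mu_per_treatment=mu)
annual_mu(m)              # -> 14062500.0 MU/year
rad_on_hours(m)           # -> 156.25 h/year at 1,500 MU/min
utilization(m)            # -> 0.078125
allowable_rate(500.0, m)  # -> 3.2 (mrem/hr at 1 m for a 500 mrem/yr budget)

# Profile metrics on a synthetic 25 mm scan at 5 cm depth:
p = SyntheticBeamParams()
prof = make_profile(p, coll=25, depth=50, n=501)
field_size(prof)          # -> 27.78 mm (25 mm field diverged to the scan plane)
penumbra(prof)            # -> (2.27, 2.27) mm 80-20% edge widths
symmetry(prof)            # -> 0.0 %

# Survey table: projected annual doses and verdicts
rep = survey_report(make_survey_table(), limit_msv=1.0, rate_limit=3.2)
rep.max_rate              # -> 3.0 mR/hr at station 1; rep.all_pass -> True

# Focal spot from the stacked-leaf camera (0.1 mm leaves + 0.1 mm spacers):
focal_spot_size(FocalSpotCamera(0.1, 0.1, 100, 228.0), 9)
# -> FocalSpotResult(size_mm=1.8, uncertainty_mm=0.2)
```

The command-line entry point `srsphys` exposes the same workflows
(`synth-beamdata`, `profiles`, `survey`, `shield`, `qa`, `dose`,
`conformality`); see `srsphys --help`.

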