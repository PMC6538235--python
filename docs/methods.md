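# Methods

## Scope and model

`srsphys` models a dedicated, self-shielded 3 MV SRS platform: a single
photon energy, eight circular collimators (4.0–25.0 mm diameter defined at
the 450 mm isocenter), absolute calibration 1 cGy/MU at the depth of dose
maximum (d_max = 7 mm), SAD 450 mm, 25 mm reference collimator. All lengths
are mm, dose is cGy, angles degrees.

The dose model is the standard factor-based point-dose formula for circular
fields: calibration × off-center ratio × tissue-maximum ratio × output
factor × inverse square. It assumes a water-equivalent medium (a
density-scaled sphere stands in for the head), no heterogeneity or scatter
kernels, and no dose outside the tabulated OCR support. Effective depth is
measured along the central axis to the projection of the calculation point,
which is exact on axis and a small-field approximation off axis; off-axis
distance is divergence-scaled to the isocenter plane, matching the geometry
in which OCR tables are measured.

## Beam-data tables and numerics

* Interpolation is linear along every axis (depth, off-axis distance,
  collimator size). Depths are tabulated densely (1 mm) and the beam is
  single-energy, so log-linear schemes would buy nothing; linearity makes the
  lookups exact on nodes and monotone between them.
* Depth queries beyond the table are clamped to the edge and warned about;
  off-axis queries beyond the table support return 0 — the alternative
  (clamping to the last OCR value) would extrapolate small but nonzero dose
  arbitrarily far from the field.
* OCR tables are stored one-sided (radial). Two-sided measured profiles are
  folded by left/right averaging; the maximum asymmetry relative to the
  central reading is reported alongside so nothing is silently discarded.
* `pdd_to_tmr` uses TMR(d) = [PDD(d)/PDD(d_max)]·((SSD+d)/(SSD+d_max))² with
  the phantom-scatter ratio set to 1. For fields ≤ 25 mm diameter the
  phantom-scatter variation with depth is small, but the approximation is
  real: converting a PDD of 40.29 % at 100 mm gives TMR ≈ 0.584, whereas the
  directly generated TMR curve is anchored at 0.5 there. Both tables are
  therefore carried independently; the conversion exists for users who can
  only measure PDD.

## Profile metrics

The reference level for the 50/80/20 % thresholds is the central-axis
reading, estimated in two passes: a crude centre from the 50 %-of-maximum
crossings, then the mean of the three samples nearest that centre. This is
robust to isolated noise spikes that would corrupt a global-maximum
reference. All crossings are linearly interpolated, so field size and
penumbra resolve to about one sample spacing; no smoothing is applied by
default (a moving-average helper exists). Symmetry is the IEC-style maximum
point difference |D(c+x) − D(c−x)|/D(c) over |x| ≤ 80 % of the field radius —
the field's own definition varies between vendors, so the choice is
documented here rather than asserted as universal.

The focal-spot estimate is line pairs × camera pitch (leaf + spacer
thickness) with a one-pitch uncertainty. No magnification correction is
applied; with the camera nearly in contact with the collimator exit the
correction is below the one-pitch uncertainty, and the plain pitch arithmetic
is what the measurement procedure defines.

## Shielding and survey arithmetic

Annual dose at a survey station is rate × use factor × duty cycle × work
hours with the fixed equivalence 100 mR = 1 mSv; exposure-to-dose physics
beyond that equivalence is out of scope. The work year defaults to 2,000 h.
Tabulated doses are rounded to 3 decimals for presentation; verdicts are
computed on unrounded values. The utilization chain satisfies the algebraic
closure utilization × allowable rate × work hours = annual limit exactly.

Shield thickness is analytic: n_TVL = −log₁₀(attenuation), thickness =
n_TVL × TVL(material, angle), maximised over the active sources and revolved
about the beam axis. First/second/third tenth-value layers are collapsed to
one equilibrium TVL per material unless the user supplies an angular table —
the package computes with user TVLs only and does not generate them
(Monte Carlo transport is out of scope). An attenuation of exactly 1
requires no shield (0 mm); values above 1 are rejected.

## QA engine

Linearity fits dose = k·MU through the origin (the calibration pins
1 cGy/MU, so a free intercept would absorb exactly the zero-offset error the
check is meant to expose) and reports the maximum relative deviation; it
requires ≥ 3 distinct settings spanning a decade. Reproducibility is the
maximum relative deviation from the replicate mean. Tolerance rules support
absolute, percent, greater-of-absolute-or-percent, and one-sided bounds;
mechanical and kV-imaging items ship in the default rule set as
informational metadata without computation. Orientation dose stability,
which has no standard measurement definition, is implemented as a generic
maximum deviation against a reference delivery with the
greater-of-2-MU-or-3 % band.

## Synthetic data: what it emulates and what it does not

The generator produces a full beam dataset with closed-form ground truth:

* **Depth curves** — linear build-up from a 50 % surface value to 100 % at
  d_max = 7 mm, then exponential decay. The decay constants are calibrated to
  the platform anchors PDD(100 mm) = 40.29 % (SSD 450 mm) and
  TMR(100 mm) = 0.5, i.e. μ_PDD = ln(100/40.29)/93 ≈ 0.00977 mm⁻¹ and
  μ_TMR = ln 2/93 ≈ 0.00745 mm⁻¹. The true build-up shape of a 3 MV beam is
  not reproduced, only its end points.
* **Lateral edges** — an ideal circular field convolved with a Gaussian
  source: OCR(r) ∝ erf((R+r)/σ√2) + erf((R−r)/σ√2), consistent with a ~2 mm
  focal spot. Tables are stored in isocenter-plane coordinates, so measured
  penumbra growth with depth is purely geometric (divergence). Per-collimator
  σ is solved numerically so the projected 80–20 width at 5 cm depth equals
  the measured values (1.77–2.27 mm); for the smallest collimators the two
  erf edges overlap, which both depresses the axis value and shifts the 50 %
  crossing slightly outward — the analytic helpers account for this, and the
  4 mm field size still reads within the ±0.25 mm gate.
* **Monitor series** — dose = k·MU·(1 + bias)·(1 + ε) on the 2–1,000 MU
  grid, with the bias ramping log-linearly from its maximum at 2 MU to zero
  at 1,000 MU so the origin-fit slope stays anchored by the high-MU points,
  and seeded Gaussian relative noise.
* **Survey table** — the canonical 15-station table ships verbatim as
  package data; seeded multiplicative perturbations generate variants.

What passing tests on these data show: the estimators recover known ground
truth at their stated resolutions, and the closed-form arithmetic reproduces
the platform's published desk-scale numbers. What they do not show: detector
volume averaging, film/scanner response, electron contamination near the
surface, in-patient heterogeneity — none of which the generator emulates.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give identical outputs.

## Problem sizes

Dose-grid checks run at 1–3 mm spacing over ±12–30 mm cubes (up to ~2×10⁵
voxels), profile checks at 401–801 samples, and the isodose-volume
convergence check at 1 mm spacing over a ±30 mm cube; these sizes keep every
check at desk scale while leaving the discretisation errors (≈ one sample
spacing, < 2 % on volumes) comfortably measurable.

## Known limitations

* No Monte Carlo transport, scatter kernels, or heterogeneity corrections;
  the dose engine is the verification formula, not a planning engine.
* Conformality is the plain volume ratio normalised to the reference
  isodose volume; Paddick/RTOG target-weighted indices are intentionally
  not implemented.
* The QA scheduler (daily/weekly/monthly calendars) is documentation-level,
  not computed; only the measurable acceptance metrics are.
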