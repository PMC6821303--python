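# Methods

## Signal model

A PRIA well produces fluorescence intensity once per sampling cycle (one
cycle = one minute at the default cadence). The analysis treats the
informative part of the curve as linear: the isothermal
replication–scission reaction produces reporter strands at an
approximately constant rate until substrate depletion, so intensity rises
linearly between an initial lag and an eventual plateau. Only the slope of
that linear phase is used; no baseline subtraction, drift correction or
Ct/Cq calling is attempted.

## Credible-slope screening

For a trace value₁…valueₘ, every contiguous cycle window [i, j] with at
least `min_window` cycles is evaluated:

1. **Slope.** Default (`endpoint`) mode uses the mean of successive
   differences, Σₖ (value₍ₖ₊₁₎ − valueₖ)/(j − i), which telescopes exactly
   to (valueⱼ − valueᵢ)/(j − i). An `ols` mode substitutes the ordinary
   least-squares slope of the window; for any window its R² is at least
   that of the endpoint slope.
2. **Intercept.** For the fixed slope, the intercept minimizing the sum of
   squared residuals has the closed form bias = mean(value) − slope ×
   mean(cycle); the closed form is used rather than any grid search since
   it is the exact minimizer.
3. **R².** 1 − SSE/SST about the window mean. A constant window has SST = 0
   and undefined R²; such windows are excluded from screening with a logged
   warning instead of propagating NaN.

Windows with R² above `r2_threshold` (strictly greater) and positive slope
form the confidence set; the credible slope is the maximal slope among
them. Ties are broken toward the longer window, then the smaller start
cycle, so results are deterministic. When no window passes, the result is
flagged non-credible (never an exception) and carries the highest-R²
window for diagnostics.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `r2_threshold` | 0.999 | — | the operative screening constraint of the assay's data processing; a stricter 0.9995 variant exists in the assay description, so the threshold is configurable |
| `min_window` | 10 | cycles | on 30–60-cycle runs, shorter windows make a high R² nearly vacuous and their endpoint slopes noisy |
| `slope_mode` | `endpoint` | — | reproduces the assay's defining formula; `ols` offered as the natural statistical alternative |
| `require_positive_slope` | true | — | amplification can only increase fluorescence; disable to diagnose decaying signals |

Cycles are 1-based and windows are inclusive [i, j]. Affine changes of the
intensity scale (y → c·y + d, c > 0, e.g. gain changes between
instruments) multiply all slopes by c and leave every R² and the selected
window unchanged, so screening is instrument-gain invariant.

## ΔS and calibration

ΔS = (S_control − S_tagged)/S_control × 100 is the *percent* slope
reduction, not an absolute difference: the assay's reported reductions and
the dimensionless intercepts of its calibration lines both require the
normalized form. ΔS may be negative (tagged faster than control) and is
preserved as such.

Calibration is unweighted OLS of ΔS on content — the published lines report
only linear equations with R², with no weighting scheme to honour.
Inversion is m = (ΔS − b)/a; estimates below the calibration blank
(negative m) are flagged `below_calibration` and never clipped, preserving
diagnostic value near the blank. The five published calibration lines are
stored at printed precision (1.56 × 10² is stored as 156, no invented
digits). The test-duplex lines' coefficient units are internally
inconsistent in the source (their stated ΔS range over the stated content
range does not satisfy the printed equation under either percent or
fraction units), so those models carry
`content_units="as_printed_ambiguous"` and are never rescaled; the genomic
lines are in ΔS-% per (% of total dN).

### Relative-error conventions

The benchmark-table recomputation supports both (measured −
reference)/reference and (measured − reference)/measured, with the
reference denominator as default: it reproduces all five rows of the 5fC
table exactly after one-decimal rounding. The 5hmC table is internally
inconsistent — two rows match only the measured denominator and one row
matches neither — so the report flags those rows
(`convention_dependent` / `no_convention_match`) rather than hiding the
discrepancy. Rounding to one decimal happens only at reporting time.

## Synthetic trace generator

The generator is phenomenological, not mechanistic: the analysis consumes
only the linear-phase slope, so per-cycle nicking/extension kinetics,
sequence context, enzyme parameters and fluorophore photophysics are
deliberately out of scope. A well is

intensity(c) = baseline + slope × max(0, min(c, plateau) − lag) + ε_c,
ε_c ~ N(0, noise_sd²) i.i.d.

Tagging retards the slope multiplicatively: S_tagged = S_control × (1 −
max_retardation × f), with effective tagged fraction f = content ×
labeling_efficiency + (1 − content) × nonspecific_rate. Noise-free, a
pair's ΔS is exactly 100 × max_retardation × f — linear in content, which
is the observed calibration behaviour the generator is meant to emulate.

Adduct presets carry the reported maximal retardations (5fC/PHPA 25.8%,
5hmC/glucosyl-CPBA 44.6%, 5caC/LY 53.3%; RNA m6A per-template totals 9.1%
and 14.9% for one and two sites) and HPLC-measured labeling efficiencies
(64.8%, 62.4%, 51.9%; 100% for m6A, which needs no chemistry).

Trace-shape defaults: 30 cycles (the genomic protocol records one reading
per minute for 30 min; the test-duplex protocol runs 60), baseline 100 AU,
control slope 50 AU/cycle, 5-cycle lag, no plateau within the run, noise
sd 1.0 AU = 2% of the control slope. The source reports neither trace
noise levels nor plateau onset, so these are stipulated as realistic for a
SYBR-type readout, not fitted; the 2%-of-slope noise level is also the
condition under which end-to-end parameter recovery is validated.

**Reproducibility rule.** A seed is mandatory whenever noise_sd > 0.
Substreams come from spawning `numpy.random.SeedSequence(seed)`:
`simulate_pair` spawns two children (control first, tagged second);
`simulate_dilution_series` spawns one child per (content, replicate) point
in row-major order. Each replicate well is therefore individually
reproducible, and identical seeds give bitwise-identical traces.

### What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
piecewise-linear kinetics, multiplicative retardation linear in content,
homoscedastic Gaussian noise, independent wells. Real instrument data add
features it does not model — heteroscedastic and autocorrelated noise,
baseline drift, smooth lag-to-linear transitions, well-to-well efficiency
variation, plate edge effects. Tests passing on synthetic data therefore
validate the algorithmic pipeline (screening, ΔS, calibration, inversion
and their numerics), not the assay chemistry; the published wet-lab
accuracy figures enter only as embedded constants that the package
recomputes from the printed tables.

## Validation problem sizes

The test battery uses desk-scale problems chosen to exercise every code
path: oracle-equivalence over 100 seeded traces of up to 40 cycles against
a pure-Python exhaustive search; 1,000 randomized traces for the
telescoping and affine-invariance identities; 200 Monte-Carlo traces for
screening bias; and an end-to-end recovery study (10-point dilution series
× 3 replicates, 20 held-out samples × 3 replicate wells averaged, matching
the n = 3 parallel-measurement design of the assay's recovery experiments)
requiring ≥ 90% of estimates within 10% relative error at 2%-of-slope
noise.

## Numerical choices and degenerate inputs

- Exhaustive enumeration is O(m²) windows per trace with O(window) fits;
  at m ≤ 60 this is milliseconds and needs no incremental-sum tricks that
  would trade accuracy for speed.
- Threshold comparison is strict (R² > threshold), matching "greater than"
  screening; equal-slope ties resolve longest-window-first.
- Traces shorter than `min_window`, non-unit cycle steps, non-finite
  intensities, empty plates, ragged/duplicate CSV rows are all hard errors
  that name the offending location.
- `delta_s` requires a positive control slope; a non-credible screening
  result never silently feeds ΔS (the CLI exits 2 under `--strict`).
- JSON output uses sorted keys and fixed separators; TSV floats are
  written at 6 significant digits — fixed inputs give byte-identical
  outputs end to end.

## Known limitations

- Single-analyte model: co-occurring adducts in one reaction are not
  deconvolved.
- No uncertainty propagation beyond the OLS fit statistics; content
  estimates carry no confidence intervals.
- The endpoint slope uses only the window's end values; its robustness
  comes from the R² constraint and the max-over-windows selection, not
  from the estimator itself. The `ols` mode is preferable when traces are
  noisy and the screening threshold is relaxed.
- The generator's homoscedastic noise makes screening slightly optimistic
  relative to real plateaus, where variance often grows with signal.
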