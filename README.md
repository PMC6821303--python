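# pria

Analysis toolkit for **polymerization-retardation isothermal amplification**
(PRIA) assays: quantifying genome-wide 5-methylcytosine oxides — 5hmC, 5fC
and 5caC — from real-time fluorescence traces recorded on an RT-qPCR
instrument or microplate reader.

## The problem and the method

The cytosine oxidation ladder (5mC → 5hmC → 5fC → 5caC) carries epigenetic
information at abundances far too low for routine PCR-based readouts. The
PRIA assay sidesteps sequencing entirely: each genomic sample is split into
a chemically **tagged aliquot (A)** — the target base carries a bulky
electron-withdrawing adduct — and an **untreated control (B)**. Both are
amplified isothermally by a strand-displacing polymerase plus nicking
endonuclease, so the polymerase passes every tagged site repeatedly and the
tiny per-pass extension delay accumulates into a measurably shallower
fluorescence rise.

This package implements the data-analysis side of that assay:

1. **Credible-slope screening.** For a trace of intensities *value₁ … valueₘ*,
   every cycle window [i, j] is fitted with

   * slope *S*ᵢⱼ = Σₖ (value<sub>k+1</sub> − valueₖ)/(j − i)  — the mean
     successive difference, which telescopes to
     (value<sub>j</sub> − value<sub>i</sub>)/(j − i);
   * intercept *bias* minimizing Σ (S·k + bias − valueₖ)² for that fixed
     slope;
   * R² = 1 − SSE/SST of the resulting line.

   The *credible slope* of a well is the maximal slope among windows with
   R² above a screening threshold (default 0.999). An `ols` slope mode is
   also available.

2. **ΔS retardation statistic.** For a tagged/control pair,
   ΔS = (S_B − S_A)/S_B × 100 — the percent slope reduction, which is
   linear in modified-base content.

3. **Linear calibration.** ΔS = a·m + b fitted by OLS on dilution-series
   points and inverted to convert a measured ΔS into content *m*. The five
   published calibration lines (test duplexes and genomic DNA for each
   analyte) ship as builtins.

4. **Synthetic traces.** A generator emulating lag → linear rise (slope
   multiplicatively retarded by adduct content × labeling efficiency) →
   plateau, with seeded Gaussian noise, so every stage is testable without
   instrument data.

The screener and calibration are scikit-learn style estimators
(`CredibleSlopeScreener`, `LinearCalibration`) and compose with sklearn
pipelines; everything is also reachable through plain functions and the
`pria` command-line tool.

## Worked example

Simulate two tagged/control pairs (5fC-like adduct, contents 25% and 75%),
screen them, calibrate on a simulated dilution series, and quantify:

```bash
pria simulate --out plate.csv --pairs pairs.csv --seed 7 \
     --adduct PHPA_5fC --content 0.25 --content 0.75
pria deltas plate.csv --pairs pairs.csv --out deltas.tsv
```

`deltas.tsv` (provenance comments omitted):

```text
tagged	control	tagged_slope	control_slope	credible	delta_s
S00R00A	S00R00B	48.1612	50.3433	true	4.33452
S01R00A	S01R00B	44.0721	50.2693	true	12.3281
```

Both wells screened credibly; the tagged channels rose 4.3% and 12.3%
slower than their controls. Calibrate and invert:

```bash
pria calibrate points.csv --analyte 5fC --out model.json
# INFO pria: fit 5fC calibration: a=16.4813 b=0.116547 r2=0.998645
pria quantify deltas.tsv --model model.json --out estimates.tsv
```

```text
label	delta_s	analyte	content	content_units	below_calibration
S00R00A	4.33452	5fC	0.255924	custom	false
S01R00A	12.3281	5fC	0.740933	custom	false
```

The inverted contents, 0.256 and 0.741, recover the injected 0.25 and 0.75
to within ~2.4% and ~1.2% relative error. (`points.csv` here came from
`pria.simulate_dilution_series` with the same adduct preset; with real
data it is the measured dilution series.) The calibration slope 16.48
sits near its noise-free value 100 × 0.258 × 0.648 ≈ 16.72 — maximal
retardation times labeling efficiency, in ΔS percent per unit content.

The published benchmark tables (assay vs ELISA/LC-MS/MS on five tissues
each) can be recomputed with `pria reproduce-tables`; rows whose printed
relative error matches only the non-default denominator convention, or
neither convention, are flagged rather than silently reproduced.

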