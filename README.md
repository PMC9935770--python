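# bilistrip

Quantitative colorimetry of direct-bilirubin urine test strips from RGB
photographs.

Urine test papers are a standard noninvasive screen for direct (conjugated)
bilirubin — the marker of jaundice and neonatal liver disease — but read by
eye they are only qualitative. Photographing the reacted paper (Fouchet's
reagent oxidises bilirubin to blue-green biliverdin) and averaging the raw
R/G/B grayscale over the paper disc turns the colour change into numbers: the
mean channel grayscale falls linearly with concentration, and the calibration
line's quality decides which camera channel and which light source to trust.
`bilistrip` implements that whole analysis for researchers working on
paper-based point-of-care assays, plus a spectral simulator that generates
realistic strip images for validation.

## The model

Per channel, each strip contributes one observation: the mean 8-bit grayscale
Ȳ over the circular paper region. Against concentration *c* (mg/dL) the
calibration is an ordinary least-squares line

&nbsp;&nbsp;&nbsp;&nbsp;Y = slope·c + intercept,

scored by the coefficient of determination in regression-sum form,

&nbsp;&nbsp;&nbsp;&nbsp;R² = Σ(Ŷᵢ − Ȳ̄)² / Σ(Yᵢ − Ȳ̄)²,

and detection limits follow the residual-based convention

&nbsp;&nbsp;&nbsp;&nbsp;LOD = 3σ̂/|slope|, LOQ = 10σ̂/|slope|, σ̂ = √(SSE/(n−2)).

The green channel is the most linear for every light source (the pigment's
absorption bands flank the green passband, so green responds linearly while
red and blue saturate), and a spectrally concentrated Mini-LED source beats
deuterium and halogen lamps. The simulator reproduces the published
green-channel lines — y = −6.2971x + 221.81 (Mini-LED), −6.2029x + 221.72
(halogen), −1.8078x + 231.56 (deuterium) over 0.1–2.0 mg/dL — both as
measurement-level tables and as rendered PNG strip images.

## Worked example

```python
from bilistrip import (default_concentration_series, generate_calibration_table,
                       response_preset, fit_line, limits_from_fit)

preset = response_preset("mini_led", "G")   # published line + calibrated noise
table = generate_calibration_table(default_concentration_series(), preset, seed=1)
fit = fit_line(table, "G")
lim = limits_from_fit(fit)
print(f"slope     {fit.slope:+.4f} counts/(mg/dL)")
print(f"intercept {fit.intercept:.2f} counts")
print(f"R^2       {fit.r_squared:.4f}")
print(f"LOD       {lim.lod:.2f} mg/dL   LOQ {lim.loq:.2f} mg/dL")
```

prints

```
slope     -6.2699 counts/(mg/dL)
intercept 222.04 counts
R^2       0.9704
LOD       0.34 mg/dL   LOQ 1.14 mg/dL
```

One simulated 12-strip series under the Mini-LED: the fitted slope and
intercept recover the generating line (−6.2971, 221.81) within noise, R²
lands in the high-0.9 range typical of this lamp, and the limits follow from
this particular draw's residual scale. Medians over 500 such series
reproduce the published R² values (0.9313 / 0.8984 / 0.7809 for
Mini-LED / halogen / deuterium) to within ~0.01.

## Command line

```bash
bilistrip simulate --out fixtures/ --seed 7       # 3 lamps x 12 strip PNGs
bilistrip analyze  --manifest fixtures/manifest.csv --out report/
bilistrip limits   --slope -6.2971 --sigma 1.17551
bilistrip spectra  --preset mini_led
```

`analyze` writes per-image ROI statistics (`stats.csv`), ranked per-channel
fits (`fits.csv` / `fits.json`) and a light-source comparison table
(`comparison.csv`). Flags can live in a `key = value` config file
(`--config`); explicit flags win.

## Analysis scripts

`analysis/` holds numbered drivers that run the full study sequence and
write their tables under `results/`:

1. `01_simulate_strips.py` — render the 36-image synthetic strip set;
2. `02_analyze_strips.py` — ROI → calibration → channel ranking per lamp
   (green first everywhere, Mini-LED most linear);
3. `03_calibration_medians.py` — 500-table Monte-Carlo recovery of the
   published green-channel R² values;
4. `04_detection_limits.py` — LOD/LOQ from the published slopes and packaged
   residual SDs (0.56 and 0.69 mg/dL; quantification threshold 10/3 × LOD).

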