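# specfinger

Metabolic fingerprinting of blood mid-infrared (FT-MIR) spectra for
discriminating **fibromyalgia (FM)** from **Long COVID (LC)** — two
clinically near-indistinguishable chronic pain conditions — plus healthy
controls (HC).  The package implements the complete chemometric workflow on
absorbance spectra of the blood low-molecular-weight fraction:

* **Pretreatment** — unit-vector normalization, Savitzky–Golay smoothing
  (5 points) and second derivative (7 points), region selection, mean
  centering.
* **OSC-filtered PLS-DA** ("OPLS-DA") — orthogonal signal correction removes
  spectral variance exactly orthogonal to the dummy-coded class response
  (FM = 1, LC = 2); NIPALS partial least squares then regresses the filtered
  spectra onto the class codes.  Validation by leave-one-out internal
  cross-validation and an independent stratified 80/20 external set, reported
  as SECV/SEP, Rcv, R², sensitivity/specificity/accuracy and ROC/AUC.
* **Band deconvolution** — the 1500–1700 cm⁻¹ amide/carboxylate region is
  resolved per sample into FWHM-parameterized Gaussian bands
  g(ν) = h·exp(−4 ln2 (ν−c)²/w²) via the inverted second derivative, with
  relative percentage areas (share of the summed fitted band areas) and fit
  diagnostics (χ², F).  The FM fingerprint contains a band near
  **1565 cm⁻¹** (glutamate carboxylate side-chain stretch) that LC and HC
  lack — the discriminating marker.
* **Group statistics** — one-way ANOVA and Tukey HSD (5%) comparisons of
  band areas and centers across disease groups with compact letter display.
* **Synthetic cohorts** — patient data are not public, so a forward
  generator renders class-specific Gaussian band mixtures with broadband
  background, amplitude/baseline/noise variation and a class-unrelated
  structured nuisance direction, giving every stage a ground truth to be
  tested against.

## Worked example

```python
import specfinger as sf

profiles = sf.default_class_profiles()
cohort = sf.simulate_cohort([profiles["FM"], profiles["LC"]],
                            sf.SimulationConfig(n_per_class=50, seed=1))

pre = sf.PreprocessConfig(region=(1528, 1624))
cfg = sf.ModelConfig(n_osc=1, n_lv=1, split_seed=1001)
train, val = sf.split_dataset(cohort, cfg)
model = sf.DiscriminantModel.fit(train, pre, cfg)
cv = sf.loocv(train, pre, cfg)
ev = sf.external_validate(model, val)
print(f"Rcv={cv.rcv:.3f}  SECV={cv.secv:.3f}  SEP={ev.sep:.3f}  "
      f"accuracy={ev.accuracy:.0f}%  specificity={ev.specificity:.0f}%")

fm = sf.deconvolve_group(cohort, "FM")
print(fm.summary()[["center_mean", "pct_area_mean", "n"]].round(1))
```

Output:

```
Rcv=0.976  SECV=0.109  SEP=0.124  accuracy=100%  specificity=100%
   center_mean  pct_area_mean   n
0       1564.9           37.5  46
1       1588.1           37.0  49
2       1637.3            4.2  46
3       1670.3           16.3  50
```

`Rcv` is the correlation of leave-one-out predictions with the class codes
and `SECV`/`SEP` their root-mean-square residuals on the class-code scale —
the held-out 10 + 10 validation samples all classify correctly.  The FM
group summary resolves the four FM bands, including the 1565 cm⁻¹ marker
carrying ≈37% of the region's band area; running the same lines with
`"LC"` yields only three bands (1581/1635/1670) with ≈64% at 1581 cm⁻¹.

The same workflow is scriptable from the shell:

```
specfinger run --seed 1 --out run1/     # full bundle: cohort, reports, tables
specfinger report --bundle run1/        # one-page summary
specfinger simulate --classes FM,LC --n 50 --seed 7 --out cohort.csv
```

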